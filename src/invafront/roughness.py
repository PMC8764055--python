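"""Dynamic-scaling (kinetic roughening) analysis of 2D invasion fronts.

The interface width

    W^2 = (1/L) * sum_i (X_i - H)^2,        H = mean_i X_i,

grows as ``W ~ t**beta`` from the flat initial condition and saturates at
``W_sat`` once lateral correlations span the strip.  Across system sizes
the curves obey the Family-Vicsek ansatz ``W ~ L**alpha f(t / L**z)`` with
``f(u) ~ u**beta`` for small ``u``, constant for large ``u``, and
``z = alpha / beta``.  This module estimates ``beta``, ``W_sat``, the
roughness exponents versus ``L`` and versus the barrier intensity ``N``,
and a numerical collapse-quality score for the ansatz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .fronts import ExponentFit, fit_power_law
from .lattice import FrontTrajectory, ModelParams

__all__ = [
    "WidthSeries",
    "ScalingSummary",
    "NotSaturatedError",
    "interface_width",
    "width_series",
    "growth_exponent",
    "saturated_width",
    "tail_slope_paired",
    "roughness_vs_L",
    "roughness_vs_N",
    "collapse_quality",
]


class NotSaturatedError(RuntimeError):
    """The tail of a width series is still growing; run longer."""


@dataclass(frozen=True)
class WidthSeries:
    """Ensemble-averaged interface width per recorded time.

    ``W_replicates`` (replicates x times), when present, lets the
    saturation test judge tail slopes against replicate-level noise.
    """

    times: np.ndarray
    W: np.ndarray
    n_replicates: int
    params: ModelParams
    W_replicates: np.ndarray | None = None


@dataclass(frozen=True)
class ScalingSummary:
    """Collected dynamic-scaling estimates for one parameter family."""

    beta: ExponentFit | None = None
    W_sat: float | None = None
    W_sat_se: float | None = None
    alpha_L: ExponentFit | None = None
    alpha_N: ExponentFit | None = None

    @property
    def z(self) -> float | None:
        """Dynamic exponent alpha/beta (saturation time ~ L**z)."""
        if self.beta is None or self.alpha_L is None or self.beta.exponent == 0:
            return None
        return self.alpha_L.exponent / self.beta.exponent


def interface_width(profile) -> float:
    """Root mean squared deviation of the profile from its mean height.

    Population divisor ``L`` (not ``L - 1``), straight from the defining
    formula.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    return float(np.sqrt(np.mean((profile - profile.mean()) ** 2)))


def width_series(
    trajectories: Sequence[FrontTrajectory], reduce: str = "mean"
) -> WidthSeries:
    """Per-time ensemble average of the interface width.

    ``reduce="mean"`` averages W over replicates (default); ``"rms"``
    averages W^2 and takes the square root.  The two differ only in
    amplitude, not in the fitted exponents.
    """
    if len(trajectories) < 1:
        raise ValueError("need at least one trajectory")
    t0 = trajectories[0].times
    widths = []
    for tr in trajectories:
        if tr.values.ndim != 2:
            raise ValueError("width analysis needs 2D front profiles")
        if not np.array_equal(tr.times, t0):
            raise ValueError("trajectories have mismatched recording times")
        v = tr.values.astype(float)
        widths.append(np.sqrt(((v - v.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)))
    widths = np.stack(widths)
    if reduce == "mean":
        W = widths.mean(axis=0)
    elif reduce == "rms":
        W = np.sqrt((widths**2).mean(axis=0))
    else:
        raise ValueError(f"unknown reduce {reduce!r}")
    return WidthSeries(times=np.asarray(t0, dtype=float), W=W,
                       n_replicates=len(trajectories),
                       params=trajectories[0].params, W_replicates=widths)


def growth_exponent(series: WidthSeries, window=None, W_sat: float | None = None) -> ExponentFit:
    """Growth exponent beta: log-log OLS slope of W versus t over a window.

    The default window starts at t = 5 (past the lattice-discreteness
    regime) and, when ``W_sat`` is supplied, ends where W first reaches
    half of it.  A window reaching into the plateau (above 0.8 W_sat) is
    rejected.
    """
    t, W = series.times, series.W
    if window is None:
        hi = t[-1]
        if W_sat is not None:
            crossing = np.nonzero(W >= 0.5 * W_sat)[0]
            if crossing.size:
                hi = t[crossing[0]]
        window = (5.0, float(hi))
    if W_sat is not None:
        crossing = np.nonzero(W >= 0.8 * W_sat)[0]
        if crossing.size and window[1] > t[crossing[0]]:
            raise ValueError(
                f"window upper end {window[1]} overlaps the plateau "
                f"(W reaches 0.8*W_sat at t={t[crossing[0]]})"
            )
    m = (t >= window[0]) & (t <= window[1]) & (t > 0) & (W > 0)
    if m.sum() < 3:
        raise ValueError(f"growth window {window} covers fewer than 3 usable points")
    res = sps.linregress(np.log(t[m]), np.log(W[m]))
    return ExponentFit(
        exponent=float(res.slope),
        stderr=float(res.stderr),
        x_values=t[m],
        fit_range=(float(t[m].min()), float(t[m].max())),
        r_squared=float(res.rvalue**2),
    )


def saturated_width(
    series: WidthSeries, tail_fraction: float = 0.25, slope_tol: float = 0.05
) -> tuple[float, float]:
    """Plateau width W_sat: mean of W over the final ``tail_fraction`` of times.

    Accepted only if the log-log slope of W versus t over that tail is
    consistent with zero: within ``slope_tol``, or — when per-replicate
    widths are available — within three standard errors of zero, the
    standard error coming from the spread of per-replicate tail slopes
    (a finite ensemble cannot resolve slopes below its own noise floor).
    Otherwise :class:`NotSaturatedError` is raised.  Returns
    ``(W_sat, standard error over the tail)``.
    """
    t, W = series.times, series.W
    n = len(t)
    i0 = int(np.ceil((1 - tail_fraction) * n))
    i0 = min(max(i0, 0), n - 3)
    tt, ww = t[i0:], W[i0:]
    good = (tt > 0) & (ww > 0)
    if good.sum() < 3:
        raise NotSaturatedError("tail too short or width not positive")
    if series.W_replicates is not None and series.n_replicates >= 4:
        reps_tail = series.W_replicates[:, i0:][:, good]
        slope, se = tail_slope_paired(tt[good], reps_tail)
        tol = slope_tol + 2.0 * se
    else:
        slope = sps.linregress(np.log(tt[good]), np.log(ww[good])).slope
        tol = slope_tol
    if abs(slope) > tol:
        raise NotSaturatedError(
            f"tail log-log slope {slope:.3f} exceeds {tol:.3f}; "
            "the width is still evolving - run longer"
        )
    return float(ww.mean()), float(ww.std(ddof=1) / np.sqrt(len(ww)))


def tail_slope_paired(times, widths) -> tuple[float, float]:
    """Log-log tail slope with a replicate-level standard error.

    Splits the tail in half; each replicate contributes the log-ratio of
    its half-means divided by the log-time separation (pairing within a
    replicate cancels its overall width offset, so the SE reflects genuine
    temporal trend uncertainty).  Returns ``(slope, slope_se)``.
    """
    times = np.asarray(times, dtype=float)
    widths = np.atleast_2d(np.asarray(widths, dtype=float))
    k = len(times) // 2
    if k < 1 or widths.shape[1] != len(times):
        raise ValueError("need at least 2 tail points")
    lt1 = np.log(times[:k]).mean()
    lt2 = np.log(times[k:]).mean()
    m1 = widths[:, :k].mean(axis=1)
    m2 = widths[:, k:].mean(axis=1)
    ok = (m1 > 0) & (m2 > 0)
    if ok.sum() < 2:
        raise ValueError("tail widths must be positive")
    s = np.log(m2[ok] / m1[ok]) / (lt2 - lt1)
    return float(s.mean()), float(s.std(ddof=1) / np.sqrt(len(s)))


def roughness_vs_L(L_values, W_sats, fit_range=None) -> ExponentFit:
    """Roughness exponent alpha_L: growth-law fit of W_sat against L."""
    return fit_power_law(L_values, W_sats, fit_range=fit_range, convention="growth")


def roughness_vs_N(N_values, W_sats, fit_range=None) -> ExponentFit:
    """Barrier-roughness exponent alpha_N: growth-law fit of W_sat against N."""
    return fit_power_law(N_values, W_sats, fit_range=fit_range, convention="growth")


def collapse_quality(
    curves: Mapping[int, tuple[np.ndarray, np.ndarray]], alpha: float, z: float,
    n_grid: int = 60,
) -> float:
    """Family-Vicsek collapse score for width curves at several L.

    Each curve ``(t, W)`` is rescaled to ``(t / L**z, W / L**alpha)``; the
    score is the mean squared log-deviation between curves over the common
    rescaled-time overlap (0 = perfect collapse).  Diagnostic only.
    """
    if len(curves) < 2:
        raise ValueError("need curves for at least 2 system sizes")
    rescaled = []
    for L, (t, W) in curves.items():
        t = np.asarray(t, dtype=float)
        W = np.asarray(W, dtype=float)
        m = (t > 0) & (W > 0)
        u = np.log(t[m] / float(L) ** z)
        w = np.log(W[m] / float(L) ** alpha)
        rescaled.append((u, w))
    lo = max(u.min() for u, _ in rescaled)
    hi = min(u.max() for u, _ in rescaled)
    if hi <= lo:
        raise ValueError("rescaled time supports do not overlap")
    grid = np.linspace(lo, hi, n_grid)
    stack = np.stack([np.interp(grid, u, w) for u, w in rescaled])
    return float(np.mean((stack - stack.mean(axis=0)) ** 2))
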