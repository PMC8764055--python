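"""Config-driven simulation sweeps and their analysis.

A sweep runs the lattice model over grids of barrier intensity ``N``,
interaction ``zeta`` and strip width ``L`` with deterministically derived
per-replicate seeds, writes plain-text trajectory files plus a JSON
manifest, and an analysis pass turns the trajectory files into Langevin
parameters (V, D), interface-width statistics and the power-law exponents
connecting them.  Four presets mirror the experiment families the model is
built to probe: the 1D single-species N-sweep, the 1D interaction sweep,
the 2D Langevin sweeps versus L and N, and the 2D roughening study.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from ._engine import Simulation
from .fronts import (
    default_window,
    ensemble_stats,
    fit_langevin,
    fit_power_law,
    read_trajectories_csv,
    write_trajectories_csv,
)
from .lattice import (
    FrontOverflowError,
    FrontTrajectory,
    ModelParams,
    run_replicate,
)
from .roughness import (
    NotSaturatedError,
    growth_exponent,
    saturated_width,
    tail_slope_paired,
    width_series,
)

__all__ = [
    "derive_seed",
    "load_config",
    "auto_box_length",
    "run_ensemble",
    "run_to_saturation",
    "SweepConfig",
    "RunManifest",
    "preset",
    "run_sweep",
    "analyze_sweep",
]

log = logging.getLogger("invafront")

#: box units allocated per expected unit of front travel; generous so the
#: occupied fraction stays small (<~5%) and bulk redraws do not distort the
#: effective clock within a run
_BOX_FACTOR = 20.0
_BOX_MIN = 64


def derive_seed(base_seed: int, *key) -> int:
    """Deterministic, collision-resistant seed for one (cell, replicate).

    Mixes the base seed with the cell key through a SeedSequence so that
    every grid point and replicate gets a distinct independent stream.
    """
    ints = [int(base_seed) & 0x7FFFFFFF]
    for k in key:
        ints.append(zlib.crc32(repr(k).encode()))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] & 0x7FFFFFFF)


def _make_params(dimension, N, n_steps, *, zeta=0.0, species_count=1, L=None,
                 record_every=1, box_length=_BOX_MIN, seed=0) -> ModelParams:
    return ModelParams(
        dimension=dimension, N=int(N), box_length=int(box_length),
        n_steps=int(n_steps), zeta=float(zeta), species_count=species_count,
        L=L, record_every=int(record_every), seed=int(seed),
    )


def auto_box_length(dimension, N, n_steps, *, zeta=0.0, species_count=1,
                    L=None, base_seed=0, cell_key=(), n_pilot=6) -> int:
    """Size the box from a short velocity pilot.

    The box is kept proportional to the expected front travel so that the
    occupied fraction follows the same time profile in every cell of a
    sweep; the residual time rescaling from bulk redraws then cancels in
    cross-cell exponent fits.
    """
    pilot_steps = int(min(max(n_steps, 1), 500))
    pilot_box = 64 + int(2.5 * pilot_steps)
    finals = []
    for r in range(n_pilot):
        p = _make_params(dimension, N, pilot_steps, zeta=zeta,
                         species_count=species_count, L=L,
                         record_every=max(1, pilot_steps // 4),
                         box_length=pilot_box,
                         seed=derive_seed(base_seed, "pilot", *cell_key, r))
        tr = run_replicate(p)
        v = tr.values[-1]
        finals.append(float(np.mean(v)))
    v_est = max(np.mean(finals), 1.0) / pilot_steps
    return max(_BOX_MIN, int(np.ceil(_BOX_FACTOR * v_est * n_steps)))


def run_ensemble(dimension, N, n_steps, replicates, *, zeta=0.0,
                 species_count=1, L=None, record_every=1, base_seed=0,
                 cell_key=(), box_length=None, engine="fast",
                 max_box_retries=3) -> list[FrontTrajectory]:
    """Run a seeded ensemble of replicates at one parameter point.

    All replicates share one box size (so they share one time unit); if
    any replicate overruns the box the whole cell restarts with a doubled
    box.
    """
    if box_length is None:
        box_length = auto_box_length(
            dimension, N, n_steps, zeta=zeta, species_count=species_count,
            L=L, base_seed=base_seed, cell_key=cell_key)
    for attempt in range(max_box_retries + 1):
        try:
            out = []
            for r in range(replicates):
                p = _make_params(dimension, N, n_steps, zeta=zeta,
                                 species_count=species_count, L=L,
                                 record_every=record_every, box_length=box_length,
                                 seed=derive_seed(base_seed, *cell_key, r))
                out.append(run_replicate(p, engine=engine))
            return out
        except FrontOverflowError:
            box_length *= 2
            log.info("box overflow; retrying cell %s with box_length=%d",
                     cell_key, box_length)
    raise FrontOverflowError(
        f"cell {cell_key} still overflows at box_length={box_length}")


def _estimate_saturation_steps(N, zeta, L, *, species_count=2, base_seed=0,
                               cell_key=(), n_pilot=10, slope_tol=0.05,
                               tail_fraction=0.25, max_steps=400_000,
                               min_steps=1000) -> int:
    """Small-ensemble pilot: extend the run until the width series flattens."""
    sims = []
    for r in range(n_pilot):
        p = _make_params(2, N, 0, zeta=zeta, species_count=species_count, L=L,
                         box_length=_BOX_MIN,
                         seed=derive_seed(base_seed, "satpilot", *cell_key, r))
        sims.append(Simulation(p))
    all_times: list[np.ndarray] = []
    all_w = [[] for _ in range(n_pilot)]
    total = 0
    chunk = 400
    flat_streak = 0
    while total < max_steps:
        rec = max(1, chunk // 40)
        for k, sim in enumerate(sims):
            front = int(sim.front_col.max())
            # worst-case unit speed on the first chunk, 3x observed speed after
            v_loc = 1.0 if sim.t == 0 else 3.0 * max(front, 8) / sim.t
            need = front + int(v_loc * chunk) + 64
            if need > sim.params.box_length:
                sim.grow(int(1.5 * need))
            times, fronts = sim.run(chunk, rec)
            f = fronts.astype(float)
            w = np.sqrt(((f - f.mean(axis=1, keepdims=True)) ** 2).mean(axis=1))
            if k == 0:
                all_times.append(times)
            all_w[k].append(w)
        total += chunk
        t = np.concatenate(all_times)
        reps = np.stack([np.concatenate(w) for w in all_w])
        n = len(t)
        i0 = min(max(int(np.ceil((1 - tail_fraction) * n)), 0), n - 3)
        tt = t[i0:]
        good = tt > 0
        if good.sum() >= 4 and total >= min_steps:
            try:
                slope, se = tail_slope_paired(tt[good], reps[:, i0:][:, good])
            except ValueError:
                slope, se = np.inf, 0.0
            # widths can grow in stages (e.g. slow domain-wall coarsening
            # under competition), so demand two consecutive flat tails and
            # give the noisy pilot only a 1-SE allowance
            flat_streak = flat_streak + 1 if abs(slope) < slope_tol + se else 0
            if flat_streak >= 2:
                return total
        chunk = int(chunk * 1.5)
    return max_steps


def run_to_saturation(N, zeta, L, replicates, *, species_count=2, base_seed=0,
                      cell_key=(), slope_tol=0.05, tail_fraction=0.25,
                      margin=1.3, max_retries=6, reduce="mean"):
    """2D width study run long enough for the interface width to saturate.

    A small pilot ensemble estimates the saturation time (requiring two
    consecutive flat tails, since competitive widths grow in stages); the
    full ensemble then runs ``margin`` times longer and the plateau is
    accepted only if the replicate-level tail-flatness test passes,
    doubling the run length otherwise.  Returns ``(WidthSeries, W_sat, W_sat_se, trajectories)``.
    """
    t_sat = _estimate_saturation_steps(
        N, zeta, L, species_count=species_count, base_seed=base_seed,
        cell_key=cell_key, slope_tol=slope_tol, tail_fraction=tail_fraction)
    n_steps = int(np.ceil(margin * t_sat))
    for attempt in range(max_retries + 1):
        rec = max(1, n_steps // 400)
        trajs = run_ensemble(
            2, N, n_steps, replicates, zeta=zeta, species_count=species_count,
            L=L, record_every=rec, base_seed=base_seed,
            cell_key=tuple(cell_key) + ("sat", attempt))
        series = width_series(trajs, reduce=reduce)
        try:
            w_sat, w_se = saturated_width(series, tail_fraction=tail_fraction,
                                          slope_tol=slope_tol)
            return series, w_sat, w_se, trajs
        except NotSaturatedError:
            n_steps *= 2
            log.info("width not saturated for cell %s; extending to %d steps",
                     cell_key, n_steps)
    raise NotSaturatedError(
        f"width series for cell {cell_key} did not saturate within {n_steps} steps")


# ---------------------------------------------------------------------------
# sweeps

@dataclass
class SweepConfig:
    """Resolved configuration of one simulation sweep."""

    experiment: str = "custom"
    dimension: int = 1
    species_count: int = 1
    N_grid: tuple = (5, 10, 20, 40, 80)
    zeta_grid: tuple = (0.0,)
    L_grid: tuple = (None,)
    replicates: int = 100
    n_steps: int = 2000
    record_every: int = 4
    base_seed: int = 0
    out_dir: str = "sweep_out"
    #: None -> package default window (drop first 20% of times)
    fit_window: tuple | None = None
    #: run 2D cells to width saturation instead of fixed n_steps
    to_saturation: bool = False
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.N_grid and self.zeta_grid and self.L_grid):
            raise ValueError("grids must be non-empty")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for any fit")

    def cells(self):
        for z in self.zeta_grid:
            for L in self.L_grid:
                for N in self.N_grid:
                    yield {"N": N, "zeta": z, "L": L}


@dataclass
class RunManifest:
    """Inventory of a completed sweep, sufficient to reproduce it bit-exactly."""

    config: dict
    cells: list
    version: str = __version__
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], cells=d["cells"],
                   version=d.get("version", "?"), created=d.get("created", ""))


def load_config(path, **overrides) -> SweepConfig:
    """Build a :class:`SweepConfig` from a YAML (or JSON) file.

    The file holds a mapping of SweepConfig fields; keyword ``overrides``
    (e.g. from CLI flags) take precedence over file values.  ``None``
    overrides are ignored.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    unknown = set(data) - {f.name for f in fields(SweepConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("N_grid", "zeta_grid", "L_grid"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    if "fit_window" in data and data["fit_window"] is not None:
        data["fit_window"] = tuple(data["fit_window"])
    return SweepConfig(**data)


def preset(experiment: str, *, seed: int = 0, scale: float = 1.0,
           out_dir: str = "sweep_out") -> SweepConfig:
    """Default sweep configurations for the four experiment families.

    ``scale`` multiplies replicate counts (and fixed step counts) for
    convergence studies.  The defaults are reduced-scale but large enough
    for stable exponent fits.
    """
    s = lambda n: max(2, int(round(n * scale)))
    if experiment == "fig2":  # 1D single species: V_f, D_f vs N
        return SweepConfig(experiment="fig2", dimension=1, species_count=1,
                           N_grid=(5, 10, 20, 40, 80), replicates=s(300),
                           n_steps=int(2000 * max(scale, 1)), record_every=4,
                           base_seed=seed, out_dir=out_dir)
    if experiment == "fig3":  # 1D two species: gamma_V, gamma_D vs zeta
        return SweepConfig(experiment="fig3", dimension=1, species_count=2,
                           N_grid=(5, 10, 20, 40),
                           zeta_grid=(-1.0, -0.5, 0.0, 0.5, 1.0),
                           replicates=s(150), n_steps=0,  # resolved per cell
                           record_every=1, base_seed=seed, out_dir=out_dir)
    if experiment == "fig4":  # 2D Langevin: D_H vs L at N=10
        return SweepConfig(experiment="fig4", dimension=2, species_count=2,
                           N_grid=(10,), zeta_grid=(-1.0, 0.0, 1.0),
                           L_grid=(8, 16, 32, 64), replicates=s(200),
                           n_steps=600, record_every=2, base_seed=seed,
                           out_dir=out_dir)
    if experiment == "fig5":  # 2D roughening: W_sat vs L and vs N
        return SweepConfig(experiment="fig5", dimension=2, species_count=2,
                           N_grid=(10,), zeta_grid=(-1.0, 0.0, 1.0),
                           L_grid=(8, 16, 32, 64), replicates=s(100),
                           n_steps=0, record_every=1, base_seed=seed,
                           out_dir=out_dir, to_saturation=True)
    raise ValueError(f"unknown experiment {experiment!r}")


def _steps_for_displacement(N, zeta, species_count, base_seed, cell_key,
                            target=60.0, cap=400_000) -> int:
    """Steps needed for the mean 1D front to travel ``target`` units."""
    sim_steps = 2000
    while True:
        finals = []
        for r in range(4):
            p = _make_params(1, N, sim_steps, zeta=zeta,
                             species_count=species_count,
                             box_length=64 + int(2.5 * sim_steps),
                             record_every=sim_steps,
                             seed=derive_seed(base_seed, "vpilot", *cell_key, r))
            finals.append(float(run_replicate(p).values[-1]))
        x = np.mean(finals)
        if x >= target or sim_steps >= cap:
            return int(min(np.ceil(sim_steps * max(target / max(x, 1e-9), 1.0)), cap))
        sim_steps *= 4


def _cell_tag(cell) -> str:
    z = f"{cell['zeta']:+.2f}"
    L = cell["L"] if cell["L"] is not None else 0
    return f"N{cell['N']}_z{z}_L{L}"


def run_sweep(config: SweepConfig) -> RunManifest:
    """Run every grid cell, writing trajectory CSVs and a manifest.

    Completed cells found in an existing manifest are skipped, so an
    interrupted sweep can resume.  Overflow failures are recorded per cell
    and do not abort the sweep.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    done = {}
    if manifest_path.exists():
        old = RunManifest.load(manifest_path)
        if old.config == _config_dict(config):
            done = {c["tag"]: c for c in old.cells if c["status"] == "ok"}
    cells = []
    for cell in config.cells():
        tag = _cell_tag(cell)
        fname = out / f"traj_{tag}.csv"
        if tag in done and fname.exists():
            cells.append(done[tag])
            continue
        entry = {"tag": tag, **{k: cell[k] for k in ("N", "zeta", "L")},
                 "file": fname.name, "replicates": config.replicates}
        t0 = time.time()
        try:
            cell_key = (config.experiment, tag)
            if config.to_saturation:
                series, w_sat, w_se, trajs = run_to_saturation(
                    cell["N"], cell["zeta"], cell["L"], config.replicates,
                    species_count=config.species_count,
                    base_seed=config.base_seed, cell_key=cell_key)
                entry["n_steps"] = int(trajs[0].params.n_steps)
            else:
                n_steps = config.n_steps
                if n_steps <= 0:  # adaptive 1D run length
                    n_steps = _steps_for_displacement(
                        cell["N"], cell["zeta"], config.species_count,
                        config.base_seed, cell_key)
                rec = max(config.record_every, n_steps // 500)
                trajs = run_ensemble(
                    config.dimension, cell["N"], n_steps, config.replicates,
                    zeta=cell["zeta"], species_count=config.species_count,
                    L=cell["L"], record_every=rec,
                    base_seed=config.base_seed, cell_key=cell_key)
                entry["n_steps"] = int(n_steps)
            write_trajectories_csv(trajs, fname)
            entry.update(
                status="ok",
                box_length=int(trajs[0].params.box_length),
                record_every=int(trajs[0].params.record_every),
                seeds=[int(tr.seed) for tr in trajs],
                runtime_s=round(time.time() - t0, 2),
            )
        except (FrontOverflowError, NotSaturatedError) as exc:
            entry.update(status="failed", error=str(exc))
            log.warning("cell %s failed: %s", tag, exc)
        cells.append(entry)
        log.info("cell %s: %s", tag, entry["status"])
    manifest = RunManifest(config=_config_dict(config), cells=cells,
                           created=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest_path.write_text(manifest.to_json())
    return manifest


def _config_dict(config: SweepConfig) -> dict:
    d = asdict(config)
    for k in ("N_grid", "zeta_grid", "L_grid", "fit_window"):
        if d[k] is not None:
            d[k] = list(d[k])
    return d


def _upper_half(values: Sequence[float]) -> list[float]:
    xs = sorted(values)
    half = xs[len(xs) // 2:]
    return half if len(half) >= 3 else xs


def analyze_sweep(manifest, out_path=None, fit_window=None) -> dict:
    """Fit Langevin parameters and scaling exponents from a sweep's files.

    Per cell: V, D (and for 2D width runs W_sat and beta).  Across cells:
    decay exponents of V and D versus N (fitted over the upper half of the
    N grid, matching the large-N regime where the power laws hold, with a
    full-grid fallback when the half-grid has fewer than 3 points), the
    decay exponent of D versus L, and growth exponents of W_sat versus L
    and N.  Returns the summary dict; optionally writes it as JSON.
    """
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.load(manifest)
    base = Path(manifest.config["out_dir"])
    missing = [c["tag"] for c in manifest.cells
               if c["status"] == "ok" and not (base / c["file"]).exists()]
    if missing:
        raise FileNotFoundError(f"trajectory files missing for cells: {missing}")

    cell_rows = []
    for c in manifest.cells:
        if c["status"] != "ok":
            cell_rows.append({**_cell_id(c), "status": c["status"]})
            continue
        trajs = read_trajectories_csv(base / c["file"])
        stats = ensemble_stats(trajs)
        window = fit_window or manifest.config.get("fit_window") or default_window(stats.times)
        lv = fit_langevin(stats, window, method="endpoints")
        row = {**_cell_id(c), "status": "ok", "V": lv.V, "V_se": lv.V_se,
               "D": lv.D, "D_se": lv.D_se,
               "fit_window": [float(window[0]), float(window[1])]}
        if trajs[0].values.ndim == 2:
            series = width_series(trajs)
            try:
                w_sat, w_se = saturated_width(series)
                row.update(W_sat=w_sat, W_sat_se=w_se)
                try:
                    beta = growth_exponent(series, W_sat=w_sat)
                    row.update(beta=beta.exponent, beta_se=beta.stderr)
                except ValueError:
                    pass
            except NotSaturatedError:
                try:
                    beta = growth_exponent(series)
                    row.update(beta=beta.exponent, beta_se=beta.stderr)
                except ValueError:
                    pass
        cell_rows.append(row)

    ok = [r for r in cell_rows if r.get("status") == "ok"]
    exponents = []
    # decay exponents vs N at fixed (zeta, L)
    for (z, L), rows in _group(ok, ("zeta", "L")):
        rows = sorted(rows, key=lambda r: r["N"])
        Ns = [r["N"] for r in rows]
        if len(Ns) >= 3:
            half = _upper_half(Ns)
            rng = (min(half), max(half))
            for qty, name in (("V", "gamma_V"), ("D", "gamma_D")):
                ys = [r[qty] for r in rows]
                if all(y > 0 for y in ys):
                    f = fit_power_law(Ns, ys, fit_range=rng, convention="decay")
                    exponents.append({"name": name, "zeta": z, "L": L,
                                      "exponent": f.exponent, "stderr": f.stderr,
                                      "fit_range": list(f.fit_range),
                                      "r_squared": f.r_squared})
        if len(Ns) >= 3 and all("W_sat" in r for r in rows):
            f = fit_power_law(Ns, [r["W_sat"] for r in rows], convention="growth")
            exponents.append({"name": "alpha_N", "zeta": z, "L": L,
                              "exponent": f.exponent, "stderr": f.stderr,
                              "fit_range": list(f.fit_range),
                              "r_squared": f.r_squared})
    # exponents vs L at fixed (zeta, N)
    for (z, N), rows in _group(ok, ("zeta", "N")):
        rows = sorted(rows, key=lambda r: r["L"] or 0)
        Ls = [r["L"] for r in rows]
        if len(Ls) >= 3 and all(L for L in Ls):
            f = fit_power_law(Ls, [r["D"] for r in rows], convention="decay")
            exponents.append({"name": "gamma_L", "zeta": z, "N": N,
                              "exponent": f.exponent, "stderr": f.stderr,
                              "fit_range": list(f.fit_range),
                              "r_squared": f.r_squared})
            if all("W_sat" in r for r in rows):
                f = fit_power_law(Ls, [r["W_sat"] for r in rows], convention="growth")
                exponents.append({"name": "alpha_L", "zeta": z, "N": N,
                                  "exponent": f.exponent, "stderr": f.stderr,
                                  "fit_range": list(f.fit_range),
                                  "r_squared": f.r_squared})
    # velocity ordering across zeta at fixed (N, L)
    orderings = []
    for (N, L), rows in _group(ok, ("N", "L")):
        rows = sorted(rows, key=lambda r: r["zeta"])
        if len(rows) >= 2:
            orderings.append({
                "N": N, "L": L,
                "zeta": [r["zeta"] for r in rows],
                "V": [r["V"] for r in rows],
                "V_increasing_in_zeta": all(
                    rows[i + 1]["V"] >= rows[i]["V"] for i in range(len(rows) - 1)),
            })

    summary = {"experiment": manifest.config.get("experiment", "custom"),
               "cells": cell_rows, "exponents": exponents,
               "velocity_ordering": orderings}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(summary, indent=1))
    return summary


def _cell_id(c) -> dict:
    return {"N": c["N"], "zeta": c["zeta"], "L": c["L"]}


def _group(rows, keys):
    groups: dict = {}
    for r in rows:
        k = tuple(r[key] for key in keys)
        groups.setdefault(k, []).append(r)
    return groups.items()
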