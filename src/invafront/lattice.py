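"""Stochastic lattice engine for invasion through a degradable barrier.

Species live on lattice units and spread by duplication and migration into
nearest neighbours (NNs).  Every unit carries a barrier that must be worn
down before it can be entered: each failed entry attempt increments a
per-unit trial counter, and the unit becomes occupiable once the counter
condition is met.  With a single species the condition is ``n >= N`` where
``N`` is the barrier intensity.  With two species the trials are counted
separately (``n1``, ``n2``) and the unit opens when

    zeta * n1 + n2 > N   or   n1 + zeta * n2 > N

where ``zeta`` weights the rival's past effort: ``zeta > 0`` means the
populations cooperate in degrading the barrier, ``zeta < 0`` that each
cancels part of the other's work, ``zeta = 0`` that they ignore each other.
The two species may co-occupy a unit; space is never contested, the barrier
is their only coupling.

Geometry: a semi-infinite 1D array seeded with one individual at unit 0, or
a 2D strip of transverse width ``L`` (periodic in the transverse direction)
seeded with a fully occupied first row.

This module holds the parameter/state types and a literal, rule-by-rule
reference implementation of the dynamics.  Production runs go through the
equivalent event-driven engine in :mod:`invafront._engine`, which skips the
(inert) bulk and is checked against this one distributionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "SiteState",
    "LatticeState",
    "FrontTrajectory",
    "ConfigurationError",
    "FrontOverflowError",
    "JammedLatticeError",
    "init_state",
    "neighbors",
    "occupiable_for",
    "attempt_entry",
    "update_unit",
    "select_and_update",
    "step",
    "run_replicate",
]

#: consecutive non-counting redraws tolerated before declaring the lattice jammed
REDRAW_BOUND = 10_000


class ConfigurationError(ValueError):
    """Raised when model parameters violate an invariant."""


class FrontOverflowError(RuntimeError):
    """The invasion front reached the far end of the allocated box.

    Results past that point would be censored; rerun with a larger
    ``box_length``.
    """


class JammedLatticeError(RuntimeError):
    """Unit selection was redrawn more than ``REDRAW_BOUND`` times in a row."""


@dataclass(frozen=True)
class ModelParams:
    """All simulation knobs.

    Parameters
    ----------
    dimension
        1 for the half-infinite array, 2 for the periodic strip.
    N
        Barrier intensity: number of failed trials a unit must absorb
        before the occupiability condition can hold (positive integer).
    box_length
        Allocated extent in the growth direction, in units.  Must
        comfortably exceed the largest front excursion; hitting the end
        raises :class:`FrontOverflowError`.
    n_steps
        Time steps to simulate.  One step elapses when the number of
        counted unit selections reaches the number of allocated units.
    zeta
        Interaction parameter (two-species model only); typically in
        [-1, 1].  Ignored when ``species_count`` is 1.
    species_count
        1 or 2.
    L
        Transverse width in units (2D only), periodic.
    record_every
        Steps between front recordings.
    seed
        Non-negative integer seeding the replicate's random stream.
    """

    dimension: int
    N: int
    box_length: int
    n_steps: int
    zeta: float = 0.0
    species_count: int = 1
    L: int | None = None
    record_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ConfigurationError(f"dimension must be 1 or 2, got {self.dimension}")
        if self.N < 1:
            raise ConfigurationError(f"N must be >= 1, got {self.N}")
        if self.box_length <= 0:
            raise ConfigurationError(f"box_length must be positive, got {self.box_length}")
        if self.species_count not in (1, 2):
            raise ConfigurationError(f"species_count must be 1 or 2, got {self.species_count}")
        if self.dimension == 2:
            if self.L is None or self.L < 2:
                raise ConfigurationError(f"2D runs need L >= 2, got L={self.L}")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be non-negative")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        if self.species_count == 2 and abs(self.zeta) > 1:
            warnings.warn(
                f"zeta={self.zeta} outside the usual [-1, 1] range", stacklevel=3
            )

    @property
    def width(self) -> int:
        """Transverse width of the stored arrays (1 in 1D)."""
        return 1 if self.dimension == 1 else int(self.L)  # type: ignore[arg-type]

    @property
    def n_units(self) -> int:
        """Number of allocated units = counted selections per time step."""
        return self.box_length * self.width


@dataclass
class SiteState:
    """Occupancy flags and barrier trial counters of one unit."""

    occ1: bool = False
    occ2: bool = False
    n1: int = 0
    n2: int = 0

    def occupied_by(self, species: int) -> bool:
        return self.occ1 if species == 1 else self.occ2


@dataclass
class LatticeState:
    """Full lattice state: per-species occupancy, counters, clock.

    Arrays are indexed ``[row]`` in 1D and ``[row, column]`` in 2D, with
    row 0 the seeded edge and the column coordinate periodic.
    """

    occ1: np.ndarray
    occ2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    t: int = 0
    selections: int = 0

    def site(self, index) -> SiteState:
        idx = _array_index(index)
        return SiteState(
            bool(self.occ1[idx]),
            bool(self.occ2[idx]),
            int(self.n1[idx]),
            int(self.n2[idx]),
        )

    def occupied_any(self) -> np.ndarray:
        return self.occ1 | self.occ2


@dataclass(frozen=True)
class FrontTrajectory:
    """Recorded front positions of one replicate.

    ``values`` has shape ``(T,)`` in 1D (front index X per recorded time)
    and ``(T, L)`` in 2D (per-column front profile X_i).
    """

    times: np.ndarray
    values: np.ndarray
    params: ModelParams
    seed: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values lengths differ")


def _array_index(index):
    """Public (1D int | 2D (column, row)) coordinate -> numpy index."""
    if np.isscalar(index):
        return int(index)
    col, row = index
    return (int(row), int(col))


def init_state(params: ModelParams) -> LatticeState:
    """Initial lattice: unit 0 occupied (1D) or the whole first row (2D).

    All modelled species start on the seeded units; every trial counter
    is zero.
    """
    shape = (params.box_length,) if params.dimension == 1 else (params.box_length, params.width)
    occ1 = np.zeros(shape, dtype=bool)
    occ2 = np.zeros(shape, dtype=bool)
    occ1[0] = True
    if params.species_count == 2:
        occ2[0] = True
    return LatticeState(
        occ1=occ1,
        occ2=occ2,
        n1=np.zeros(shape, dtype=np.int64),
        n2=np.zeros(shape, dtype=np.int64),
    )


def neighbors(index, params: ModelParams) -> list:
    """Nearest neighbours of a unit.

    1D: up to two (no unit beyond either end of the box).  2D: four, with
    the column coordinate wrapped periodically and the row (growth)
    direction bounded as in 1D.  1D coordinates are plain ints; 2D
    coordinates are ``(column, row)`` pairs.
    """
    if params.dimension == 1:
        k = int(index)
        if not 0 <= k < params.box_length:
            raise IndexError(f"index {k} outside the box")
        return [j for j in (k - 1, k + 1) if 0 <= j < params.box_length]
    col, row = (int(index[0]), int(index[1]))
    L = params.width
    if not (0 <= col < L and 0 <= row < params.box_length):
        raise IndexError(f"index {(col, row)} outside the box")
    out = [((col - 1) % L, row), ((col + 1) % L, row)]
    out += [(col, r) for r in (row - 1, row + 1) if 0 <= r < params.box_length]
    return out


def _directions(index, params: ModelParams) -> list:
    """Migration draw targets: one entry per lattice direction.

    ``None`` marks a direction pointing outside the box (the wall at the
    seeded edge or the far end): a migration draw landing there fails with
    no side effect, exactly like a draw onto a unit holding the acting
    species.
    """
    if params.dimension == 1:
        k = int(index)
        return [j if 0 <= j < params.box_length else None for j in (k - 1, k + 1)]
    col, row = (int(index[0]), int(index[1]))
    L = params.width
    out: list = [((col - 1) % L, row), ((col + 1) % L, row)]
    out += [(col, r) if 0 <= r < params.box_length else None for r in (row - 1, row + 1)]
    return out


def occupiable_for(site: SiteState, species: int, params: ModelParams) -> bool:
    """Whether the barrier at ``site`` is open to an entering individual.

    Single species: ``n >= N``.  Two species: ``zeta*n1 + n2 > N`` or
    ``n1 + zeta*n2 > N`` (real arithmetic, strict), re-evaluated from the
    current counters at every attempt.  The condition is symmetric, so the
    answer does not depend on ``species``.
    """
    if params.species_count == 1:
        return site.n1 >= params.N
    z = params.zeta
    return (z * site.n1 + site.n2 > params.N) or (site.n1 + z * site.n2 > params.N)


def attempt_entry(target, species: int, state: LatticeState, params: ModelParams) -> bool:
    """One entry trial of ``species`` on ``target``.

    Returns True if the unit is occupiable (the caller then performs the
    actual occupation); otherwise increments the acting species' trial
    counter on the target by one and returns False.
    """
    idx = _array_index(target)
    occ = state.occ1 if species == 1 else state.occ2
    if occ[idx]:
        raise ValueError(f"entry attempt on a unit already holding species {species}")
    if occupiable_for(state.site(target), species, params):
        return True
    counters = state.n1 if species == 1 else state.n2
    counters[idx] += 1
    return False


def _occupants(state: LatticeState, idx) -> list[int]:
    out = []
    if state.occ1[idx]:
        out.append(1)
    if state.occ2[idx]:
        out.append(2)
    return out


def update_unit(index, state: LatticeState, params: ModelParams, rng: np.random.Generator) -> None:
    """Duplication and migration trials for every species on one unit.

    All occupants run their duplication trials first (in random order when
    the unit is co-occupied), then their migration trials (fresh random
    order).  Duplication targets a uniform choice among in-box NNs empty of
    the acting species.  Migration draws uniformly over the lattice
    *directions* (two per dimension); a draw pointing outside the box, or
    onto a unit already holding the species, simply fails.  Either trial,
    on a closed target, wears the barrier down by one instead.
    """
    idx = _array_index(index)
    nbs = neighbors(index, params)
    dirs = _directions(index, params)
    occupants = _occupants(state, idx)

    for phase in ("duplicate", "migrate"):
        order = occupants if len(occupants) == 1 else list(rng.permutation(occupants))
        for s in order:
            occ = state.occ1 if s == 1 else state.occ2
            if phase == "duplicate":
                cands = [nb for nb in nbs if not occ[_array_index(nb)]]
                if not cands:
                    continue
                target = cands[rng.integers(len(cands))]
                if attempt_entry(target, s, state, params):
                    occ[_array_index(target)] = True
            else:
                target = dirs[rng.integers(len(dirs))]
                if target is None:
                    continue  # migration pointing out of the box fails
                tidx = _array_index(target)
                if occ[tidx]:
                    continue  # migration into own kind fails silently
                if attempt_entry(target, s, state, params):
                    occ[idx] = False
                    occ[tidx] = True


def _can_act(state: LatticeState, index, params: ModelParams) -> bool:
    """True if some occupant species has a NN not containing it."""
    idx = _array_index(index)
    nbs = [_array_index(nb) for nb in neighbors(index, params)]
    for s in _occupants(state, idx):
        occ = state.occ1 if s == 1 else state.occ2
        if any(not occ[nb] for nb in nbs):
            return True
    return False


def _draw_unit(state: LatticeState, params: ModelParams, rng: np.random.Generator):
    if params.dimension == 1:
        return int(rng.integers(params.box_length))
    flat = int(rng.integers(params.n_units))
    return (flat % params.width, flat // params.width)


def select_and_update(state: LatticeState, params: ModelParams, rng: np.random.Generator) -> str:
    """One counted unit selection.

    Draws a unit uniformly over the whole box.  Empty draws count toward
    the step tally and do nothing (``"empty"``).  Occupied units with no
    available NN are redrawn without counting; otherwise the unit's
    occupants update and the draw counts (``"acted"``).
    """
    for _ in range(REDRAW_BOUND):
        index = _draw_unit(state, params, rng)
        idx = _array_index(index)
        if not (state.occ1[idx] or state.occ2[idx]):
            state.selections += 1
            return "empty"
        if _can_act(state, index, params):
            update_unit(index, state, params, rng)
            state.selections += 1
            return "acted"
    raise JammedLatticeError(
        f"no countable unit found in {REDRAW_BOUND} consecutive redraws"
    )


def step(state: LatticeState, params: ModelParams, rng: np.random.Generator) -> LatticeState:
    """Advance one time step: counted selections equal to the unit count."""
    target = state.selections + params.n_units
    while state.selections < target:
        select_and_update(state, params, rng)
    state.t += 1
    return state


def _front_of(state: LatticeState, params: ModelParams) -> np.ndarray:
    occ = state.occupied_any()
    if params.dimension == 1:
        return np.array([int(np.max(np.nonzero(occ)[0]))], dtype=np.int64)
    rows = np.arange(occ.shape[0], dtype=np.int64)[:, None]
    return np.where(occ, rows, -1).max(axis=0)


def run_replicate(params: ModelParams, engine: str = "fast") -> FrontTrajectory:
    """Run one seeded replicate and record its front trajectory.

    ``engine="fast"`` uses the event-driven compiled engine (default);
    ``engine="reference"`` runs the literal rule-by-rule implementation in
    this module.  The two are distributionally equivalent but consume
    random numbers differently, so trajectories are only bit-reproducible
    within one engine.
    """
    if engine == "fast":
        from ._engine import Simulation

        sim = Simulation(params)
        times, fronts = sim.run(params.n_steps, params.record_every)
        values = fronts[:, 0] if params.dimension == 1 else fronts
        return FrontTrajectory(times=times, values=values, params=params, seed=params.seed)
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")

    rng = np.random.default_rng(params.seed)
    state = init_state(params)
    times = [0]
    fronts = [_front_of(state, params)]
    for _ in range(params.n_steps):
        try:
            step(state, params, rng)
        except JammedLatticeError:
            # a fully occupied box jams before the per-step overflow check
            if _front_of(state, params).max() >= params.box_length - 1:
                raise FrontOverflowError(
                    f"front reached box_length-1={params.box_length - 1}; "
                    "rerun with a larger box_length"
                ) from None
            raise
        front = _front_of(state, params)
        if front.max() >= params.box_length - 1:
            raise FrontOverflowError(
                f"front reached box_length-1={params.box_length - 1} at t={state.t}; "
                "rerun with a larger box_length"
            )
        if state.t % params.record_every == 0:
            times.append(state.t)
            fronts.append(front)
    stacked = np.array(fronts, dtype=np.int64)
    values = stacked[:, 0] if params.dimension == 1 else stacked
    return FrontTrajectory(
        times=np.array(times, dtype=np.int64), values=values, params=params, seed=params.seed
    )
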