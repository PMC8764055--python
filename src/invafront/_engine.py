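"""Event-driven compiled engine, distributionally equivalent to the
literal rules in :mod:`invafront.lattice`.

The literal process spends almost all draws on units where nothing can
happen: empty units (a counted no-op) and occupied units whose occupants
have no free neighbour (an uncounted redraw).  Each counted selection is
therefore uniform over the *countable* units — the empty ones plus the
"active" occupied ones — and between two actions the state does not
change.  The engine keeps the active set explicitly, draws the geometric
number of counted no-op selections separating consecutive actions, and
executes only the actions.  This is an exact reformulation of the
sequential dynamics, not an approximation; a distributional cross-check
against the reference engine is part of the test suite.

Sites are stored flat (``i = row * L + col``, ``L = 1`` in 1D) with
occupancy as a species bitmask.  The per-column front (maximum occupied
row) is maintained incrementally: raised on entry, rescanned downward on
the rare vacation of a lead unit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .lattice import (
    FrontOverflowError,
    LatticeState,
    ModelParams,
)

__all__ = ["Simulation"]

_OCC = 0  # counts[] slots
_ACT = 1
_OVF = 2


@njit(cache=True)
def _nbrs(i, dim, L, rows, out):
    """Fill ``out`` with the flat neighbour indices of ``i``; return count."""
    row = i // L
    col = i - row * L
    c = 0
    if dim == 2:
        out[c] = row * L + ((col - 1) % L)
        c += 1
        out[c] = row * L + ((col + 1) % L)
        c += 1
    if row > 0:
        out[c] = i - L
        c += 1
    if row < rows - 1:
        out[c] = i + L
        c += 1
    return c


@njit(cache=True)
def _occupiable(i, n1, n2, species_count, zeta, N):
    if species_count == 1:
        return n1[i] >= N
    return (zeta * n1[i] + n2[i] > N) or (n1[i] + zeta * n2[i] > N)


@njit(cache=True)
def _refresh(i, occ, active, act_list, act_pos, counts, dim, L, rows, nb):
    """Recompute the active flag of site ``i`` and fix the active list."""
    o = occ[i]
    a = False
    if o != 0:
        nnb = _nbrs(i, dim, L, rows, nb)
        for bit in (1, 2):
            if o & bit:
                for k in range(nnb):
                    if occ[nb[k]] & bit == 0:
                        a = True
                        break
            if a:
                break
    if a and active[i] == 0:
        active[i] = 1
        act_pos[i] = counts[_ACT]
        act_list[counts[_ACT]] = i
        counts[_ACT] += 1
    elif (not a) and active[i] == 1:
        active[i] = 0
        p = act_pos[i]
        last = counts[_ACT] - 1
        moved = act_list[last]
        act_list[p] = moved
        act_pos[moved] = p
        counts[_ACT] = last
        act_pos[i] = -1


@njit(cache=True)
def _refresh_around(i, occ, active, act_list, act_pos, counts, dim, L, rows, nb, nb2):
    _refresh(i, occ, active, act_list, act_pos, counts, dim, L, rows, nb2)
    nnb = _nbrs(i, dim, L, rows, nb)
    for k in range(nnb):
        _refresh(nb[k], occ, active, act_list, act_pos, counts, dim, L, rows, nb2)


@njit(cache=True)
def _set_occ(i, bit, occ, counts, front_col, L):
    if occ[i] == 0:
        counts[_OCC] += 1
    occ[i] |= bit
    row = i // L
    col = i - row * L
    if row > front_col[col]:
        front_col[col] = row


@njit(cache=True)
def _clear_occ(i, bit, occ, counts, front_col, L):
    occ[i] &= 3 ^ bit
    if occ[i] == 0:
        counts[_OCC] -= 1
        row = i // L
        col = i - row * L
        if row == front_col[col]:
            r = row
            while r >= 0 and occ[r * L + col] == 0:
                r -= 1
            front_col[col] = r


@njit(cache=True)
def _update_unit(
    i, occ, n1, n2, active, act_list, act_pos, counts, front_col,
    dim, L, rows, species_count, zeta, N, rng, nb, nb2, nb3, cand,
):
    """Duplication round then migration round for the occupants of ``i``.

    Occupant set is captured at selection time; with two occupants each
    round runs them in fresh uniform order.
    """
    nnb = _nbrs(i, dim, L, rows, nb)
    o0 = occ[i]
    for phase in range(2):
        if o0 == 3:
            first = 1 if rng.random() < 0.5 else 2
            second = 3 ^ first
        else:
            first = o0
            second = 0
        for slot in range(2):
            bit = first if slot == 0 else second
            if bit == 0:
                continue
            if phase == 0:
                # duplication: uniform among NNs empty of this species
                c = 0
                for k in range(nnb):
                    if occ[nb[k]] & bit == 0:
                        cand[c] = nb[k]
                        c += 1
                if c == 0:
                    continue
                tgt = cand[int(rng.random() * c)]
                if _occupiable(tgt, n1, n2, species_count, zeta, N):
                    _set_occ(tgt, bit, occ, counts, front_col, L)
                    _refresh_around(tgt, occ, active, act_list, act_pos, counts,
                                    dim, L, rows, nb2, nb3)
                elif bit == 1:
                    n1[tgt] += 1
                else:
                    n2[tgt] += 1
            else:
                # migration: uniform over lattice directions; out-of-box or
                # own-kind draws fail with no side effect
                d = int(rng.random() * (2 * dim))
                row = i // L
                col = i - row * L
                if dim == 2 and d == 0:
                    tgt = row * L + ((col - 1) % L)
                elif dim == 2 and d == 1:
                    tgt = row * L + ((col + 1) % L)
                elif d == 2 * dim - 2:
                    tgt = i - L if row > 0 else -1
                else:
                    tgt = i + L if row < rows - 1 else -1
                if tgt < 0 or occ[tgt] & bit:
                    continue
                if _occupiable(tgt, n1, n2, species_count, zeta, N):
                    _clear_occ(i, bit, occ, counts, front_col, L)
                    _set_occ(tgt, bit, occ, counts, front_col, L)
                    _refresh_around(i, occ, active, act_list, act_pos, counts,
                                    dim, L, rows, nb2, nb3)
                    _refresh_around(tgt, occ, active, act_list, act_pos, counts,
                                    dim, L, rows, nb2, nb3)
                elif bit == 1:
                    n1[tgt] += 1
                else:
                    n2[tgt] += 1


@njit(cache=True)
def _rebuild_active(occ, active, act_list, act_pos, counts, dim, L, rows):
    nb = np.empty(4, np.int64)
    counts[_ACT] = 0
    n_occ = 0
    for i in range(rows * L):
        active[i] = 0
        act_pos[i] = -1
        if occ[i] != 0:
            n_occ += 1
    counts[_OCC] = n_occ
    for i in range(rows * L):
        if occ[i] != 0:
            _refresh(i, occ, active, act_list, act_pos, counts, dim, L, rows, nb)


@njit(cache=True)
def _run(
    occ, n1, n2, active, act_list, act_pos, front_col, counts,
    dim, L, rows, species_count, zeta, N,
    t0, n_steps, record_every, rec_times, rec_fronts, rng,
):
    """Advance ``n_steps`` steps, recording the front every ``record_every``.

    Returns the number of records written; sets ``counts[_OVF]`` and stops
    early if the front touches the far end of the box.
    """
    S = rows * L
    nb = np.empty(4, np.int64)
    nb2 = np.empty(4, np.int64)
    nb3 = np.empty(4, np.int64)
    cand = np.empty(4, np.int64)
    nrec = 0
    for si in range(n_steps):
        remaining = S
        while remaining > 0:
            A = counts[_ACT]
            if A == 0:
                break
            E = S - counts[_OCC]
            p = A / (A + E)
            if p < 1.0:
                # counted no-op draws before the next action: Geometric(p)
                g = int(np.log1p(-rng.random()) / np.log1p(-p)) + 1
            else:
                g = 1
            if g > remaining:
                break
            remaining -= g
            i = act_list[int(rng.random() * A)]
            _update_unit(i, occ, n1, n2, active, act_list, act_pos, counts,
                         front_col, dim, L, rows, species_count, zeta, N,
                         rng, nb, nb2, nb3, cand)
        t = t0 + si + 1
        mx = front_col[0]
        for c in range(1, L):
            if front_col[c] > mx:
                mx = front_col[c]
        if mx >= rows - 1:
            counts[_OVF] = 1
            return nrec
        if t % record_every == 0:
            rec_times[nrec] = t
            for c in range(L):
                rec_fronts[nrec, c] = front_col[c]
            nrec += 1
    return nrec


class Simulation:
    """Stateful fast engine for one replicate; supports continuation.

    ``run`` may be called repeatedly; the random stream, clock and lattice
    persist across calls, so a run can be extended (e.g. until an
    interface-width series saturates) without restarting.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        rows, L = params.box_length, params.width
        S = rows * L
        self.occ = np.zeros(S, dtype=np.int64)
        self.n1 = np.zeros(S, dtype=np.int64)
        self.n2 = np.zeros(S, dtype=np.int64)
        mask = 1 if params.species_count == 1 else 3
        self.occ[:L] = mask  # row 0 seeded by every modelled species
        self.active = np.zeros(S, dtype=np.int64)
        self.act_list = np.zeros(S, dtype=np.int64)
        self.act_pos = np.full(S, -1, dtype=np.int64)
        self.front_col = np.zeros(L, dtype=np.int64)
        self.counts = np.zeros(4, dtype=np.int64)
        _rebuild_active(self.occ, self.active, self.act_list, self.act_pos,
                        self.counts, params.dimension, L, rows)
        self.rng = np.random.default_rng(params.seed)
        self.t = 0

    def run(self, n_steps: int, record_every: int = 1):
        """Advance and return ``(times, fronts)`` for the new records.

        ``fronts`` has shape ``(n_records, L)`` (``L = 1`` in 1D).  The
        record at the current time is included only on the first call
        (t = 0, the flat seeded front).
        """
        p = self.params
        rows, L = p.box_length, p.width
        cap = n_steps // record_every + 1
        rec_times = np.zeros(cap, dtype=np.int64)
        rec_fronts = np.zeros((cap, L), dtype=np.int64)
        nrec = _run(
            self.occ, self.n1, self.n2, self.active, self.act_list, self.act_pos,
            self.front_col, self.counts,
            p.dimension, L, rows, p.species_count, float(p.zeta), p.N,
            self.t, n_steps, record_every, rec_times, rec_fronts, self.rng,
        )
        if self.counts[_OVF]:
            raise FrontOverflowError(
                f"front reached box_length-1={rows - 1}; rerun with a larger box_length"
            )
        include_t0 = self.t == 0
        self.t += n_steps
        times = rec_times[:nrec]
        fronts = rec_fronts[:nrec]
        if include_t0:
            times = np.concatenate(([0], times))
            fronts = np.concatenate((self.front_col[None, :] * 0, fronts))
        return times, fronts

    def grow(self, new_box_length: int) -> None:
        """Extend the box in the growth direction, preserving the state.

        Used by long adaptive runs (e.g. run-until-saturation) to avoid
        sizing the box for an unknown end time up front.  Enlarging the
        box also enlarges the per-step selection count, which slightly
        lowers the rate at which the redrawn bulk selections are
        reassigned to the front; the effect is a smooth O(occupied
        fraction) time rescaling, kept small by generous sizing.
        """
        p = self.params
        old_rows, L = p.box_length, p.width
        if new_box_length <= old_rows:
            return
        S = new_box_length * L
        for name in ("occ", "n1", "n2"):
            old = getattr(self, name)
            new = np.zeros(S, dtype=np.int64)
            new[: old_rows * L] = old
            setattr(self, name, new)
        self.active = np.zeros(S, dtype=np.int64)
        self.act_list = np.zeros(S, dtype=np.int64)
        self.act_pos = np.full(S, -1, dtype=np.int64)
        self.counts[_OVF] = 0
        _rebuild_active(self.occ, self.active, self.act_list, self.act_pos,
                        self.counts, p.dimension, L, new_box_length)
        from dataclasses import replace

        self.params = replace(p, box_length=new_box_length)

    @property
    def state(self) -> LatticeState:
        """Current lattice as a :class:`~invafront.lattice.LatticeState`."""
        p = self.params
        shape = (p.box_length,) if p.dimension == 1 else (p.box_length, p.width)
        occ = self.occ.reshape(shape)
        return LatticeState(
            occ1=(occ & 1).astype(bool),
            occ2=(occ & 2).astype(bool),
            n1=self.n1.reshape(shape).copy(),
            n2=self.n2.reshape(shape).copy(),
            t=self.t,
            selections=self.t * p.n_units,
        )
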