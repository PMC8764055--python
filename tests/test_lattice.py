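"""Unit and property tests for the lattice update rules and engines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from invafront._engine import Simulation, _rebuild_active
from invafront.lattice import (
    ConfigurationError,
    JammedLatticeError,
    ModelParams,
    SiteState,
    attempt_entry,
    init_state,
    neighbors,
    occupiable_for,
    run_replicate,
    select_and_update,
    step,
    update_unit,
)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelParams(dimension=3, N=1, box_length=10, n_steps=1)
        with pytest.raises(ConfigurationError):
            ModelParams(dimension=1, N=0, box_length=10, n_steps=1)
        with pytest.raises(ConfigurationError):
            ModelParams(dimension=2, N=1, box_length=10, n_steps=1, L=1)
        with pytest.raises(ConfigurationError):
            ModelParams(dimension=1, N=1, box_length=0, n_steps=1)

    def test_zeta_outside_unit_interval_warns(self):
        with pytest.warns(UserWarning):
            ModelParams(dimension=1, N=1, box_length=10, n_steps=1,
                        species_count=2, zeta=1.5)


class TestInitState:
    def test_1d_single_seed(self, params_1d):
        state = init_state(params_1d)
        assert state.occ1.sum() == 1 and state.occ1[0]
        assert not state.occ2.any()
        assert state.n1.sum() == 0 and state.n2.sum() == 0

    def test_2d_first_row_both_species(self, params_2d):
        state = init_state(params_2d)
        assert state.occ1[0].all() and state.occ2[0].all()
        assert state.occ1.sum() == 5 and state.occ2.sum() == 5
        assert state.n1.sum() == 0 and state.n2.sum() == 0


class TestNeighbors:
    def test_1d_origin_has_single_neighbor(self, params_1d):
        assert neighbors(0, params_1d) == [1]

    def test_1d_interior(self, params_1d):
        assert sorted(neighbors(7, params_1d)) == [6, 8]

    def test_2d_periodic_wrap(self):
        p = ModelParams(dimension=2, N=1, L=4, box_length=20, n_steps=1)
        nbs = neighbors((3, 7), p)
        assert sorted(nbs) == sorted([(2, 7), (0, 7), (3, 6), (3, 8)])

    def test_out_of_box_raises(self, params_1d):
        with pytest.raises(IndexError):
            neighbors(params_1d.box_length, params_1d)


class TestOccupiability:
    def test_single_species_threshold_inclusive(self):
        p = ModelParams(dimension=1, N=5, box_length=10, n_steps=1)
        assert occupiable_for(SiteState(n1=5), 1, p)
        assert not occupiable_for(SiteState(n1=4), 1, p)

    def test_two_species_strict_and_symmetric(self):
        p = ModelParams(dimension=1, N=3, box_length=10, n_steps=1,
                        species_count=2, zeta=1.0)
        assert occupiable_for(SiteState(n1=2, n2=2), 1, p)  # 4 > 3
        assert occupiable_for(SiteState(n1=2, n2=2), 2, p)
        p0 = ModelParams(dimension=1, N=3, box_length=10, n_steps=1,
                         species_count=2, zeta=0.0)
        assert not occupiable_for(SiteState(n1=3, n2=0), 1, p0)  # strict: 3 > 3 fails
        pm = ModelParams(dimension=1, N=3, box_length=10, n_steps=1,
                         species_count=2, zeta=-1.0)
        assert not occupiable_for(SiteState(n1=3, n2=3), 1, pm)  # cancellation

    def test_rival_trials_open_barrier_through_weighted_term(self):
        # a lone leader benefits from the rival's past trials: with n1=0, n2=5
        # the printed condition zeta*n1 + n2 > N holds for any zeta
        p = ModelParams(dimension=1, N=1, box_length=10, n_steps=1,
                        species_count=2, zeta=-1.0)
        assert occupiable_for(SiteState(n1=0, n2=5), 1, p)

    @given(n1=st.integers(0, 5), n2=st.integers(0, 5),
           zeta=st.sampled_from([-1.0, -0.5, 0.0, 0.5, 1.0]),
           N=st.integers(1, 4))
    @settings(max_examples=200, deadline=None)
    def test_two_species_matches_enumerated_condition(self, n1, n2, zeta, N):
        p = ModelParams(dimension=1, N=N, box_length=10, n_steps=1,
                        species_count=2, zeta=zeta)
        expected = (zeta * n1 + n2 > N) or (n1 + zeta * n2 > N)
        assert occupiable_for(SiteState(n1=n1, n2=n2), 1, p) == expected
        assert occupiable_for(SiteState(n1=n1, n2=n2), 2, p) == expected


class TestAttemptEntry:
    def test_open_target_no_counter_change(self):
        p = ModelParams(dimension=1, N=2, box_length=10, n_steps=1)
        state = init_state(p)
        state.n1[3] = 2
        assert attempt_entry(3, 1, state, p)
        assert state.n1[3] == 2

    def test_closed_target_increments(self):
        p = ModelParams(dimension=1, N=2, box_length=10, n_steps=1)
        state = init_state(p)
        assert not attempt_entry(3, 1, state, p)
        assert state.n1[3] == 1

    def test_entry_on_own_unit_is_contract_violation(self):
        p = ModelParams(dimension=1, N=2, box_length=10, n_steps=1)
        state = init_state(p)
        with pytest.raises(ValueError):
            attempt_entry(0, 1, state, p)


class TestUpdateUnit:
    def test_open_neighbors_duplicate_and_maybe_migrate(self):
        # both NNs open: one gains a duplicate; total mass becomes 2
        p = ModelParams(dimension=1, N=1, box_length=10, n_steps=1)
        moved = 0
        for seed in range(40):
            state = init_state(p)
            state.occ1[:] = False
            state.occ1[5] = True
            state.n1[4] = state.n1[6] = 1  # both occupiable
            update_unit(5, state, p, np.random.default_rng(seed))
            assert state.occ1.sum() == 2
            occ = set(np.nonzero(state.occ1)[0])
            assert occ in ({4, 5}, {5, 6}, {4, 6})
            moved += 5 not in occ
        assert 0 < moved < 40  # migration happens sometimes, not always

    def test_migration_onto_own_kind_fails_silently(self):
        p = ModelParams(dimension=1, N=5, box_length=10, n_steps=1)
        for seed in range(20):
            state = init_state(p)
            state.occ1[:] = False
            state.occ1[4] = state.occ1[5] = state.occ1[6] = True
            n_before = state.n1.copy()
            update_unit(5, state, p, np.random.default_rng(seed))
            assert state.occ1.sum() == 3
            assert np.array_equal(state.n1, n_before)  # no trials at all

    def test_co_occupied_unit_increments_both_counters(self):
        # closed NNs: each species' duplication wears the barrier down by one
        p = ModelParams(dimension=1, N=50, box_length=12, n_steps=1,
                        species_count=2)
        both_same_target = 0
        for seed in range(60):
            state = init_state(p)
            state.occ1[:] = state.occ2[:] = False
            state.occ1[5] = state.occ2[5] = True
            update_unit(5, state, p, np.random.default_rng(seed))
            inc1 = state.n1[4] + state.n1[6]
            inc2 = state.n2[4] + state.n2[6]
            assert 1 <= inc1 <= 2  # dup trial certain, migration 50/50
            assert 1 <= inc2 <= 2
            if state.n1[6] >= 1 and state.n2[6] >= 1:
                both_same_target += 1
        assert both_same_target > 0  # both species can hit the same NN

    def test_counters_never_decrease(self):
        p = ModelParams(dimension=1, N=4, box_length=30, n_steps=1,
                        species_count=2, zeta=-0.5)
        state = init_state(p)
        rng = np.random.default_rng(3)
        prev1, prev2 = state.n1.copy(), state.n2.copy()
        for _ in range(200):
            select_and_update(state, p, rng)
            assert np.all(state.n1 >= prev1) and np.all(state.n2 >= prev2)
            prev1, prev2 = state.n1.copy(), state.n2.copy()


class TestSelectionAndStep:
    def test_empty_draw_counts_and_does_nothing(self):
        p = ModelParams(dimension=1, N=2, box_length=6, n_steps=1)
        state = init_state(p)
        rng = np.random.default_rng(0)
        tags = [select_and_update(state, p, rng) for _ in range(30)]
        assert state.selections == 30
        assert set(tags) <= {"empty", "acted"}
        assert "empty" in tags and "acted" in tags

    def test_fully_blocked_lattice_jams(self):
        p = ModelParams(dimension=1, N=2, box_length=5, n_steps=1)
        state = init_state(p)
        state.occ1[:] = True
        with pytest.raises(JammedLatticeError):
            select_and_update(state, p, np.random.default_rng(0))

    def test_step_advances_tally_by_unit_count(self):
        p = ModelParams(dimension=1, N=2, box_length=17, n_steps=1)
        state = init_state(p)
        step(state, p, np.random.default_rng(1))
        assert state.selections == 17 and state.t == 1

    def test_occupied_count_never_decreases(self):
        p = ModelParams(dimension=2, N=2, L=4, box_length=40, n_steps=1,
                        species_count=2, zeta=0.5)
        state = init_state(p)
        rng = np.random.default_rng(5)
        c1, c2 = state.occ1.sum(), state.occ2.sum()
        for _ in range(25):
            step(state, p, rng)
            assert state.occ1.sum() >= c1 and state.occ2.sum() >= c2
            c1, c2 = state.occ1.sum(), state.occ2.sum()

    def test_duplication_adds_at_most_one_per_species_per_update(self):
        p = ModelParams(dimension=1, N=1, box_length=30, n_steps=1,
                        species_count=2, zeta=1.0)
        state = init_state(p)
        rng = np.random.default_rng(7)
        for _ in range(150):
            c1, c2 = state.occ1.sum(), state.occ2.sum()
            select_and_update(state, p, rng)
            assert 0 <= state.occ1.sum() - c1 <= 1
            assert 0 <= state.occ2.sum() - c2 <= 1


class TestRunReplicate:
    def test_deterministic_per_engine(self):
        p = ModelParams(dimension=1, N=3, box_length=120, n_steps=150, seed=11)
        for engine in ("fast", "reference"):
            a = run_replicate(p, engine=engine)
            b = run_replicate(p, engine=engine)
            assert np.array_equal(a.values, b.values)
            assert np.array_equal(a.times, b.times)

    def test_zero_steps_returns_initial_front(self):
        p = ModelParams(dimension=1, N=3, box_length=10, n_steps=0, seed=1)
        tr = run_replicate(p)
        assert list(tr.times) == [0] and list(tr.values) == [0]

    def test_2d_records_profiles(self):
        p = ModelParams(dimension=2, N=3, L=6, box_length=60, n_steps=40,
                        species_count=2, zeta=0.0, record_every=10, seed=2)
        tr = run_replicate(p)
        assert tr.values.shape == (5, 6)
        assert np.array_equal(tr.times, [0, 10, 20, 30, 40])
        assert (tr.values[0] == 0).all()

    def test_overflow_raises(self):
        p = ModelParams(dimension=1, N=1, box_length=12, n_steps=500, seed=3)
        from invafront.lattice import FrontOverflowError

        with pytest.raises(FrontOverflowError):
            run_replicate(p)


def _lone_species_finals(N, n, seed0, steps=150, box=420):
    """Two-species engine with species 2 removed at t=0."""
    out = []
    for r in range(n):
        p = ModelParams(dimension=1, N=N, box_length=box, n_steps=steps,
                        species_count=2, zeta=0.0, record_every=steps,
                        seed=seed0 + r)
        sim = Simulation(p)
        sim.occ &= 1  # strip species 2 from the seed
        _rebuild_active(sim.occ, sim.active, sim.act_list, sim.act_pos,
                        sim.counts, p.dimension, p.width, p.box_length)
        _, fronts = sim.run(steps, steps)
        out.append(fronts[-1, 0])
    return np.array(out)


def _single_species_finals(N, n, seed0, steps=150, box=420):
    return np.array([
        run_replicate(ModelParams(dimension=1, N=N, box_length=box,
                                  n_steps=steps, record_every=steps,
                                  seed=seed0 + r)).values[-1]
        for r in range(n)
    ])


class TestModelReductions:
    def test_lone_species_reduces_to_strict_threshold(self):
        # two-species rule with zeta=0 and one species reads n > N, i.e. the
        # single-species model at N+1; at N=1 it must NOT match N=1 itself
        lone = _lone_species_finals(N=1, n=200, seed0=10_000)
        same = _single_species_finals(N=2, n=200, seed0=20_000)
        off = _single_species_finals(N=1, n=200, seed0=30_000)
        assert ks_2samp(lone, same).pvalue > 0.01
        assert ks_2samp(lone, off).pvalue < 0.01

    def test_species_labels_are_exchangeable(self):
        c1, c2 = [], []
        for r in range(150):
            p = ModelParams(dimension=1, N=2, box_length=200, n_steps=120,
                            species_count=2, zeta=0.5, record_every=120,
                            seed=40_000 + r)
            sim = Simulation(p)
            sim.run(120, 120)
            st = sim.state
            c1.append(st.occ1.sum())
            c2.append(st.occ2.sum())
        assert ks_2samp(c1, c2).pvalue > 0.01


class TestLatchingEquivalence:
    @pytest.mark.parametrize("zeta", [0.0, 0.5, 1.0])
    def test_occupiability_is_monotone_for_nonnegative_zeta(self, zeta):
        p = ModelParams(dimension=1, N=3, box_length=60, n_steps=1,
                        species_count=2, zeta=zeta, seed=0)
        state = init_state(p)
        rng = np.random.default_rng(9)
        z = zeta
        open_before = np.zeros(p.box_length, dtype=bool)
        for _ in range(60):
            step(state, p, rng)
            open_now = (z * state.n1 + state.n2 > p.N) | (state.n1 + z * state.n2 > p.N)
            assert np.all(open_now >= open_before)  # once open, stays open
            open_before = open_now


class TestEngineEquivalence:
    """The event-driven engine must match the literal rules distributionally."""

    @pytest.mark.parametrize("N", [2, 5])
    def test_1d_front_moments_match(self, N):
        steps, box, n = 120, 300, 500
        fast = _single_species_finals(N, n, 50_000, steps=steps, box=box)
        ref = np.array([
            run_replicate(ModelParams(dimension=1, N=N, box_length=box,
                                      n_steps=steps, record_every=steps,
                                      seed=60_000 + r),
                          engine="reference").values[-1]
            for r in range(n)
        ])
        se = np.sqrt(fast.var() / n + ref.var() / n)
        assert abs(fast.mean() - ref.mean()) <= 3 * se
        assert ks_2samp(fast, ref).pvalue > 0.001

    @pytest.mark.parametrize("N", [2, 5])
    def test_2d_front_moments_match(self, N):
        steps, box, L, n = 50, 45, 5, 500
        def finals(engine, seed0):
            out = []
            for r in range(n):
                p = ModelParams(dimension=2, N=N, L=L, box_length=box,
                                n_steps=steps, species_count=2, zeta=0.0,
                                record_every=steps, seed=seed0 + r)
                out.append(run_replicate(p, engine=engine).values[-1].mean())
            return np.array(out)
        fast = finals("fast", 70_000)
        ref = finals("reference", 80_000)
        se = np.sqrt(fast.var() / n + ref.var() / n)
        assert abs(fast.mean() - ref.mean()) <= 3 * se
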