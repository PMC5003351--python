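"""Trial-loop semantics, acceptance probabilities, and reproducibility."""

import math

import numpy as np
import pytest

import microwell_mc as mw
from microwell_mc import _kernel
from microwell_mc.engine import acceptance_table, advance_trials, make_cell_list


def _ref_splitmix64(seed, count):
    """Independent big-int reference for the kernel RNG."""
    mask = (1 << 64) - 1
    x = seed & mask
    out = []
    for _ in range(count):
        x = (x + 0x9E3779B97F4A7C15) & mask
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        out.append((z ^ (z >> 31)) & mask)
    return out


class TestRngStream:
    def test_matches_pure_python_reference(self):
        rng = mw.RngStream(42)
        assert [rng.u64() for _ in range(50)] == _ref_splitmix64(42, 50)

    def test_identical_seed_identical_sequence(self):
        a, b = mw.RngStream(7), mw.RngStream(7)
        assert [a.uniform() for _ in range(20)] == [b.uniform() for _ in range(20)]

    def test_uniform_in_half_open_unit_interval(self):
        rng = mw.RngStream(3)
        draws = [rng.uniform() for _ in range(2000)]
        assert all(0.0 < u <= 1.0 for u in draws)
        assert abs(np.mean(draws) - 0.5) < 0.03

    def test_randint_bounds_and_coverage(self):
        rng = mw.RngStream(5)
        draws = [rng.randint(6) for _ in range(1200)]
        assert set(draws) == set(range(6))

    def test_gamma_matches_sum_of_exponentials_in_mean(self):
        rng = mw.RngStream(11)
        k = 40  # exercises the Marsaglia-Tsang branch
        draws = [float(_kernel.gamma_int(rng.state, k)) for _ in range(4000)]
        assert abs(np.mean(draws) - k) / k < 0.02
        assert abs(np.var(draws) - k) / k < 0.10


class TestSeedCells:
    def test_counts_and_distinctness(self, half_well, rng):
        st = mw.seed_cells(half_well, 5, rng)
        assert st.n_cells == 5
        assert int(st.occ.sum()) == 5
        assert st.time == 0.0
        st.check_invariants(half_well)

    def test_reproducible(self, half_well):
        a = mw.seed_cells(half_well, 5, mw.RngStream(9))
        b = mw.seed_cells(half_well, 5, mw.RngStream(9))
        assert np.array_equal(a.occ, b.occ)

    def test_full_occupancy(self, tiny_box, rng):
        st = mw.seed_cells(tiny_box, tiny_box.N, rng)
        assert st.theta(tiny_box) == 1.0

    def test_rejects_bad_counts(self, tiny_box, rng):
        with pytest.raises(ValueError):
            mw.seed_cells(tiny_box, 0, rng)
        with pytest.raises(ValueError):
            mw.seed_cells(tiny_box, tiny_box.N + 1, rng)


class TestDiffusionAcceptance:
    @pytest.mark.parametrize(
        "ctx,params,expected",
        [
            ((0, 0, False), {}, 1.0),
            ((1, 0, False), {"eps_cc": -1.2}, math.exp(-1.2)),
            ((2, 1, False), {"eps_cc": -1.2, "eps_cs": -1.2}, math.exp(-3.6)),
            ((0, 0, True), {"eps_g": -0.03}, math.exp(-0.03)),
            ((3, 2, True), {"eps_cc": -1.0, "eps_cs": -0.5, "eps_g": -0.1},
             math.exp(-4.1)),
        ],
    )
    def test_closed_form(self, ctx, params, expected):
        p = mw.SimParams(**params)
        got = mw.diffusion_acceptance(mw.MoveContext(*ctx), p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 < got <= 1.0

    def test_table_matches_function(self):
        p = mw.SimParams(eps_cc=-1.2, eps_cs=-0.7, eps_g=-0.03)
        acc = acceptance_table(p)
        for n in range(7):
            for m in range(7 - n):
                for up in (False, True):
                    assert acc[n, m, int(up)] == pytest.approx(
                        mw.diffusion_acceptance(mw.MoveContext(n, m, up), p)
                    )


class TestAdvanceTime:
    def test_positive_and_mean_one_over_n(self, tiny_box):
        rng = mw.RngStream(21)
        incs = [mw.advance_time(tiny_box, rng) for _ in range(20000)]
        assert all(i >= 0 for i in incs)
        # E|ln rho| = 1 for rho uniform on (0, 1]: mean increment is 1/N.
        assert np.mean(incs) == pytest.approx(1 / tiny_box.N, rel=0.05)


class TestMcTrial:
    def test_vacant_site_is_noop_with_time_advance(self, tiny_box):
        rng = mw.RngStream(2)
        st = mw.seed_cells(tiny_box, 1, rng)
        before = st.occ.copy()
        outcomes = set()
        t_prev = st.time
        for _ in range(50):
            out = mw.mc_trial(st, tiny_box, mw.SimParams(p_div=0.0), rng)
            outcomes.add(out)
            assert st.time > t_prev  # time advances on every trial
            t_prev = st.time
        assert mw.Outcome.NOOP in outcomes
        assert int(st.occ.sum()) == 1
        assert st.trials == 50

    def test_pdiv_one_never_diffuses(self, tiny_box):
        # With p_div = 1 every occupied-site trial attempts a division, so
        # cells never move: the original seed site stays occupied forever.
        rng = mw.RngStream(3)
        st = mw.seed_cells(tiny_box, 1, rng)
        seed_site = tuple(np.argwhere(st.occ)[0])
        p = mw.SimParams(p_div=1.0)
        for _ in range(600):
            mw.mc_trial(st, tiny_box, p, rng)
        assert st.occ[seed_site] == 1
        assert st.n_cells > 1  # divisions did happen
        st.check_invariants(tiny_box)

    def test_full_lattice_everything_rejected(self, tiny_box):
        rng = mw.RngStream(4)
        st = mw.seed_cells(tiny_box, tiny_box.N, rng)
        p = mw.SimParams(p_div=0.5)
        outs = {mw.mc_trial(st, tiny_box, p, rng) for _ in range(200)}
        assert outs <= {mw.Outcome.REJECTED}
        assert st.n_cells == tiny_box.N

    def test_conservation_and_containment(self, half_well):
        rng = mw.RngStream(6)
        st = mw.seed_cells(half_well, 20, rng)
        p = mw.SimParams(p_div=0.05, eps_cc=-1.2)
        n_prev = st.n_cells
        for _ in range(3000):
            out = mw.mc_trial(st, half_well, p, rng)
            if out == mw.Outcome.DIVIDED:
                assert st.n_cells == n_prev + 1
            else:
                assert st.n_cells == n_prev
            n_prev = st.n_cells
        st.check_invariants(half_well)


class TestRunUntilOccupancy:
    def test_immediate_return_at_seed_occupancy(self, tiny_box):
        N = tiny_box.N
        p = mw.SimParams(n_seed=10, theta_stop=10 / N,
                         snapshot_thetas=(10 / N,), rng_seed=1)
        trace, snaps = mw.run_until_occupancy(tiny_box, p)
        assert len(snaps) == 1
        assert snaps[0].n_cells == 10
        assert snaps[0].time == 0.0
        assert trace.n_cells[-1] == 10

    def test_theta_series_nondecreasing(self, tiny_box):
        p = mw.SimParams(p_div=0.2, n_seed=2, theta_stop=0.5,
                         snapshot_thetas=(0.25, 0.5), rng_seed=5)
        trace, snaps = mw.run_until_occupancy(tiny_box, p)
        assert (np.diff(trace.n_cells) >= 0).all()
        assert (np.diff(trace.time) >= 0).all()

    def test_snapshot_cell_counts_match_thresholds(self, tiny_box):
        N = tiny_box.N
        p = mw.SimParams(p_div=0.2, n_seed=2, theta_stop=0.4,
                         snapshot_thetas=(0.2, 0.4), rng_seed=5)
        _, snaps = mw.run_until_occupancy(tiny_box, p)
        assert [s.n_cells for s in snaps] == [
            int(np.ceil(0.2 * N - 1e-9)), int(np.ceil(0.4 * N - 1e-9))
        ]

    def test_bit_identical_reproducibility(self, tiny_box):
        p = mw.SimParams(p_div=0.1, n_seed=3, theta_stop=0.3,
                         snapshot_thetas=(0.3,), rng_seed=77)
        t1, s1 = mw.run_until_occupancy(tiny_box, p)
        t2, s2 = mw.run_until_occupancy(tiny_box, p)
        assert np.array_equal(t1.time, t2.time)
        assert np.array_equal(t1.n_cells, t2.n_cells)
        assert np.array_equal(s1[0].coords, s2[0].coords)
        assert s1[0].time == s2[0].time

    def test_trial_budget_guard_warns(self, tiny_box):
        p = mw.SimParams(p_div=0.0, n_seed=2, theta_stop=0.5,
                         snapshot_thetas=(0.5,), rng_seed=1)
        with pytest.warns(RuntimeWarning, match="budget"):
            trace, snaps = mw.run_until_occupancy(tiny_box, p,
                                                  max_trials=5000)
        assert snaps == []
        assert trace.n_cells[-1] == 2


class TestDriverEquivalence:
    """The literal per-trial loop and the event-driven loop are the same
    stochastic process; their ensemble statistics must agree."""

    def test_growth_and_clock_statistics_agree(self, tiny_box):
        p = mw.SimParams(p_div=0.05, eps_cc=-1.2, n_seed=3,
                         theta_stop=1.0, snapshot_thetas=(1.0,))
        acc = acceptance_table(p)
        n_trials, n_reps = 4000, 120
        finals = {"literal": [], "events": []}
        times = {"literal": [], "events": []}
        rec = (np.zeros(1), np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64))
        for rep in range(n_reps):
            for kind in ("literal", "events"):
                rng = mw.RngStream(1000 + rep if kind == "literal" else 5000 + rep)
                st = mw.seed_cells(tiny_box, 3, rng)
                if kind == "literal":
                    _kernel.run_chunk(
                        st.occ, tiny_box.mask, tiny_box.wall_m, tiny_box.sites,
                        tiny_box.periodic, p.p_div, acc, rng.state,
                        st.time_box, st.counters, 2**62, n_trials, 2**62,
                        *rec,
                    )
                else:
                    advance_trials(st, tiny_box, p, rng, n_trials)
                st.check_invariants(tiny_box)
                assert st.trials == n_trials
                finals[kind].append(st.n_cells)
                times[kind].append(st.time)
        # Means agree within a few combined standard errors.
        for stat in (finals, times):
            a, b = np.array(stat["literal"]), np.array(stat["events"])
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 4 * se + 1e-9
        # The clock averages ~1 MCS per N trials in both drivers.
        expected_t = n_trials / tiny_box.N
        for v in times.values():
            assert np.mean(v) == pytest.approx(expected_t, rel=0.05)
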