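"""Stochastic lattice: rates, bookkeeping, statistics, FRAP."""

import numpy as np
import pytest
from ampar_trafficking import (CoopParams, GridState, TraffickingParams,
                               run_lattice, simulate_frap, slot_rates,
                               step_stochastic)
from ampar_trafficking.lattice import neighbour_fraction, scan_conditional_rates


@pytest.fixture()
def coop():
    return CoopParams(seed=7)


class TestSlotRates:
    def test_isolated_slots_have_basal_rates(self, coop):
        grid = GridState.empty(6)
        grid.occ[2, 2] = 1
        k_ub, k_bu = slot_rates(grid, coop)
        assert k_bu[2, 2] == pytest.approx(coop.k_BU)       # no neighbours
        assert k_ub[0, 0] == pytest.approx(coop.k_UB)

    def test_full_neighbourhood(self, coop):
        grid = GridState.empty(5)
        grid.occ[1:4, 1:4] = 1
        grid.occ[2, 2] = 0
        k_ub, k_bu = slot_rates(grid, coop)
        # chi = 1 at the hole: binding 17x basal (alpha=16), and an interior
        # occupied slot of a full block cannot unbind
        assert k_ub[2, 2] == pytest.approx(coop.k_UB * 17.0)
        assert k_ub[2, 2] == pytest.approx(0.0085, abs=1e-6)
        grid.occ[2, 2] = 1
        _, k_bu = slot_rates(grid, coop)
        assert k_bu[2, 2] == pytest.approx(0.0)

    def test_edge_slots_keep_denominator_eight(self, coop):
        grid = GridState.empty(4)
        grid.occ[:, :] = 1
        grid.occ[0, 0] = 0
        chi = neighbour_fraction(grid.occ)
        assert chi[0, 0] == pytest.approx(3 / 8)   # corner: 3 of 8 occupied


class TestStepping:
    def test_empty_system_stays_empty(self, coop, base_params):
        grid = GridState.empty(6)
        rng = np.random.default_rng(0)
        U = step_stochastic(grid, 0.0, coop, base_params, 0.2, rng,
                            k_in=0.0)
        assert grid.B == 0
        assert U == 0.0

    def test_probability_overflow_raises(self, coop, base_params):
        grid = GridState.empty(6)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="smaller dt"):
            step_stochastic(grid, 1e6, coop, base_params, 0.5, rng)

    def test_event_bookkeeping_is_exact(self, coop, base_params):
        rng = np.random.default_rng(3)
        grid = GridState.empty(8)
        U = 10.0
        for _ in range(4000):
            U = step_stochastic(grid, U, coop, base_params, 0.2, rng)
        assert grid.bind_events.sum() - grid.unbind_events.sum() == grid.B

    def test_seed_reproducibility(self, coop, base_params):
        runs = [run_lattice(8, coop, base_params, T=200.0, seed=42)
                for _ in range(2)]
        assert np.array_equal(runs[0].B, runs[1].B)
        assert np.array_equal(runs[0].U, runs[1].U)

    def test_dt_halving_leaves_stationary_mean_unchanged(self, base_params):
        means = {}
        for dt in (0.4, 0.2):
            vals = []
            for seed in range(4):
                run = run_lattice(8, CoopParams(dt=dt), base_params,
                                  T=1200.0, burn=400.0, seed=seed,
                                  clamp_conc=10.0)
                vals.append(run.B.mean())
            means[dt] = (np.mean(vals), np.std(vals) / np.sqrt(len(vals)))
        diff = abs(means[0.4][0] - means[0.2][0])
        sem = np.hypot(means[0.4][1], means[0.2][1])
        assert diff < 4.0 * sem + 1.0


class TestOccupancyStatistics:
    def test_independent_slots_are_binomial(self, base_params):
        # alpha = 0: stationary occupancy of each slot is an independent
        # two-state process, so B ~ Binomial(P, p)
        cp = CoopParams(alpha=0.0, dt=0.2)
        conc = 40.0
        p_occ = conc * cp.k_UB / (conc * cp.k_UB + cp.k_BU)
        run = run_lattice(8, cp, base_params, T=4000.0, burn=500.0, seed=5,
                          clamp_conc=conc)
        P = 64
        assert run.B.mean() == pytest.approx(P * p_occ, rel=0.08)
        cv_binom = np.sqrt((1 - p_occ) / (P * p_occ))
        cv = run.B.std() / run.B.mean()
        assert cv == pytest.approx(cv_binom, rel=0.25)

    def test_cooperative_cv_exceeds_binomial(self, coop, base_params):
        run = run_lattice(8, coop, base_params, T=3000.0, burn=800.0,
                          seed=11, clamp_conc=9.0)
        mean = run.B.mean()
        occ = mean / 64
        assert 0.1 < occ < 0.9          # mid-range occupancy
        cv = run.B.std() / mean
        cv_binom = np.sqrt((1 - occ) / (64 * occ))
        assert cv > 1.5 * cv_binom

    def test_conditional_rates_monotone_in_occupancy(self, coop):
        rec = {}
        rng = np.random.default_rng(9)
        for conc in (4.0, 8.0, 12.0, 20.0):
            scan_conditional_rates(8, conc, coop, T=800.0, rng=rng,
                                   record=rec)
        Bs = np.array(sorted(rec))
        ok = np.array([rec[b][0] for b in Bs]) >= 20
        rBU = np.array([rec[b][1] / rec[b][0] for b in Bs])[ok]
        rUB = np.array([rec[b][2] / rec[b][0] for b in Bs])[ok]
        # pooled trend over coarse occupancy bins
        idx = np.linspace(0, ok.sum() - 1, 5).astype(int)
        assert np.all(np.diff(rUB[idx]) > 0)    # binding grows with B
        assert np.all(np.diff(rBU[idx]) < 0)    # unbinding falls with B

    def test_dwell_times_span_an_order_of_magnitude(self, base_params):
        run = run_lattice(10, CoopParams(dt=0.2), base_params, T=3600.0,
                          seed=13, clamp_conc=20.0)
        assert run.B.mean() / 100 > 0.5         # high occupancy
        dwell = run.grid.mean_dwell_map()
        visited = dwell[run.grid.bind_events > 0]
        assert visited.max() / max(visited.min(), 1e-9) >= 10.0


class TestFRAP:
    def test_recovery_starts_at_zero_and_rises(self):
        df = simulate_frap(9, 11.2, CoopParams(dt=0.2), bleach_time=240.0,
                           t_end=540.0, trials=10, seed=2)
        post = df[df.t_s > 0]
        assert post.frac_unbleached.iloc[0] < 0.1
        assert post.frac_unbleached.iloc[-1] > post.frac_unbleached.iloc[0]

    def test_cooperative_recovery_slows_at_high_concentration(self):
        cp = CoopParams(dt=0.2)
        lo = simulate_frap(9, 11.2, cp, bleach_time=300.0, t_end=720.0,
                           trials=25, seed=3)
        hi = simulate_frap(9, 33.4, cp, bleach_time=300.0, t_end=720.0,
                           trials=25, seed=3)
        t_probe = 300.0
        f_lo = np.interp(t_probe, lo.t_s, lo.frac_unbleached)
        f_hi = np.interp(t_probe, hi.t_s, hi.frac_unbleached)
        assert f_hi < f_lo - 0.1

    def test_independent_model_recovery_concentration_invariant(self):
        cp = CoopParams(alpha=0.0, dt=0.2)
        lo = simulate_frap(9, 11.2, cp, bleach_time=300.0, t_end=720.0,
                           trials=25, seed=4)
        hi = simulate_frap(9, 33.4, cp, bleach_time=300.0, t_end=720.0,
                           trials=25, seed=4)
        t_probe = 300.0
        f_lo = np.interp(t_probe, lo.t_s, lo.frac_unbleached)
        f_hi = np.interp(t_probe, hi.t_s, hi.frac_unbleached)
        assert abs(f_hi - f_lo) < 0.1

    def test_early_bleach_warns(self):
        with pytest.warns(RuntimeWarning, match="equilibration"):
            simulate_frap(6, 11.2, CoopParams(dt=0.2), bleach_time=60.0,
                          t_end=120.0, trials=2, seed=5)


class TestLatticeStatistics:
    def test_full_grid_unbinding_matches_combinatorial_oracle(self, coop,
                                                              base_params):
        # frozen fully-occupied N x N grid: exhaustive neighbour counting
        # gives the mean unbinding rate exactly
        from ampar_trafficking import lattice_statistics
        N = 6
        grid = GridState(occ=np.ones((N, N), dtype=np.int8))
        _, k_bu = slot_rates(grid, coop)
        interior = (N - 2) ** 2          # chi = 1, rate 0
        edges = 4 * (N - 2)              # 5 of 8 neighbours occupied
        corners = 4                      # 3 of 8 neighbours occupied
        oracle = coop.k_BU * (edges * 3 / 8 + corners * 5 / 8) / N ** 2
        assert k_bu.mean() == pytest.approx(oracle, rel=1e-12)
        assert interior + edges + corners == N ** 2

    def test_single_receptor_unbinds_at_basal_rate(self, coop):
        grid = GridState.empty(7)
        grid.occ[3, 3] = 1
        _, k_bu = slot_rates(grid, coop)
        assert k_bu[3, 3] == pytest.approx(coop.k_BU, rel=1e-12)

    def test_stats_summarise_stationary_run(self, coop, base_params):
        from ampar_trafficking import lattice_statistics
        run = run_lattice(6, coop, base_params, T=800.0, burn=200.0, seed=1,
                          clamp_conc=10.0)
        stats = lattice_statistics(run, coop)
        assert stats.P == 36
        assert stats.mean_B == pytest.approx(run.B.mean())
        assert 0.0 < stats.occupancy < 1.0
        assert stats.cv_B > 0
        assert stats.dwell_map.shape == (6, 6)
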