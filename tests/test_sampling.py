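"""Cost function and random parameter sampling."""

import numpy as np
import pytest

from ampar_trafficking import (DEFAULT_REFERENCE, SampleRange,
                               TraffickingParams, cost, run_sampling,
                               simulate)
from ampar_trafficking.reference import to_receptor_counts


class TestCost:
    def test_identical_curves_cost_nothing(self):
        t = np.arange(0.0, 100.0, 1.0)
        a = (t, np.sin(t / 10.0) + 2.0)
        b = (t, np.cos(t / 7.0) + 2.0)
        assert cost(a, b, a, b) == 0.0

    def test_unit_offset_in_both_conditions_costs_two(self):
        t = np.arange(0.0, 100.0, 1.0)
        ref1 = (t, np.sin(t / 10.0) + 5.0)
        ref2 = (t, np.cos(t / 7.0) + 5.0)
        sim1 = (t, ref1[1] + 1.0)
        sim2 = (t, ref2[1] + 1.0)
        assert cost(sim1, sim2, ref1, ref2) == pytest.approx(2.0, rel=1e-12)

    def test_matches_fine_riemann_oracle(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 50.0, 2001)
        f = np.cumsum(rng.normal(size=t.size)) * 0.01 + 3.0
        g = np.cumsum(rng.normal(size=t.size)) * 0.01 + 3.0
        # fine-grid Riemann sum of |f - g| / T on midpoints
        mid = 0.5 * (np.abs(f - g)[1:] + np.abs(f - g)[:-1])
        oracle = np.sum(mid * np.diff(t)) / (t[-1] - t[0])
        got = cost((t, f), (t, np.zeros_like(t) + 3.0),
                   (t, g), (t, np.zeros_like(t) + 3.0))
        first = oracle
        second = np.trapezoid(np.abs(np.zeros_like(t)), t)
        assert got == pytest.approx(first + second, rel=1e-9)

    def test_grid_mismatch_is_resampled(self):
        t1 = np.linspace(0.0, 100.0, 201)
        t2 = np.linspace(0.0, 100.0, 101)
        flat = lambda t: np.full_like(t, 7.0)
        c = cost((t1, flat(t1)), (t1, flat(t1)),
                 (t2, flat(t2)), (t2, flat(t2)))
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_refinement_invariance(self):
        c = DEFAULT_REFERENCE["E-LTP"]
        t1, v1 = c.grid(dt=10.0)
        t2, v2 = c.grid(dt=5.0)
        sim1 = (t1, v1 * 0.9)
        sim2 = (t2, v2 * 0.9)
        zero = (t1, v1)
        zero2 = (t2, v2)
        c1 = cost(sim1, zero, (t1, v1), (t1, v1))
        c2 = cost(sim2, zero2, (t2, v2), (t2, v2))
        assert abs(c1 - c2) / c1 < 1e-3


class TestRunSampling:
    def test_top_fraction_arithmetic(self):
        res = run_sampling("coop", n_trials=40, top_frac=0.1, seed=3, dt=0.5)
        assert len(res.top) == 4
        assert res.trials.cost.is_monotonic_increasing

    def test_seed_reproducibility(self):
        a = run_sampling("coop", n_trials=30, top_frac=0.1, seed=9, dt=0.5)
        b = run_sampling("coop", n_trials=30, top_frac=0.1, seed=9, dt=0.5)
        assert np.array_equal(a.trials.cost.to_numpy(),
                              b.trials.cost.to_numpy())
        assert (a.trials.k_BU.to_numpy() == b.trials.k_BU.to_numpy()).all()

    def test_collapsed_ranges_equal_direct_simulation(self, base_params):
        # point ranges at the table values: the sampled trial must score
        # exactly like a direct simulation of the same model
        ranges = [
            SampleRange("k_exo0", 0.0018, 0.0018),
            SampleRange("tau_exo2", 60.0, 60.0),
            SampleRange("A_exo", 5.0, 5.0),
            SampleRange("k_BU", 0.1, 0.1),
            SampleRange("tau_UB2", 60.0, 60.0),
            SampleRange("A_UB", 30.0, 30.0),
        ]
        res = run_sampling("basic", n_trials=2, top_frac=0.5, seed=0,
                           ranges=ranges, dt=0.5)
        direct_cost = 0.0
        for key, proto in (("E-LTP", "ltp"), ("k_exo=0", "ltp-noexo")):
            ref = DEFAULT_REFERENCE[key]
            traj = simulate("basic", proto, base_params, t_end=ref.T, dt=0.05,
                            thin=200)
            ref_B = to_receptor_counts(ref.value(traj.t), base_params.B_star)
            T = traj.t[-1] - traj.t[0]
            direct_cost += np.trapezoid(np.abs(traj.B - ref_B), traj.t) / T
        assert res.trials.cost.iloc[0] == pytest.approx(direct_cost, rel=5e-3)

    def test_planted_truth_is_recovered(self):
        # reference curves generated by one known parameter set: that draw
        # must beat perturbed draws
        truth = dict(k_exo0=0.004, tau_exo2=120.0, A_exo=6.0, k_BU=0.15,
                     tau_UB2=90.0, A_UB=20.0)

        class _Ref:
            def __init__(self, traj, T):
                self.T = T
                self._t, self._v = traj

            def value(self, t):
                return np.interp(t, self._t, self._v)

        from ampar_trafficking.params import InductionParams
        p = TraffickingParams(k_exo0=truth["k_exo0"], k_BU=truth["k_BU"])
        ind = InductionParams(A_exo=truth["A_exo"],
                              tau_exo2=truth["tau_exo2"],
                              A_UB=truth["A_UB"], tau_UB2=truth["tau_UB2"])
        refs = {}
        for key, proto, T in (("E-LTP", "ltp", 3600.0),
                              ("k_exo=0", "ltp-noexo", 1800.0)):
            traj = simulate("basic", proto, p, t_end=T, dt=0.05, thin=200,
                            induction=ind)
            refs[key] = _Ref((traj.t, 100.0 * traj.B / p.B_star), T)

        def point_ranges(d):
            return [SampleRange(k, v, v) for k, v in d.items()]

        exact = run_sampling("basic", n_trials=1, top_frac=1.0, seed=0,
                             ranges=point_ranges(truth), references=refs,
                             dt=0.5)
        perturbed = dict(truth, A_UB=truth["A_UB"] * 1.5,
                         k_BU=truth["k_BU"] * 1.4)
        other = run_sampling("basic", n_trials=1, top_frac=1.0, seed=0,
                             ranges=point_ranges(perturbed), references=refs,
                             dt=0.5)
        assert exact.trials.cost.iloc[0] < 0.1
        assert exact.trials.cost.iloc[0] < other.trials.cost.iloc[0]

    def test_rejected_trials_are_flagged_not_ranked(self):
        # force invalid draws: decay faster than the fixed rise time
        ranges = [
            SampleRange("k_exo0", 0.0, 0.0),      # k_endo < 0 for k_exo0 = 0
            SampleRange("tau_exo2", 1.0, 1.0),    # below tau_exo1 = 25 s
            SampleRange("A_exo", 1.0, 1.0),
            SampleRange("k_BU", 0.1, 0.1),
            SampleRange("tau_UB2", 60.0, 60.0),
            SampleRange("A_UB", 5.0, 5.0),
        ]
        res = run_sampling("basic", n_trials=3, top_frac=0.5, seed=0,
                           ranges=ranges, dt=0.5)
        assert res.n_rejected == 3
        assert np.all(np.isinf(res.trials.cost))

    def test_summaries_cover_required_observables(self):
        res = run_sampling("coop", n_trials=20, top_frac=0.2, seed=5, dt=0.5)
        for key in ("E-LTP", "k_exo=0"):
            cols = set(res.summaries[key].columns)
            assert {"B_pct_mean", "B_pct_sd", "U_conc_pct_mean",
                    "k_exo_rel_mean", "k_UB_rel_mean"} <= cols
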