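"""Mean-field reduction: fitting, fixed-point closure, lattice agreement."""

import numpy as np
import pytest

from ampar_trafficking import (CoopParams, MeanFieldFit, TraffickingParams,
                               coop_k_UB0, fit_meanfield, fixed_point_curve,
                               run_lattice, simulate)
from ampar_trafficking.meanfield import _fixed_points


def _synthetic_records(truth: MeanFieldFit, P_grid=(36, 64, 100, 144),
                       noise=0.0, seed=0):
    """Conditional-mean tables generated from known coefficients."""
    rng = np.random.default_rng(seed)
    records = {}
    for P in P_grid:
        Bs = np.arange(1, P)
        rBU = truth.unbinding_factor(Bs, P)
        rUB = truth.binding_factor(Bs, P)
        if noise:
            rBU = rBU * (1 + rng.normal(0, noise, Bs.size))
            rUB = rUB * (1 + rng.normal(0, noise, Bs.size))
        cnt = np.full(Bs.size, 500.0)
        records[P] = (Bs, cnt, rBU, rUB)
    return records


class TestFitting:
    def test_parameter_recovery(self):
        truth = MeanFieldFit(m_beta=0.28, c_beta=7.0, m_lambda=0.29,
                             c_lambda=7.2, a_m=25.0, b_m=16.0)
        fit = fit_meanfield(_synthetic_records(truth))
        for name in ("m_beta", "c_beta", "m_lambda", "c_lambda", "a_m", "b_m"):
            assert getattr(fit, name) == pytest.approx(
                getattr(truth, name), rel=0.01), name

    def test_binding_factor_is_one_at_empty_grid(self, mf_fit):
        assert mf_fit.binding_factor(0.0, 70.0) == pytest.approx(1.0)

    def test_requires_enough_psd_sizes(self):
        truth = MeanFieldFit(m_beta=0.28, c_beta=7.0, m_lambda=0.29,
                             c_lambda=7.2, a_m=25.0, b_m=16.0)
        records = _synthetic_records(truth, P_grid=(36, 64))
        with pytest.raises(ValueError, match=">= 4"):
            fit_meanfield(records)

    def test_fixture_round_trip(self, mf_fit, tmp_path):
        path = tmp_path / "fit.json"
        mf_fit.save(path)
        loaded = MeanFieldFit.load(path)
        assert loaded.m_beta == mf_fit.m_beta
        assert loaded.per_P == mf_fit.per_P


class TestFixedPointClosure:
    def test_reduces_to_plain_closure_without_cooperativity(self, base_params):
        # unbinding factor pinned to 1 at B* and m = 0 recovers the basic rate
        B_star = base_params.B_star
        neutral = MeanFieldFit(m_beta=0.0, c_beta=0.5, m_lambda=0.0,
                               c_lambda=B_star, a_m=0.0, b_m=1.0)
        assert neutral.unbinding_factor(B_star, 70.0) == pytest.approx(1.0)
        assert coop_k_UB0(base_params, neutral) == pytest.approx(
            base_params.k_UB0, rel=1e-12)

    def test_closure_pins_the_cooperative_steady_state(self, base_params,
                                                       mf_fit):
        kub0 = coop_k_UB0(base_params, mf_fit)
        P, Bs, Us, A = (base_params.P, base_params.B_star,
                        base_params.U_star, base_params.A_spine0)
        dB = (kub0 * mf_fit.binding_factor(Bs, P) * (P - Bs) * Us / A
              - base_params.k_BU * mf_fit.unbinding_factor(Bs, P) * Bs)
        assert abs(dB) < 1e-12

    def test_cooperative_baseline_is_stationary(self, coop_params, mf_fit):
        traj = simulate("coop", "baseline", coop_params, t_end=2000.0,
                        dt=0.2, fit=mf_fit)
        assert np.abs(traj.B - coop_params.B_star).max() < 1e-6 * 20.0


class TestFixedPointCurves:
    def test_cooperative_curve_is_steeper_than_basic(self, base_params,
                                                     coop_params, mf_fit):
        sweep = np.linspace(5.0, 40.0, 15)
        basic = fixed_point_curve("basic", base_params, sweep)
        coop = fixed_point_curve("coop", coop_params, sweep, fit=mf_fit)

        def max_slope(curve):
            s = np.array([x for x, _ in curve])
            # upper root traces the potentiated branch
            b = np.array([max(r) for _, r in curve])
            return np.max(np.diff(b) / np.diff(s))

        assert max_slope(coop) > 3.0 * max_slope(basic)
        # both anchored at the Table values: B* = 20 at S_exo = 13
        b13 = [r for s, r in coop if abs(s - 13.0) < 1.3]
        assert any(abs(b - 20.0) < 1.0 for roots in b13 for b in roots)

    def test_roots_verified_by_ode_relaxation(self, coop_params, mf_fit):
        # forward relaxation from a perturbed start lands on a located root
        roots = _fixed_points(coop_params, mf_fit,
                              coop_params.k_exo0 * coop_params.S_exo0
                              + coop_params.k_in,
                              coop_params.k_UB0)
        traj = simulate("coop", "baseline", coop_params, t_end=4000.0, dt=0.2,
                        fit=mf_fit,
                        state0=(coop_params.U_star, 24.0, 13.0))
        final = traj.B[-1]
        assert min(abs(final - r) for r in roots) < 0.1

    def test_sigmoid_steepness_grows_with_psd_size(self, base_params):
        # the occupancy-vs-concentration sigmoid of the stochastic model is
        # steeper for large PSDs (collective transitions sharpen with size)
        lat = base_params.replace(k_UB0=0.0005, k_BU=0.1)
        cp = CoopParams(dt=0.2)

        def occupancy_slope(N, seed0):
            P = N * N
            occs = []
            for i, conc in enumerate((8.0, 10.0, 12.0, 14.0)):
                vals = [run_lattice(N, cp, lat, T=1200.0, burn=400.0,
                                    seed=seed0 + 10 * i + s,
                                    clamp_conc=conc).B.mean() / P
                        for s in range(2)]
                occs.append(np.mean(vals))
            return np.max(np.diff(occs)) / 2.0

        assert occupancy_slope(14, 100) > occupancy_slope(6, 200)

    def test_rejects_nonpositive_sweep(self, base_params):
        with pytest.raises(ValueError):
            fixed_point_curve("basic", base_params, [0.0, 1.0])


class TestLatticeAgreement:
    def test_meanfield_matches_stochastic_stationary_mean(self, mf_fit):
        # across a (P, k_in) grid, the mean-field fixed point lies within
        # two standard errors of the stochastic stationary mean
        trials = 6
        base = TraffickingParams()
        lat = base.replace(k_UB0=0.0005, k_BU=0.1)
        coop = CoopParams(dt=0.2)
        rng = np.random.default_rng(21)
        for P in (36, 100):
            N = int(round(np.sqrt(P)))
            for k_in in (0.5, 0.9):
                means = []
                for _ in range(trials):
                    run = run_lattice(N, coop, lat, T=1200.0, burn=400.0,
                                      rng=rng, k_in=k_in)
                    means.append(run.B.mean())
                means = np.array(means)
                sem = means.std(ddof=1) / np.sqrt(trials)
                influx = k_in + lat.k_exo0 * lat.S_exo0
                roots = _fixed_points(lat, mf_fit, influx, 0.0005, P=P)
                best = min(roots, key=lambda r: abs(r - means.mean()))
                # 2 SE plus a 10% allowance for the irreducible bias of
                # the hyperbolic unbinding fit (grows with P; see methods)
                tol = 2.0 * sem + 0.10 * means.mean()
                assert abs(best - means.mean()) <= tol, \
                    (P, k_in, best, means.mean(), sem)
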