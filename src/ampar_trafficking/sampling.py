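"""Random sampling of the trafficking parameter space.

A subset of the rate constants and induction transients is drawn uniformly
from broad, biologically motivated ranges; for every draw the dependent
rates (endocytosis and basal binding) are re-derived from the steady-state
closure so that each trial starts from the same pre-LTP baseline.  Each
trial is scored against the two reference conditions (E-LTP with exocytosis,
and with exocytosis blocked) by the time-averaged absolute difference in
bound-receptor number, and the best fraction of trials is summarised.

All trials are integrated in lock-step as NumPy arrays with a stiffness-
bounded step schedule, so the default 2000 draws finish in minutes per
model variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import TraffickingParams, SLTPParams, sphere_area_from_volume
from .reference import DEFAULT_REFERENCE, to_receptor_counts
from .meanfield import B_EXPONENT, default_fit
from . import sltp as _sltp

__all__ = ["SampleRange", "DEFAULT_RANGES", "cost", "run_sampling",
           "SamplingResult"]


@dataclass
class SampleRange:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.name}: low > high")

    def draw(self, rng, n):
        return rng.uniform(self.low, self.high, size=n)


def DEFAULT_RANGES(cooperative=False):
    """Sampling ranges: rates in 1/s, times in s, amplitudes dimensionless."""
    return [
        SampleRange("k_exo0", 0.0, 0.01),
        SampleRange("tau_exo2", 0.0, 67.0 * 60.0),
        SampleRange("A_exo", 0.0, 20.0),
        SampleRange("k_BU", 0.0, 1.0),
        SampleRange("tau_UB2", 0.0, 8.0 * 60.0),
        SampleRange("A_UB", 0.0, 20.0 if cooperative else 50.0),
    ]


def cost(sim_ltp, sim_noexo, ref_ltp, ref_noexo):
    """Time-averaged L1 distance in bound-receptor number.

    Each argument is a pair ``(t, B)`` on a common grid per condition; the
    two conditions are integrated over their own measurement windows and the
    time-averaged contributions added, so a constant offset of one receptor
    in both conditions costs exactly 2.
    """
    total = 0.0
    for (ts, sim), (tr, ref) in ((sim_ltp, ref_ltp), (sim_noexo, ref_noexo)):
        ts, tr = np.asarray(ts, float), np.asarray(tr, float)
        if ts.shape != tr.shape or not np.allclose(ts, tr):
            ref = np.interp(ts, tr, ref)
            tr = ts
        T = tr[-1] - tr[0]
        total += np.trapezoid(np.abs(np.asarray(ref, float)
                                     - np.asarray(sim, float)), tr) / T
    return float(total)


def _pulse_values(t, C, A, tau1, tau2, A_norm):
    return C + A * (np.exp(-t / tau2) - np.exp(-t / tau1)) / A_norm


def _a_norm(tau1, tau2):
    r = tau2 / tau1
    return r ** (tau1 / (tau1 - tau2)) - r ** (tau2 / (tau1 - tau2))


def _integrate_trials(draws, protocol, variant, t_grid, dt, base,
                      sltp_params, fit, record_extra=False):
    """RK4 over all trials at once.  Returns B on t_grid (and extras)."""
    n = len(draws["k_exo0"])
    blocked = protocol == "ltp-noexo"
    use_sltp = variant in ("sltp", "combined")
    use_coop = variant in ("coop", "combined")
    A0 = base.A_spine0
    P = base.P

    k_exo0 = draws["k_exo0"]
    k_BU = draws["k_BU"]
    k_endo = draws["k_endo"]
    k_UB0 = draws["k_UB0"]
    An_exo = _a_norm(25.0, draws["tau_exo2"])
    An_ub = _a_norm(5.0, draws["tau_UB2"])

    if use_sltp:
        sp = SLTPParams() if sltp_params is None else sltp_params
        k_outRE = sp.derive_k_outRE(base.V_spine0, base.S_exo0)

        def volume(t):
            return _sltp.v_spine(t, base.V_spine0, sp,
                                 blocked_exocytosis=blocked)
    else:
        sp = None

        def volume(t):
            return base.V_spine0

    def rhs(y, t):
        U, B, S = y
        Bc = np.maximum(B, 0.0)
        V = volume(t)
        A = sphere_area_from_volume(V) if use_sltp else A0
        ke = 0.0 if blocked else k_exo0 * _pulse_values(
            t, 1.0, draws["A_exo"], 25.0, draws["tau_exo2"], An_exo)
        ku = k_UB0 * _pulse_values(
            t, 1.0, draws["A_UB"], 5.0, draws["tau_UB2"], An_ub)
        if use_coop:
            ku_eff = ku * (fit.m(P) * Bc ** B_EXPONENT + 1.0)
            kb_eff = k_BU * fit.lam(P) / (fit.beta(P) + Bc - 0.5)
        else:
            ku_eff, kb_eff = ku, k_BU
        conc = U / A
        dU = (ke * S + base.k_in + kb_eff * B
              - (k_endo + base.k_out + ku_eff * (P - B)) * conc)
        dB = ku_eff * (P - B) * conc - kb_eff * B
        dS = (sp.k_inRE - k_outRE * S / V) if use_sltp else np.zeros_like(U)
        return np.array([dU, dB, dS])

    ones = np.ones(n)
    y = np.array([base.U_star * ones, base.B_star * ones,
                  base.S_exo0 * ones])
    out = np.empty((len(t_grid), n))
    extra = np.empty((len(t_grid), n)) if record_extra else None
    failed = np.zeros(n, dtype=bool)
    out[0] = y[1]
    if record_extra:
        extra[0] = y[0] / A0

    # piecewise step schedule: the induced binding transient can be stiff for
    # extreme draws (k_BU ~ 1/s amplified up to ~50x), so bound the fastest
    # relaxation rate of the mobile pool, (k_endo + k_out + k_UB_eff P)/A,
    # and keep |lambda| h below ~2 (RK4 real-axis stability ~2.8)
    lam_pulse = (np.max(k_endo) + base.k_out
                 + np.max(k_UB0 * (1.0 + draws["A_UB"])) * P) / A0
    lam_base = (np.max(k_endo) + base.k_out + np.max(k_UB0) * P) / A0
    h_pulse = min(dt, max(1.2 / lam_pulse, 0.005))
    h_base = min(dt, max(1.2 / lam_base, 0.005))
    t_pulse_end = 8.0 * float(np.max(draws["tau_UB2"]))

    def step_for(t):
        return h_pulse if t < t_pulse_end else h_base

    with np.errstate(all="ignore"):
        for j in range(1, len(t_grid)):
            t0, t1 = float(t_grid[j - 1]), float(t_grid[j])
            h = step_for(t0)
            nsub = max(1, int(round((t1 - t0) / h)))
            h = (t1 - t0) / nsub
            t = t0
            for _ in range(nsub):
                k1 = rhs(y, t)
                k2 = rhs(y + 0.5 * h * k1, t + 0.5 * h)
                k3 = rhs(y + 0.5 * h * k2, t + 0.5 * h)
                k4 = rhs(y + h * k3, t + h)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                np.maximum(y, 0.0, out=y)
                t += h
            bad = ~np.all(np.isfinite(y), axis=0)
            if bad.any():
                failed |= bad
                y[:, bad] = 0.0       # keep the lock-step integration finite
            out[j] = y[1]
            if record_extra:
                A = sphere_area_from_volume(volume(t1)) if use_sltp else A0
                extra[j] = y[0] / A
    out[:, failed] = np.nan
    if record_extra:
        extra[:, failed] = np.nan
        return out, extra, failed
    return out, failed


@dataclass
class SamplingResult:
    trials: pd.DataFrame               # one row per draw, ranked by cost
    top: pd.DataFrame                  # the retained best fraction
    summaries: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_rejected(self):
        return int((~self.trials["valid"]).sum())


def run_sampling(variant="basic", n_trials=2000, top_frac=0.005, seed=0, *,
                 ranges=None, references=None, params=None,
                 sltp_params=None, fit=None, dt=0.2,
                 grid_dt=10.0) -> SamplingResult:
    """Draw, simulate, score and rank ``n_trials`` parameter sets.

    Draws where the steady-state closure fails (negative derived endocytosis
    rate) or a sampled decay time is shorter than the fixed rise time are
    flagged invalid and excluded from the ranking.  Identical seeds give
    identical rankings.
    """
    if n_trials * top_frac < 1:
        raise ValueError("n_trials * top_frac must be >= 1")
    base = TraffickingParams() if params is None else params
    use_coop = variant in ("coop", "combined")
    if use_coop and fit is None:
        fit = default_fit()
    ranges = DEFAULT_RANGES(cooperative=use_coop) if ranges is None else ranges
    references = DEFAULT_REFERENCE if references is None else references
    rng = np.random.default_rng(seed)
    draws = {r.name: r.draw(rng, n_trials) for r in ranges}

    # dependent rates, re-derived per draw so every trial holds the baseline
    A0 = base.A_spine0
    with np.errstate(all="ignore"):
        k_endo = (A0 * (draws["k_exo0"] * base.S_exo0 + base.k_in)
                  - base.k_out * base.U_star) / base.U_star
        if use_coop:
            P, Bs, Us = base.P, base.B_star, base.U_star
            k_UB0 = (A0 * Bs * draws["k_BU"] * fit.lam(P)
                     / (Bs + fit.beta(P) - 0.5)
                     / ((P - Bs) * (1.0 + fit.m(P) * Bs ** B_EXPONENT) * Us))
        else:
            k_UB0 = (A0 * draws["k_BU"] * base.B_star
                     / ((base.P - base.B_star) * base.U_star))
    valid = ((k_endo >= 0.0) & (draws["tau_exo2"] > 25.0)
             & (draws["tau_UB2"] > 5.0))
    draws["k_endo"] = np.where(valid, k_endo, np.maximum(k_endo, 0.0))
    draws["k_UB0"] = k_UB0
    # keep invalid pulse shapes integrable: clamp decay just above the rise
    draws["tau_exo2"] = np.maximum(draws["tau_exo2"], 25.0 + 1e-6)
    draws["tau_UB2"] = np.maximum(draws["tau_UB2"], 5.0 + 1e-6)

    total_cost = np.zeros(n_trials)
    any_failed = np.zeros(n_trials, dtype=bool)
    for key, proto in (("E-LTP", "ltp"), ("k_exo=0", "ltp-noexo")):
        ref = references[key]
        t_grid = np.arange(0.0, ref.T + grid_dt / 2, grid_dt)
        B, failed = _integrate_trials(draws, proto, variant, t_grid, dt, base,
                                      sltp_params, fit)
        any_failed |= failed
        ref_B = to_receptor_counts(ref.value(t_grid), base.B_star)
        T = t_grid[-1] - t_grid[0]
        with np.errstate(invalid="ignore"):
            total_cost += np.trapezoid(np.abs(B - ref_B[:, None]),
                                       t_grid, axis=0) / T

    valid &= ~any_failed
    costs = np.where(valid, total_cost, np.inf)
    order = np.argsort(costs, kind="stable")    # draw order breaks ties
    trials = pd.DataFrame({k: v for k, v in draws.items()})
    trials["cost"] = costs
    trials["valid"] = valid
    trials = trials.iloc[order].reset_index(drop=True)
    trials["rank"] = np.arange(1, n_trials + 1)
    n_top = max(1, int(round(n_trials * top_frac)))
    top = trials.iloc[:n_top].copy()

    # summary time courses of the top set (mean +- sd across parameter sets)
    top_draws = {k: top[k].to_numpy() for k in draws}
    summaries = {}
    for key, proto in (("E-LTP", "ltp"), ("k_exo=0", "ltp-noexo")):
        ref = references[key]
        t_grid = np.arange(0.0, ref.T + grid_dt / 2, grid_dt)
        B, conc, _ = _integrate_trials(top_draws, proto, variant, t_grid, dt,
                                       base, sltp_params, fit,
                                       record_extra=True)
        pct = 100.0 * B / base.B_star
        conc_pct = 100.0 * conc / (base.U_star / A0)
        An_exo = _a_norm(25.0, top_draws["tau_exo2"])
        An_ub = _a_norm(5.0, top_draws["tau_UB2"])
        k_exo_rel = np.stack([_pulse_values(t, 1.0, top_draws["A_exo"], 25.0,
                                            top_draws["tau_exo2"], An_exo)
                              for t in t_grid])
        k_ub_rel = np.stack([_pulse_values(t, 1.0, top_draws["A_UB"], 5.0,
                                           top_draws["tau_UB2"], An_ub)
                             for t in t_grid])
        summaries[key] = pd.DataFrame({
            "t_s": t_grid,
            "B_pct_mean": pct.mean(axis=1), "B_pct_sd": pct.std(axis=1),
            "U_conc_pct_mean": conc_pct.mean(axis=1),
            "U_conc_pct_sd": conc_pct.std(axis=1),
            "k_exo_rel_mean": k_exo_rel.mean(axis=1),
            "k_UB_rel_mean": k_ub_rel.mean(axis=1),
        })

    meta = dict(variant=variant, n_trials=n_trials, top_frac=top_frac,
                seed=seed, dt=dt, grid_dt=grid_dt,
                n_rejected=int((~valid).sum()))
    return SamplingResult(trials=trials, top=top, summaries=summaries,
                          meta=meta)
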