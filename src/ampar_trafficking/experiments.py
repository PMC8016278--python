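"""Scripted computational experiments over the model hierarchy.

Each experiment runs the library end to end and returns tidy DataFrames so
that the analysis drivers (and the test suite) consume one well-defined
surface.  Deterministic experiments are exactly reproducible; stochastic
ones record their seed in the returned metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (CoopParams, InductionParams, SLTPParams,
                     TraffickingParams, sphere_area_from_volume)
from .trafficking import Trajectory, find_return_time, simulate
from .meanfield import MeanFieldFit, coop_k_UB0, default_fit
from .lattice import CoopParams as _CoopParams  # noqa: F401  (re-export)
from .lattice import run_lattice, simulate_frap

__all__ = [
    "experiment_eltp_comparison", "experiment_size_sweep",
    "experiment_occupancy_curve", "experiment_cv", "experiment_dwell",
    "experiment_frap", "SUSTAINED_PCT",
]

# "sustained" potentiation: bound receptors above this % of baseline at 2 h
SUSTAINED_PCT = 110.0


def _coop_params(base: TraffickingParams, fit: MeanFieldFit):
    """Re-derive the basal binding rate for the cooperative fixed point."""
    return base.replace(k_UB0=coop_k_UB0(base, fit),
                        k_endo=base.k_endo)


def experiment_eltp_comparison(*, params: TraffickingParams | None = None,
                               induction: InductionParams | None = None,
                               sltp_params: SLTPParams | None = None,
                               fit: MeanFieldFit | None = None,
                               t_end=7200.0, dt=0.1,
                               threshold_frac=0.015):
    """E-LTP time courses of all four model variants, with and without
    exocytosis.

    Returns ``(curves, diagnostics)``: per (variant, protocol) the bound
    receptors in % of baseline over ``t_end`` seconds, plus return-time,
    final-level and trough diagnostics.
    """
    params = TraffickingParams() if params is None else params
    fit = default_fit() if fit is None else fit
    rows, frames = [], []
    for variant in ("basic", "sltp", "coop", "combined"):
        p = _coop_params(params, fit) if variant in ("coop", "combined") \
            else params
        for protocol in ("ltp", "ltp-noexo"):
            traj = simulate(variant, protocol, p, t_end=t_end, dt=dt,
                            induction=induction, sltp_params=sltp_params,
                            fit=fit)
            df = traj.df[["t_s", "B_pct_baseline", "U_conc_per_um2"]].copy()
            df["variant"] = variant
            df["protocol"] = protocol
            frames.append(df)
            pct = traj.df["B_pct_baseline"].to_numpy()
            try:
                rt = find_return_time(traj, threshold_frac)
            except ValueError:
                rt = np.nan
            rows.append(dict(
                variant=variant, protocol=protocol,
                peak_pct=float(pct.max()),
                trough_pct=float(pct[np.argmax(pct):].min()),
                final_pct=float(pct[-1]),
                return_time_s=rt,
                sustained=bool(pct[-1] > SUSTAINED_PCT),
            ))
    return pd.concat(frames, ignore_index=True), pd.DataFrame(rows)


def _params_for_P(P, mode, S_exo0_basal=13.0, V_ref=0.08):
    """Scaled parameter set for one PSD size in a size sweep."""
    A_basal = sphere_area_from_volume(V_ref)
    if mode == "P_only":
        # PSD size varies, spine geometry fixed at the reference volume
        scale = P / 70.0
        U_star, B_star = 10.0 * scale, 20.0 * scale
        A0 = A_basal
        return TraffickingParams(
            k_in=0.02 * U_star, k_out=0.02 * A0, P=P,
            U_star=U_star, B_star=B_star, V_spine0=V_ref,
            S_exo0=S_exo0_basal)
    # spine volume follows the PSD size through the area scaling
    V0 = V_ref * (P / 70.0) ** 1.5
    if mode == "P_with_area":
        S_exo0 = S_exo0_basal                      # exocytosis held constant
    elif mode == "S_exo_scaled":
        S_exo0 = S_exo0_basal * V0 / V_ref         # RE supply tracks volume
    else:
        raise ValueError(f"unknown size-sweep mode {mode!r}")
    return TraffickingParams.for_spine_size(V0, S_exo0=S_exo0)


def experiment_size_sweep(mode="P_with_area", grid=(40.0, 70.0, 100.0, 200.0),
                          *, variant="combined",
                          fit: MeanFieldFit | None = None,
                          sltp_params: SLTPParams | None = None,
                          t_end=7200.0, dt=0.1, threshold_frac=0.015):
    """E-LTP metrics across PSD/spine sizes.

    Modes: ``P_only`` (slot count varies, spine volume fixed),
    ``P_with_area`` (volume follows the slot count, basal exocytosis event
    size held at 13), ``S_exo_scaled`` (event size scales with the initial
    volume).  Per size the sweep reports the baseline and peak occupancy,
    the return time and the potentiation 1 and 20 minutes after induction.
    """
    fit = default_fit() if fit is None else fit
    rows = []
    for P in grid:
        base = _params_for_P(float(P), mode)
        p = _coop_params(base, fit) if variant in ("coop", "combined") \
            else base
        traj = simulate(variant, "ltp", p, t_end=t_end, dt=dt, fit=fit,
                        sltp_params=sltp_params)
        B = traj.B
        pct = traj.df["B_pct_baseline"].to_numpy()
        t = traj.t
        try:
            rt = find_return_time(traj, threshold_frac)
        except ValueError:
            rt = np.nan
        rows.append(dict(
            P=float(P), V_spine0=base.V_spine0, mode=mode,
            S_exo0=base.S_exo0,
            base_occ_pct=100.0 * base.B_star / base.P,
            peak_occ_pct=float(100.0 * B.max() / base.P),
            return_time_s=rt,
            pct_at_1min=float(np.interp(60.0, t, pct)),
            pct_at_20min=float(np.interp(1200.0, t, pct)),
            final_pct=float(pct[-1]),
            sustained=bool(pct[-1] > SUSTAINED_PCT),
        ))
    return pd.DataFrame(rows)


def experiment_occupancy_curve(P_grid=(36, 100, 196),
                               k_in_grid=(0.3, 0.5, 0.7, 0.9, 1.1), *,
                               coop: CoopParams | None = None,
                               fit: MeanFieldFit | None = None,
                               trials=5, T=1500.0, burn=500.0, seed=0):
    """Stationary occupancy versus mobile concentration: lattice vs mean-field.

    For each (P, k_in) the stochastic lattice is run ``trials`` times and the
    stationary mean bound count compared with the mean-field fixed point at
    the same average concentration.  Returns one row per condition with the
    stochastic mean, its standard error over trials, and the mean-field
    prediction.
    """
    from .meanfield import _fixed_points
    coop = CoopParams() if coop is None else coop
    fit = default_fit() if fit is None else fit
    base = TraffickingParams()
    rng = np.random.default_rng(seed)
    rows = []
    for P in P_grid:
        N = int(round(np.sqrt(P)))
        lat = base.replace(k_UB0=coop.k_UB, k_BU=coop.k_BU)
        for k_in in k_in_grid:
            means, concs = [], []
            for _ in range(trials):
                run = run_lattice(N, coop, lat, T=T, burn=burn, rng=rng,
                                  k_in=k_in)
                means.append(run.B.mean())
                concs.append(run.U.mean() / lat.A_spine0)
            means = np.array(means)
            conc = float(np.mean(concs))
            influx = k_in + lat.k_exo0 * lat.S_exo0
            roots = _fixed_points(lat, fit, influx, coop.k_UB, P=P)
            # pick the root nearest to the stochastic mean (branch selection)
            mf = roots[int(np.argmin([abs(r - means.mean()) for r in roots]))] \
                if roots else np.nan
            rows.append(dict(
                P=P, k_in=k_in, conc=conc,
                B_mean=float(means.mean()),
                B_sem=float(means.std(ddof=1) / np.sqrt(trials)),
                B_meanfield=float(mf), n_roots=len(roots),
                occupancy=float(means.mean() / P)))
    return pd.DataFrame(rows)


def experiment_cv(P_grid=(36, 100), conc_grid=(6.0, 8.0, 10.0, 12.0, 16.0),
                  *, coop: CoopParams | None = None, T=2000.0, burn=500.0,
                  seed=0):
    """CV of the bound count versus occupancy, cooperative vs binomial.

    Clamped-concentration runs; the non-cooperative control uses alpha = 0,
    whose stationary occupancy is binomial, so its CV traces the binomial
    reference ``sqrt((1-p)/(P p))``.
    """
    coop = CoopParams() if coop is None else coop
    rng = np.random.default_rng(seed)
    base = TraffickingParams()
    rows = []
    for P in P_grid:
        N = int(round(np.sqrt(P)))
        for conc in conc_grid:
            run = run_lattice(N, coop, base, T=T, burn=burn, rng=rng,
                              clamp_conc=conc)
            mean, sd = run.B.mean(), run.B.std()
            occ = mean / P
            rows.append(dict(model="cooperative", P=P, conc=conc,
                             occupancy=occ,
                             cv=float(sd / mean) if mean > 0 else np.nan,
                             cv_binomial=float(np.sqrt((1 - occ) / (P * occ)))
                             if occ > 0 else np.nan))
            if occ <= 0 or occ >= 1:
                continue
            # independent-slot control at the matched occupancy: with
            # alpha = 0 the stationary occupancy is exactly binomial with
            # p = conc k_UB / (conc k_UB + k_BU)
            cp0 = CoopParams(alpha=0.0, k_UB=coop.k_UB, k_BU=coop.k_BU,
                             dt=coop.dt)
            conc0 = occ / (1.0 - occ) * coop.k_BU / coop.k_UB
            run0 = run_lattice(N, cp0, base, T=T, burn=burn, rng=rng,
                               clamp_conc=conc0)
            m0, s0 = run0.B.mean(), run0.B.std()
            occ0 = m0 / P
            rows.append(dict(model="independent", P=P, conc=conc0,
                             occupancy=occ0,
                             cv=float(s0 / m0) if m0 > 0 else np.nan,
                             cv_binomial=float(np.sqrt((1 - occ0) / (P * occ0)))
                             if occ0 > 0 else np.nan))
    return pd.DataFrame(rows)


def experiment_dwell(P=100, conc_grid=(6.0, 10.0, 16.0), *,
                     coop: CoopParams | None = None, T=3600.0, seed=0):
    """Per-slot mean dwell-time maps over a one-hour stationary stretch."""
    coop = CoopParams() if coop is None else coop
    rng = np.random.default_rng(seed)
    base = TraffickingParams()
    N = int(round(np.sqrt(P)))
    out = {}
    for conc in conc_grid:
        run = run_lattice(N, coop, base, T=T, burn=0.0, rng=rng,
                          clamp_conc=conc)
        out[conc] = dict(dwell_map=run.grid.mean_dwell_map(),
                         mean_B=float(run.B.mean()))
    return out


def experiment_frap(*, P=81, conc_levels=(11.2, 33.4),
                    coop: CoopParams | None = None, trials=100,
                    bleach_time=300.0, t_end=900.0, seed=0):
    """FRAP recovery curves, cooperative vs non-cooperative model.

    Recovery at a low and a high mobile concentration; in the cooperative
    model high concentration slows recovery (receptors are trapped in
    clusters), in the independent-slot control the curves coincide.
    """
    coop = CoopParams() if coop is None else coop
    N = int(round(np.sqrt(P)))
    frames = []
    for alpha, label in ((coop.alpha, "cooperative"), (0.0, "independent")):
        cp = CoopParams(alpha=alpha, k_UB=coop.k_UB, k_BU=coop.k_BU,
                        dt=coop.dt)
        for conc in conc_levels:
            df = simulate_frap(N, conc, cp, bleach_time=bleach_time,
                               t_end=t_end, trials=trials, seed=seed)
            df["model"] = label
            df["conc"] = conc
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
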