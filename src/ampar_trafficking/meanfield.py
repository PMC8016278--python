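"""Mean-field reduction of the cooperative lattice model.

The spatial lattice is replaced by occupancy-dependent effective rates

    k_BU_coop / k_BU = lambda(P) / (beta(P) + B - 0.5)
    k_UB_coop / k_UB = m(P) B^0.8 + 1

whose coefficients are fitted to the conditional mean rates measured on the
stochastic lattice across a grid of PSD sizes.  ``beta`` and ``lambda``
depend linearly on P, ``m`` hyperbolically (``m = a_m/(P + b_m)``).  With
these factors in place the basal cooperative binding rate follows from the
adapted fixed-point closure (the analogue of the plain-model derivation).

Calibration procedure: clamped-concentration lattice scans cover the full
occupancy range for each P; conditional means are weighted by their visit
counts; the unbinding-ratio fit is restricted to B <= 0.6 P, the occupancy
range that trafficking trajectories actually visit (the hyperbolic form
cannot represent both the cluster-dominated tail and the dilute regime at
once).  With these conventions the fixed-point closure reproduces the
reference basal cooperative binding rate of 5e-4 um^2/(# s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from scipy.optimize import brentq, curve_fit

from .params import CoopParams, TraffickingParams
from .lattice import scan_conditional_rates

__all__ = [
    "MeanFieldFit", "fit_meanfield", "calibrate", "default_fit",
    "coop_k_UB0", "fixed_point_curve",
]

B_EXPONENT = 0.8            # fixed exponent of the binding enhancement
UNBIND_FIT_MAX_OCC = 0.6    # occupancy range entering the unbinding fit


@dataclass
class MeanFieldFit:
    """Fitted coefficients of the occupancy-dependent effective rates."""

    m_beta: float
    c_beta: float
    m_lambda: float
    c_lambda: float
    a_m: float
    b_m: float
    per_P: dict = field(default_factory=dict)    # P -> (lambda, beta, m)
    meta: dict = field(default_factory=dict)

    def beta(self, P):
        return self.m_beta * P + self.c_beta

    def lam(self, P):
        return self.m_lambda * P + self.c_lambda

    def m(self, P):
        return self.a_m / (P + self.b_m)

    def unbinding_factor(self, B, P):
        """``k_BU_coop / k_BU`` at bound count B and PSD size P."""
        return self.lam(P) / (self.beta(P) + B - 0.5)

    def binding_factor(self, B, P):
        """``k_UB_coop / k_UB`` at bound count B and PSD size P."""
        return self.m(P) * np.maximum(B, 0.0) ** B_EXPONENT + 1.0

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        d["per_P"] = {int(k): tuple(v) for k, v in d.get("per_P", {}).items()}
        return cls(**d)


_default_fit_cache = None


def default_fit() -> MeanFieldFit:
    """The packaged calibration fixture (versioned output of ``calibrate``)."""
    global _default_fit_cache
    if _default_fit_cache is None:
        with resources.files("ampar_trafficking.data").joinpath(
                "meanfield_fit.json").open() as fh:
            d = json.load(fh)
        d["per_P"] = {int(k): tuple(v) for k, v in d.get("per_P", {}).items()}
        _default_fit_cache = MeanFieldFit(**d)
    return _default_fit_cache


def fit_meanfield(records) -> MeanFieldFit:
    """Fit the mean-field coefficient functions to conditional rate means.

    ``records`` maps each PSD size P to either a dict ``B -> [count, sum_rBU,
    sum_rUB]`` (as produced by :func:`scan_conditional_rates`) or a tuple of
    arrays ``(B, count, rBU, rUB)``.  At least 4 distinct P values are
    required; each P needs enough distinct B levels for the two per-P fits.
    """
    if len(records) < 4:
        raise ValueError("need lattice statistics for >= 4 PSD sizes")
    per_P = {}
    for P, rec in sorted(records.items()):
        if isinstance(rec, dict):
            Bs = np.array(sorted(rec), dtype=float)
            cnt = np.array([rec[int(b)][0] for b in Bs], dtype=float)
            rBU = np.array([rec[int(b)][1] / rec[int(b)][0] for b in Bs])
            rUB = np.array([rec[int(b)][2] / rec[int(b)][0] for b in Bs])
        else:
            Bs, cnt, rBU, rUB = (np.asarray(x, dtype=float) for x in rec)
        ok = cnt >= 10
        if ok.sum() < 5:
            raise ValueError(f"too few well-sampled B levels at P={P}")
        sel = ok & (Bs <= UNBIND_FIT_MAX_OCC * P)
        if sel.sum() < 3:
            raise ValueError(f"too few B levels below the occupancy cut at P={P}")
        (lam, beta), _ = curve_fit(
            lambda B, l, b: l / (b + B - 0.5), Bs[sel], rBU[sel],
            p0=[3.0, 3.0], sigma=1.0 / np.sqrt(cnt[sel]), maxfev=20000)
        # binding enhancement: weighted linear LS for the single slope m
        w = cnt[ok]
        m = float(np.sum(w * (rUB[ok] - 1.0) * Bs[ok] ** B_EXPONENT)
                  / np.sum(w * Bs[ok] ** (2 * B_EXPONENT)))
        per_P[int(P)] = (float(lam), float(beta), m)
    Ps = np.array(sorted(per_P), dtype=float)
    lams = np.array([per_P[int(p)][0] for p in Ps])
    betas = np.array([per_P[int(p)][1] for p in Ps])
    ms = np.array([per_P[int(p)][2] for p in Ps])
    m_lambda, c_lambda = np.polyfit(Ps, lams, 1)
    m_beta, c_beta = np.polyfit(Ps, betas, 1)
    (a_m, b_m), _ = curve_fit(lambda P, a, b: a / (P + b), Ps, ms,
                              p0=[20.0, 10.0], maxfev=20000)
    fit = MeanFieldFit(m_beta=float(m_beta), c_beta=float(c_beta),
                       m_lambda=float(m_lambda), c_lambda=float(c_lambda),
                       a_m=float(a_m), b_m=float(b_m), per_P=per_P)
    # residuals of the P-level fits, for diagnostics
    fit.meta["resid_lambda"] = float(np.max(np.abs(
        fit.lam(Ps) - lams) / lams))
    fit.meta["resid_beta"] = float(np.max(np.abs(
        fit.beta(Ps) - betas) / betas))
    fit.meta["resid_m"] = float(np.max(np.abs(
        fit.m(Ps) - ms) / ms))
    return fit


def calibrate(P_grid=(36, 64, 100, 144, 196), conc_grid=None, *,
              coop: CoopParams | None = None, T=1500.0, dt=0.2,
              seed=0) -> MeanFieldFit:
    """Run the full lattice calibration pipeline and fit the mean-field.

    For each PSD size the lattice is scanned at clamped mobile
    concentrations spanning the dilute-to-saturated range; conditional rate
    means are accumulated and fitted.  ``T`` seconds per scan with a 25%
    burn-in; the defaults finish in a few minutes on one core.
    """
    coop = CoopParams() if coop is None else coop
    if conc_grid is None:
        conc_grid = np.array(
            [2.0, 4.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 14.0, 18.0, 30.0])
    rng = np.random.default_rng(seed)
    records = {}
    for P in P_grid:
        N = int(round(np.sqrt(P)))
        if N * N != P:
            raise ValueError(f"PSD size {P} is not a square lattice")
        rec = {}
        for conc in conc_grid:
            scan_conditional_rates(N, conc, coop, T=T, dt=dt, rng=rng,
                                   record=rec)
        records[P] = rec
    fit = fit_meanfield(records)
    fit.meta.update(dict(P_grid=list(P_grid), T=T, dt=dt, seed=seed,
                         conc_grid=list(np.asarray(conc_grid, dtype=float)),
                         alpha=coop.alpha, k_UB=coop.k_UB, k_BU=coop.k_BU))
    return fit


def coop_k_UB0(params: TraffickingParams, fit: MeanFieldFit):
    """Basal cooperative binding rate from the adapted fixed-point closure.

    ``k_UB0 = A0 B* k_BU lambda(P)/(B* + beta(P) - 0.5)
              / [(P - B*) (1 + m(P) B*^0.8) U*]``;
    in the non-cooperative limit (unbinding factor 1, m = 0) this reduces to
    the plain-model closure.
    """
    P, Bs, Us = params.P, params.B_star, params.U_star
    denom = (P - Bs) * (1.0 + fit.m(P) * Bs ** B_EXPONENT) * Us
    if denom <= 0:
        raise ValueError("fixed-point closure denominator must be positive")
    num = params.A_spine0 * Bs * params.k_BU * fit.lam(P) \
        / (Bs + fit.beta(P) - 0.5)
    return num / denom


def _fixed_points(params, fit, influx, k_UB0, P=None):
    """All roots of dB/dt = 0 with the mobile pool at quasi-steady state."""
    P = params.P if P is None else P
    A = params.A_spine0

    def dB(B):
        if fit is not None:
            kub = k_UB0 * fit.binding_factor(B, P)
            kbu = params.k_BU * fit.unbinding_factor(B, P)
        else:
            kub, kbu = k_UB0, params.k_BU
        conc = (influx + kbu * B) / (params.k_endo + params.k_out
                                     + kub * (P - B))
        return kub * (P - B) * conc - kbu * B

    grid = np.linspace(1e-6, P - 1e-6, 400)
    vals = np.array([dB(b) for b in grid])
    roots = []
    for i in np.nonzero(np.diff(np.sign(vals)) != 0)[0]:
        roots.append(brentq(dB, grid[i], grid[i + 1]))
    return roots


def fixed_point_curve(variant, params: TraffickingParams, sweep, *,
                      sweep_var="S_exo", fit: MeanFieldFit | None = None):
    """Steady-state bound count across a sweep of drive levels.

    ``sweep_var`` is either ``"S_exo"`` (exocytosis event size, the spine
    drive during structural plasticity) or ``"conc"``, in which case the
    sweep values are mobile concentrations (#/um^2) imposed directly.  For
    each sweep value all coexisting fixed points are located by dense sign
    scanning plus bisection; multiple roots flag bistability.  Returns a
    list of (sweep value, [B* roots]) pairs.
    """
    use_coop = variant in ("coop", "combined")
    if use_coop and fit is None:
        fit = default_fit()
    k_UB0 = coop_k_UB0(params, fit) if use_coop else params.k_UB0
    out = []
    for s in np.asarray(sweep, dtype=float):
        if s <= 0:
            raise ValueError("sweep values must be positive")
        if sweep_var == "S_exo":
            influx = params.k_exo0 * s + params.k_in
            roots = _fixed_points(params, fit if use_coop else None,
                                  influx, k_UB0)
        elif sweep_var == "conc":
            P = params.P

            def dB(B, conc=s):
                if use_coop:
                    kub = k_UB0 * fit.binding_factor(B, P)
                    kbu = params.k_BU * fit.unbinding_factor(B, P)
                else:
                    kub, kbu = k_UB0, params.k_BU
                return kub * (P - B) * conc - kbu * B

            grid = np.linspace(1e-6, P - 1e-6, 400)
            vals = np.array([dB(b) for b in grid])
            roots = [brentq(dB, grid[i], grid[i + 1]) for i in
                     np.nonzero(np.diff(np.sign(vals)) != 0)[0]]
        else:
            raise ValueError("sweep_var must be 'S_exo' or 'conc'")
        out.append((float(s), roots))
    return out
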