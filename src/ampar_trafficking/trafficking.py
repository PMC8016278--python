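"""Deterministic simulation engine for the spine trafficking models.

Four model variants share one pair of balance equations for the mobile pool
``U`` and the bound pool ``B``::

    dU/dt = k_exo S_exo + k_in + k_BU_eff B
            - (k_endo + k_out + k_UB_eff (P - B)) U / A_spine
    dB/dt = k_UB_eff (P - B) U / A_spine - k_BU_eff B

* ``basic`` -- constant spine geometry, plain rates.
* ``sltp`` -- spine volume follows the structural-plasticity time course;
  the exocytosis event size ``S_exo`` relaxes toward the enlarged volume.
* ``coop`` -- binding/unbinding rates carry the occupancy-dependent
  mean-field cooperativity factors calibrated from the lattice model.
* ``combined`` -- sLTP and cooperativity together.

Protocols: ``baseline`` (no induction), ``ltp`` (rate transients from t=0),
``ltp-noexo`` (LTP induction with exocytosis blocked from t=0, which also
abolishes the sustained sLTP phase).

Integration uses the classical fixed-step 4th-order Runge-Kutta scheme; all
state variables may be NumPy arrays, which the parameter-sampling stage uses
to integrate thousands of parameter draws in lock-step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (InductionParams, PulseSpec, SLTPParams, TraffickingParams,
                     sphere_area_from_volume)
from . import sltp as _sltp

__all__ = [
    "MODEL_VARIANTS", "PROTOCOLS", "Trajectory", "IntegrationError",
    "rhs_basic", "make_rhs", "simulate", "find_return_time",
]

MODEL_VARIANTS = ("basic", "sltp", "coop", "combined")
PROTOCOLS = ("baseline", "ltp", "ltp-noexo")


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Fixed-interval model trajectory plus run metadata.

    ``df`` columns: t_s, U, B, V_spine_um3, S_exo, A_spine_um2,
    B_pct_baseline, U_conc_per_um2.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def t(self):
        return self.df["t_s"].to_numpy()

    @property
    def U(self):
        return self.df["U"].to_numpy()

    @property
    def B(self):
        return self.df["B"].to_numpy()

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


def rhs_basic(U, B, t, params: TraffickingParams, exo_pulse=None, ub_pulse=None,
              S_exo=None, A_spine=None):
    """Time derivatives (dU/dt, dB/dt) of the plain two-pool model.

    Pulses are multiplicative transients on ``k_exo`` and ``k_UB``; omitted
    pulses mean basal rates.  ``A_spine`` defaults to the basal sphere area.
    """
    S_exo = params.S_exo0 if S_exo is None else S_exo
    A = params.A_spine0 if A_spine is None else A_spine
    k_exo = params.k_exo0 * (exo_pulse.value(t) if exo_pulse is not None else 1.0)
    k_UB = params.k_UB0 * (ub_pulse.value(t) if ub_pulse is not None else 1.0)
    conc = U / A
    dU = (k_exo * S_exo + params.k_in + params.k_BU * B
          - (params.k_endo + params.k_out + k_UB * (params.P - B)) * conc)
    dB = k_UB * (params.P - B) * conc - params.k_BU * B
    return dU, dB


def make_rhs(variant, protocol, params: TraffickingParams,
             induction: InductionParams | None = None,
             sltp_params: SLTPParams | None = None,
             fit=None, instantaneous_area=True):
    """Build the state derivative function ``rhs(y, t) -> dy`` for a run.

    State ``y = (U, B, S_exo)``; each component may be an array of parallel
    runs.  Returns ``(rhs, aux)`` where ``aux(t)`` yields the spine volume
    used at time ``t`` (for trajectory output).
    """
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    induction = InductionParams() if induction is None else induction
    use_sltp = variant in ("sltp", "combined")
    use_coop = variant in ("coop", "combined")
    blocked = protocol == "ltp-noexo"
    induced = protocol in ("ltp", "ltp-noexo")

    if use_coop:
        if fit is None:
            from .meanfield import default_fit
            fit = default_fit()
        binding_factor = fit.binding_factor
        unbinding_factor = fit.unbinding_factor

    exo_pulse = induction.exo_pulse() if induced else None
    ub_pulse = induction.ub_pulse(cooperative=use_coop) if induced else None

    if use_sltp:
        sp = SLTPParams() if sltp_params is None else sltp_params
        k_outRE = sp.derive_k_outRE(params.V_spine0, params.S_exo0)
        sltp_active = induced  # volume course is triggered by induction

        def volume(t):
            if not sltp_active:
                return params.V_spine0
            return _sltp.v_spine(t, params.V_spine0, sp,
                                 blocked_exocytosis=blocked)
    else:
        sp = None

        def volume(t):
            return params.V_spine0

    P = params.P
    A0 = params.A_spine0

    def rhs(y, t):
        U, B, S = y
        Bc = np.maximum(B, 0.0)
        V = volume(t)
        A = sphere_area_from_volume(V) if (use_sltp and instantaneous_area) else A0
        k_exo = 0.0 if blocked else params.k_exo0 * (
            exo_pulse.value(t) if exo_pulse is not None else 1.0)
        k_UB = params.k_UB0 * (
            ub_pulse.value(t) if ub_pulse is not None else 1.0)
        if use_coop:
            k_UB_eff = k_UB * binding_factor(Bc, P)
            k_BU_eff = params.k_BU * unbinding_factor(Bc, P)
        else:
            k_UB_eff = k_UB
            k_BU_eff = params.k_BU
        conc = U / A
        dU = (k_exo * S + params.k_in + k_BU_eff * B
              - (params.k_endo + params.k_out + k_UB_eff * (P - B)) * conc)
        dB = k_UB_eff * (P - B) * conc - k_BU_eff * B
        if use_sltp:
            dS = _sltp.rhs_s_exo(S, V, sp.k_inRE, k_outRE)
        else:
            dS = np.zeros_like(np.asarray(S, dtype=float))
        return np.array([dU, dB, dS])

    return rhs, volume


def _rk4(rhs, y0, t_end, dt, thin, clip_negative=True):
    """Fixed-step RK4 driver.  Returns (times, states) at thinned intervals."""
    n = int(round(t_end / dt))
    y = np.array(y0, dtype=float)
    ts = [0.0]
    ys = [y.copy()]
    clipped = False
    for i in range(n):
        t = i * dt
        k1 = rhs(y, t)
        k2 = rhs(y + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = rhs(y + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = rhs(y + dt * k3, t + dt)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if clip_negative and np.any(y < 0.0):
            y = np.maximum(y, 0.0)
            if not clipped:
                warnings.warn(
                    "negative state clipped to 0 during integration",
                    RuntimeWarning, stacklevel=3)
            clipped = True
        if (i + 1) % thin == 0 or i == n - 1:
            if not np.all(np.isfinite(y)):
                raise IntegrationError(
                    f"non-finite state at step {i + 1} (t={t + dt:g} s)")
            ts.append((i + 1) * dt)
            ys.append(y.copy())
    return np.array(ts), np.array(ys)


def simulate(variant, protocol, params: TraffickingParams | None = None, *,
             t_end=7200.0, dt=0.1, thin=None,
             induction: InductionParams | None = None,
             sltp_params: SLTPParams | None = None,
             fit=None, instantaneous_area=True, state0=None) -> Trajectory:
    """Integrate one model variant under one protocol.

    ``dt`` defaults to 0.1 s (50x finer than the fastest induced transient);
    output is thinned to 1 s unless ``thin`` is given.  The run starts at the
    basal fixed point unless ``state0=(U, B, S_exo)`` is supplied; induction
    occurs at t = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params = TraffickingParams() if params is None else params
    thin = max(1, int(round(1.0 / dt))) if thin is None else thin
    rhs, volume = make_rhs(variant, protocol, params, induction=induction,
                           sltp_params=sltp_params, fit=fit,
                           instantaneous_area=instantaneous_area)
    if state0 is None:
        state0 = (params.U_star, params.B_star, params.S_exo0)
    ts, ys = _rk4(rhs, state0, t_end, dt, thin)
    use_sltp = variant in ("sltp", "combined")
    V = np.array([volume(t) for t in ts]) if use_sltp else \
        np.full_like(ts, params.V_spine0)
    A = sphere_area_from_volume(V) if (use_sltp and instantaneous_area) else \
        np.full_like(ts, params.A_spine0)
    df = pd.DataFrame({
        "t_s": ts,
        "U": ys[:, 0],
        "B": ys[:, 1],
        "V_spine_um3": V,
        "S_exo": ys[:, 2],
        "A_spine_um2": A,
        "B_pct_baseline": 100.0 * ys[:, 1] / params.B_star,
        "U_conc_per_um2": ys[:, 0] / A,
    })
    meta = {
        "variant": variant, "protocol": protocol, "dt": dt, "thin": thin,
        "t_end": t_end, "params": params.asdict(),
        "B_star": params.B_star, "U_star": params.U_star,
    }
    return Trajectory(df=df, meta=meta)


def find_return_time(traj: Trajectory, threshold_frac=0.015, baseline=None):
    """First post-peak time at which ``|B - B*|/B*`` drops below the band.

    The trajectory must show a potentiation peak above baseline; a flat
    (baseline) trajectory raises ``ValueError``.  Returns ``np.inf`` if the
    trajectory never re-enters the band after its peak.  The default band of
    1.5% is the operational definition of "returned to the basal level"; it
    reproduces the characteristic decay windows of all model variants.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    B = traj.B
    t = traj.t
    B_star = traj.meta.get("B_star") if baseline is None else baseline
    ipk = int(np.argmax(B))
    if B[ipk] <= B_star * (1.0 + threshold_frac):
        raise ValueError("trajectory shows no potentiation peak above the "
                         "baseline band; return time undefined")
    rel = np.abs(B[ipk:] - B_star) / B_star
    below = np.nonzero(rel <= threshold_frac)[0]
    if below.size == 0:
        return float("inf")
    return float(t[ipk + below[0]])
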