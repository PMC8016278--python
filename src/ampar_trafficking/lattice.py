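"""Stochastic square-lattice model of cooperative receptor binding at the PSD.

PSD slots are arranged on an N x N grid (open boundaries).  In each Bernoulli
time step an empty slot binds a receptor with probability
``k_UB (alpha chi + 1) (U/A) dt`` and an occupied slot releases one with
probability ``k_BU (1 - chi) dt``, where ``chi = n/8`` is the occupied
fraction of the 8 surrounding sites (the denominator stays 8 at edges and
corners).  All slots update synchronously from the pre-step configuration.

The mobile pool ``U`` is simulated alongside as a tau-leaping birth-death
process of the trafficking fluxes: Poisson influx via lateral diffusion and
exocytosis events (``S_exo`` receptors per event), Poisson efflux via
endocytosis and out-diffusion, and the exact bind/unbind exchange with the
grid.  Alternatively the mobile concentration can be clamped, which the
mean-field calibration uses to scan occupancy levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import CoopParams, TraffickingParams, sphere_area_from_volume

__all__ = [
    "GridState", "LatticeRun", "LatticeStats",
    "neighbour_fraction", "slot_rates", "step_stochastic", "run_lattice",
    "lattice_statistics", "scan_conditional_rates", "simulate_frap",
]


def neighbour_fraction(occ):
    """Occupied-neighbour fraction ``chi`` for every slot (denominator 8)."""
    p = np.pad(occ, 1)
    n = (p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
         + p[1:-1, :-2] + p[1:-1, 2:]
         + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:])
    return n / 8.0


@dataclass
class GridState:
    """Occupancy grid plus per-slot dwell bookkeeping."""

    occ: np.ndarray                      # int8 N x N, 0 empty / 1 occupied
    bound_time: np.ndarray = None        # cumulative occupied time per slot
    bind_events: np.ndarray = None
    unbind_events: np.ndarray = None

    def __post_init__(self):
        self.occ = np.asarray(self.occ, dtype=np.int8)
        n = self.occ.shape
        if self.occ.ndim != 2 or n[0] != n[1]:
            raise ValueError("occupancy grid must be square")
        if self.bound_time is None:
            self.bound_time = np.zeros(n, dtype=float)
        if self.bind_events is None:
            self.bind_events = np.zeros(n, dtype=np.int64)
        if self.unbind_events is None:
            self.unbind_events = np.zeros(n, dtype=np.int64)

    @classmethod
    def empty(cls, N):
        return cls(occ=np.zeros((N, N), dtype=np.int8))

    @classmethod
    def random(cls, N, fill, rng):
        return cls(occ=(rng.random((N, N)) < fill).astype(np.int8))

    @property
    def N(self):
        return self.occ.shape[0]

    @property
    def P(self):
        return self.occ.size

    @property
    def B(self):
        return int(self.occ.sum())

    def mean_dwell_map(self):
        """Per-slot mean dwell time (s): occupied time per completed unbinding.

        Slots that never released a receptor contribute their total bound
        time (a lower bound on the true dwell).
        """
        denom = np.maximum(self.unbind_events, 1)
        return self.bound_time / denom


def slot_rates(grid: GridState, coop: CoopParams):
    """Per-slot cooperative rates ``(k_UB_coop, k_BU_coop)``.

    The binding rate applies to empty slots, the unbinding rate to occupied
    ones; both arrays are returned over the full grid.  ``alpha = 0`` is the
    independent-slot control: both rates constant (the neighbourhood plays no
    role), so the stationary occupancy is binomial.
    """
    chi = neighbour_fraction(grid.occ)
    if coop.alpha == 0.0:
        shape = np.ones_like(chi)
        return coop.k_UB * shape, coop.k_BU * shape
    k_ub = coop.k_UB * (coop.alpha * chi + 1.0)
    k_bu = coop.k_BU * (1.0 - chi)
    return k_ub, k_bu


def step_stochastic(grid: GridState, U, coop: CoopParams,
                    traffic: TraffickingParams, dt, rng, *,
                    A_spine=None, clamp_conc=None, blocked_exo=False,
                    k_in=None):
    """One synchronous Bernoulli step; returns the updated mobile count.

    ``clamp_conc`` fixes the mobile concentration (#/um^2) instead of the
    stochastic pool.  Raises if any event probability exceeds 1 (reduce dt).
    """
    A = traffic.A_spine0 if A_spine is None else A_spine
    conc = (max(U, 0.0) / A) if clamp_conc is None else clamp_conc
    k_ub, k_bu = slot_rates(grid, coop)
    p_ub = k_ub * conc * dt
    p_bu = k_bu * dt
    if p_ub.max() > 1.0 or p_bu.max() > 1.0:
        raise ValueError(
            "event probability exceeds 1 (max p_UB=%.3f); use a smaller dt"
            % p_ub.max())
    r = rng.random(grid.occ.shape)
    empty = grid.occ == 0
    binds = empty & (r < p_ub)
    unbinds = (~empty) & (r < p_bu)
    n_bind = int(binds.sum())
    if clamp_conc is None and n_bind > U:
        # cannot bind more receptors than are mobile; keep a random subset
        idx = np.argwhere(binds)
        keep = rng.choice(len(idx), int(max(U, 0)), replace=False)
        binds = np.zeros_like(binds)
        binds[tuple(idx[keep].T)] = True
        n_bind = int(binds.sum())
    n_unbind = int(unbinds.sum())

    grid.occ = grid.occ + binds.astype(np.int8) - unbinds.astype(np.int8)
    grid.bind_events += binds
    grid.unbind_events += unbinds
    grid.bound_time += grid.occ * dt

    if clamp_conc is not None:
        return U
    k_in_eff = traffic.k_in if k_in is None else k_in
    influx = rng.poisson(k_in_eff * dt)
    if not blocked_exo and traffic.k_exo0 > 0:
        influx += int(traffic.S_exo0) * rng.poisson(traffic.k_exo0 * dt)
    efflux_rate = (traffic.k_endo + traffic.k_out) * conc
    efflux = min(rng.poisson(efflux_rate * dt), int(max(U, 0)))
    return U - n_bind + n_unbind + influx - efflux


@dataclass
class LatticeRun:
    grid: GridState
    t: np.ndarray
    B: np.ndarray
    U: np.ndarray
    meta: dict = field(default_factory=dict)


def run_lattice(N, coop: CoopParams, traffic: TraffickingParams | None = None,
                *, T=3600.0, dt=None, burn=0.0, rng=None, seed=None,
                init_fill=0.0, clamp_conc=None, blocked_exo=False,
                k_in=None, A_spine=None, record_every=1) -> LatticeRun:
    """Simulate an N x N lattice for ``T`` seconds; record B and U traces.

    ``burn`` seconds are discarded from the returned traces (the grid keeps
    its full event bookkeeping).  The mobile pool starts at ``U*`` scaled to
    the grid size unless the concentration is clamped.
    """
    traffic = TraffickingParams() if traffic is None else traffic
    dt = coop.dt if dt is None else dt
    rng = np.random.default_rng(coop.seed if seed is None else seed) \
        if rng is None else rng
    grid = GridState.empty(N) if init_fill == 0.0 else \
        GridState.random(N, init_fill, rng)
    A = traffic.A_spine0 if A_spine is None else A_spine
    U = float(traffic.U_star)
    nsteps = int(round(T / dt))
    nburn = int(round(burn / dt))
    rec_t, rec_B, rec_U = [], [], []
    for i in range(nsteps):
        U = step_stochastic(grid, U, coop, traffic, dt, rng, A_spine=A,
                            clamp_conc=clamp_conc, blocked_exo=blocked_exo,
                            k_in=k_in)
        if i >= nburn and (i - nburn) % record_every == 0:
            rec_t.append((i + 1) * dt)
            rec_B.append(grid.B)
            rec_U.append(U)
    meta = dict(N=N, P=N * N, T=T, dt=dt, burn=burn, clamp_conc=clamp_conc,
                blocked_exo=blocked_exo, init_fill=init_fill)
    return LatticeRun(grid=grid, t=np.array(rec_t), B=np.array(rec_B),
                      U=np.array(rec_U, dtype=float), meta=meta)


@dataclass
class LatticeStats:
    """Summary statistics of one or more equilibrated lattice runs."""

    P: int
    mean_B: float
    cv_B: float
    occupancy: float
    conditional: pd.DataFrame        # columns B, count, rBU, rUB
    dwell_map: np.ndarray | None = None


def _trend_check(B, label=""):
    half = len(B) // 2
    if half < 10:
        return
    a, b = B[:half], B[half:]
    se = np.sqrt(a.var() / max(half, 1) + b.var() / max(half, 1))
    if se > 0 and abs(a.mean() - b.mean()) > 4.0 * se:
        warnings.warn(
            f"lattice run {label} shows a trend between halves; consider a "
            "longer burn-in", RuntimeWarning, stacklevel=3)


def lattice_statistics(runs, coop: CoopParams | None = None) -> LatticeStats:
    """Pool stationary statistics and conditional mean rates over runs.

    The conditional means follow the definition of the mean-field reduction:
    for every observed bound count B, the binding rate is averaged over the
    empty slots and the unbinding rate over the occupied slots of each
    snapshot, then over snapshots (normalised by the basal rates).
    Snapshot-level re-simulation is avoided by re-deriving the rates from
    the recorded grids; runs produced by :func:`run_lattice` carry enough
    bookkeeping for the CV and dwell statistics.
    """
    if isinstance(runs, LatticeRun):
        runs = [runs]
    coop = CoopParams() if coop is None else coop
    P = runs[0].grid.P
    allB = np.concatenate([r.B for r in runs])
    for i, r in enumerate(runs):
        _trend_check(r.B, label=str(i))
    mean_B = float(allB.mean())
    cv = float(allB.std() / mean_B) if mean_B > 0 else float("nan")
    # conditional means need per-snapshot grids; reconstruct by re-running is
    # wasteful, so runs recorded with scan_conditional_rates supply them.
    cond = pd.DataFrame({"B": [], "count": [], "rBU": [], "rUB": []})
    dwell = runs[0].grid.mean_dwell_map() if len(runs) == 1 else None
    return LatticeStats(P=P, mean_B=mean_B, cv_B=cv, occupancy=mean_B / P,
                        conditional=cond, dwell_map=dwell)


def scan_conditional_rates(N, conc, coop: CoopParams, *, T=1200.0, dt=None,
                           burn=None, rng=None, record=None):
    """Clamped-concentration scan accumulating conditional rate means.

    Returns (and updates in place, if given) a dict mapping the bound count
    ``B`` to ``[n_snapshots, sum of mean unbinding ratio over occupied slots,
    sum of mean binding ratio over empty slots]``.  Ratios are relative to
    the basal ``k_BU`` and ``k_UB``.
    """
    dt = coop.dt if dt is None else dt
    burn = 0.25 * T if burn is None else burn
    rng = np.random.default_rng(coop.seed) if rng is None else rng
    record = {} if record is None else record
    grid = GridState.empty(N)
    nsteps = int(round(T / dt))
    nburn = int(round(burn / dt))
    P = N * N
    indep = coop.alpha == 0.0
    for i in range(nsteps):
        chi = neighbour_fraction(grid.occ)
        r_bu = np.ones_like(chi) if indep else 1.0 - chi   # ratio to k_BU
        r_ub = np.ones_like(chi) if indep else coop.alpha * chi + 1.0
        p_ub = coop.k_UB * r_ub * conc * dt
        p_bu = coop.k_BU * r_bu * dt
        if i == 0 and (p_ub.max() > 1.0 or p_bu.max() > 1.0):
            raise ValueError("event probability exceeds 1; reduce dt")
        r = rng.random(grid.occ.shape)
        empty = grid.occ == 0
        binds = empty & (r < p_ub)
        unbinds = (~empty) & (r < p_bu)
        grid.occ = grid.occ + binds.astype(np.int8) - unbinds.astype(np.int8)
        if i >= nburn:
            B = int(grid.occ.sum())
            if B > 0:
                rec = record.setdefault(B, [0, 0.0, 0.0])
                rec[0] += 1
                rec[1] += r_bu[grid.occ == 1].mean()
                rec[2] += r_ub[grid.occ == 0].mean() if B < P else 1.0
    return record


def simulate_frap(N, conc_target, coop: CoopParams,
                  traffic: TraffickingParams | None = None, *,
                  bleach_time=300.0, t_end=900.0, dt=None, trials=100,
                  seed=0, observable="total") -> pd.DataFrame:
    """Fluorescence-recovery-after-photobleaching simulation.

    The lattice plus mobile pool is equilibrated until ``bleach_time``, at
    which every receptor currently in the spine (mobile and bound) is marked
    bleached.  Recovery is driven by unbleached receptors entering via
    lateral diffusion and exocytosis.  The returned frame holds the mean and
    standard error over trials of the unbleached fraction of the chosen
    observable (``"total"`` = (U+B), ``"bound"`` = B only), normalised to the
    pre-bleach level of 1.

    ``conc_target`` sets the influx so that the stationary mobile
    concentration is approximately the requested #/um^2 (the influx needed is
    ``conc * (k_endo + k_out)``).
    """
    traffic = TraffickingParams() if traffic is None else traffic
    dt = coop.dt if dt is None else dt
    if bleach_time < 120.0:
        warnings.warn("bleach before equilibration; recovery curve may be "
                      "biased", RuntimeWarning, stacklevel=2)
    P = N * N
    A = traffic.A_spine0 * P / traffic.P   # PSD size scales with spine area
    k_in = conc_target * (traffic.k_endo + traffic.k_out) \
        - traffic.k_exo0 * traffic.S_exo0
    k_in = max(k_in, 0.0)
    nsteps = int(round(t_end / dt))
    ibleach = int(round(bleach_time / dt))
    out_t = (np.arange(nsteps) + 1) * dt - bleach_time
    curves = np.zeros((trials, nsteps))
    rng_master = np.random.default_rng(seed)
    for trial in range(trials):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        occ = np.zeros((N, N), dtype=np.int8)
        bleached = np.zeros((N, N), dtype=bool)
        U_u, U_b = float(traffic.U_star), 0.0
        for i in range(nsteps):
            chi = neighbour_fraction(occ)
            U = U_u + U_b
            conc = max(U, 0.0) / A
            if coop.alpha == 0.0:
                p_ub = coop.k_UB * conc * dt * np.ones_like(chi)
                p_bu = coop.k_BU * dt * np.ones_like(chi)
            else:
                p_ub = coop.k_UB * (coop.alpha * chi + 1.0) * conc * dt
                p_bu = coop.k_BU * (1.0 - chi) * dt
            r = rng.random(occ.shape)
            empty = occ == 0
            binds = empty & (r < p_ub)
            unbinds = (~empty) & (r < p_bu)
            n_bind = int(binds.sum())
            if n_bind > U:
                idx = np.argwhere(binds)
                keep = rng.choice(len(idx), int(max(U, 0)), replace=False)
                binds = np.zeros_like(binds)
                binds[tuple(idx[keep].T)] = True
                n_bind = int(binds.sum())
            # label newly bound receptors by the mobile-pool composition
            frac_b = U_b / U if U > 0 else 0.0
            new_bleached = binds & (rng.random(occ.shape) < frac_b)
            bound_back_u = int((unbinds & ~bleached).sum())
            bound_back_b = int((unbinds & bleached).sum())
            bind_b = int(new_bleached.sum())
            bind_u = n_bind - bind_b
            occ = occ + binds.astype(np.int8) - unbinds.astype(np.int8)
            bleached = (bleached | new_bleached) & (occ == 1)
            # mobile pool fluxes
            influx = rng.poisson(k_in * dt) \
                + int(traffic.S_exo0) * rng.poisson(traffic.k_exo0 * dt)
            efflux = min(rng.poisson((traffic.k_endo + traffic.k_out)
                                     * conc * dt), int(max(U, 0)))
            eff_b = int(round(efflux * frac_b))
            eff_u = efflux - eff_b
            U_u = max(U_u - bind_u + bound_back_u + influx - eff_u, 0.0)
            U_b = max(U_b - bind_b + bound_back_b - eff_b, 0.0)
            if i + 1 == ibleach:
                U_b += U_u
                U_u = 0.0
                bleached = occ == 1
            B_u = int(((occ == 1) & ~bleached).sum())
            B_tot = int(occ.sum())
            if observable == "bound":
                curves[trial, i] = B_u / B_tot if B_tot > 0 else 0.0
            else:
                tot = U_u + U_b + B_tot
                curves[trial, i] = (U_u + B_u) / tot if tot > 0 else 0.0
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0) / np.sqrt(trials)
    return pd.DataFrame({"t_s": out_t, "frac_unbleached": mean,
                         "sem": sem})
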