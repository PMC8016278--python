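"""Parameter containers for the spine AMPAR-trafficking model.

The basal parameter set describes an "average" dendritic spine: a spherical
head of volume ``V_spine0`` whose membrane carries a pool of laterally mobile
AMPA receptors ``U`` exchanging with a pool ``B`` bound to scaffold slots of
the postsynaptic density (PSD).  Two of the rate constants, the endocytosis
rate ``k_endo`` and the basal binding rate ``k_UB0``, are not free: they are
derived from the requirement that ``(U*, B*)`` is an exact fixed point of the
trafficking equations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "sphere_area_from_volume",
    "PulseSpec",
    "TraffickingParams",
    "InductionParams",
    "SLTPParams",
    "CoopParams",
]

_SPHERE_CONST = (36.0 * math.pi) ** (1.0 / 3.0)


def sphere_area_from_volume(volume):
    """Surface area (um^2) of a sphere with the given volume (um^3).

    Spine heads are treated as spheres, so ``A = (36 pi)^(1/3) V^(2/3)``.
    Raises ``ValueError`` for non-positive volumes.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0.0):
        raise ValueError("spine volume must be positive, got %r" % (volume,))
    area = _SPHERE_CONST * v ** (2.0 / 3.0)
    return float(area) if np.isscalar(volume) or np.ndim(volume) == 0 else area


@dataclass
class PulseSpec:
    """Normalised double-exponential transient ``C + A (e^-t/tau2 - e^-t/tau1)/A_norm``.

    ``A_norm`` is chosen so that the transient part has maximum exactly ``A``;
    ``C`` is the baseline multiplier.  Used both for the LTP-induced rate
    modulations and for the spine-volume time course.
    """

    C: float
    A: float
    tau1: float
    tau2: float

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        A = np.asarray(self.A, dtype=float)
        t1 = np.asarray(self.tau1, dtype=float)
        t2 = np.asarray(self.tau2, dtype=float)
        if np.any(t1 <= 0.0) or np.any(t2 <= 0.0):
            raise ValueError("pulse time constants must be positive")
        if np.any(t1 == t2):
            raise ValueError(
                "degenerate pulse timescales tau1 == tau2: A_norm undefined")
        if np.any(t2 < t1):
            raise ValueError("require tau2 > tau1 (rise faster than decay)")
        if np.any(A < 0.0) or np.any(C < 0.0):
            raise ValueError("pulse amplitude and baseline must be >= 0")

    @property
    def A_norm(self):
        """Peak of ``e^-t/tau2 - e^-t/tau1`` over ``t >= 0`` (closed form)."""
        t1 = np.asarray(self.tau1, dtype=float)
        t2 = np.asarray(self.tau2, dtype=float)
        r = t2 / t1
        return r ** (t1 / (t1 - t2)) - r ** (t2 / (t1 - t2))

    def value(self, t):
        """Evaluate the pulse at time(s) ``t`` (s, >= 0)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0.0):
            raise ValueError("pulse time must be >= 0")
        shape = (np.exp(-t / self.tau2) - np.exp(-t / self.tau1)) / self.A_norm
        return self.C + self.A * shape

    def peak_time(self):
        """Time of the transient maximum, ``ln(tau2/tau1)/(1/tau1 - 1/tau2)``."""
        t1, t2 = float(self.tau1), float(self.tau2)
        return math.log(t2 / t1) / (1.0 / t1 - 1.0 / t2)


@dataclass
class TraffickingParams:
    """Basal trafficking constants of the average spine.

    Units: rates that act on a surface concentration (``k_endo``, ``k_out``,
    ``k_UB0``) carry um^2/s (per-receptor for ``k_UB0``); ``k_in`` is an
    absolute influx in receptors/s; ``k_exo0`` is an event rate in 1/s with
    ``S_exo0`` receptors delivered per event.

    ``k_endo`` and ``k_UB0`` default to the steady-state closure values and
    may be overridden explicitly (e.g. to switch off pathways in tests).
    """

    k_exo0: float = 0.0018      # exocytosis event rate, 1/s
    S_exo0: float = 13.0        # receptors per exocytosis event
    k_in: float = 0.2           # diffusive influx, #/s
    k_out: float = 0.018        # diffusive efflux, um^2/s
    k_BU: float = 0.1           # unbinding rate, 1/s
    P: float = 70.0             # PSD slot count
    U_star: float = 10.0        # steady-state mobile receptors
    B_star: float = 20.0        # steady-state bound receptors
    V_spine0: float = 0.08      # basal spine volume, um^3
    k_endo: float | None = None     # derived unless given, um^2/s
    k_UB0: float | None = None      # derived unless given, um^2/(# s)

    def __post_init__(self):
        if self.U_star < 0 or self.B_star < 0:
            raise ValueError("steady-state receptor numbers must be >= 0")
        if self.P < self.B_star:
            raise ValueError("slot count P must be >= B_star")
        for name in ("k_exo0", "S_exo0", "k_in", "k_out", "k_BU"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_endo is None:
            self.k_endo = self.derive_k_endo()
        if self.k_UB0 is None:
            self.k_UB0 = self.derive_k_UB0()

    @property
    def A_spine0(self):
        """Basal spine surface area (um^2), sphere of volume ``V_spine0``."""
        return sphere_area_from_volume(self.V_spine0)

    def derive_k_endo(self):
        """Endocytosis rate from the mobile-pool steady-state balance.

        ``k_endo = [A0 (k_exo0 S_exo0 + k_in) - k_out U*] / U*``; a negative
        result means the configured influx cannot sustain ``U*``.
        """
        if self.U_star <= 0:
            raise ValueError("U_star must be > 0 to derive k_endo")
        val = (self.A_spine0 * (self.k_exo0 * self.S_exo0 + self.k_in)
               - self.k_out * self.U_star) / self.U_star
        if val < 0:
            raise ValueError(
                "inconsistent parameters: influx too small for U*=%g "
                "(derived k_endo=%g < 0)" % (self.U_star, val))
        return val

    def derive_k_UB0(self):
        """Basal binding rate from the bound-pool steady state.

        ``k_UB0 = A0 k_BU B* / ((P - B*) U*)``.
        """
        if self.U_star <= 0:
            raise ValueError("U_star must be > 0 to derive k_UB0")
        if self.P <= self.B_star:
            raise ValueError("require P > B_star to derive k_UB0")
        return (self.A_spine0 * self.k_BU * self.B_star
                / ((self.P - self.B_star) * self.U_star))

    @classmethod
    def for_spine_size(cls, V_spine0, *, P_basal=70.0, A_basal=None,
                       k_in_prime=0.02, S_exo0=13.0, **overrides):
        """Parameters for a spine of a different basal volume.

        The PSD slot count scales linearly with the spine surface area,
        ``P = P_basal * A0 / A_basal``, and the steady-state receptor numbers
        scale with ``P`` (bound receptor content grows linearly with PSD
        size).  Diffusive rates follow the per-area convention
        ``k_in = k_in' U*``, ``k_out = k_in' A0``, which keeps the diffusion
        balance intact for any spine size.
        """
        ref = cls(**{k: v for k, v in overrides.items()
                     if k in ("k_exo0", "k_BU")})
        A_basal = sphere_area_from_volume(0.08) if A_basal is None else A_basal
        A0 = sphere_area_from_volume(V_spine0)
        P = P_basal * A0 / A_basal
        scale = P / P_basal
        U_star = 10.0 * scale
        B_star = 20.0 * scale
        kwargs = dict(
            k_exo0=ref.k_exo0, S_exo0=S_exo0,
            k_in=k_in_prime * U_star, k_out=k_in_prime * A0,
            k_BU=ref.k_BU, P=P, U_star=U_star, B_star=B_star,
            V_spine0=V_spine0)
        kwargs.update({k: v for k, v in overrides.items() if k in kwargs})
        return cls(**kwargs)

    def replace(self, **changes):
        """Copy with fields changed; derived rates are re-derived unless given."""
        base = dataclasses.asdict(self)
        if any(k in changes for k in
               ("k_exo0", "S_exo0", "k_in", "k_out", "k_BU", "P",
                "U_star", "B_star", "V_spine0")):
            base["k_endo"] = None
            base["k_UB0"] = None
        base.update(changes)
        return TraffickingParams(**base)

    def asdict(self):
        return dataclasses.asdict(self)


@dataclass
class InductionParams:
    """LTP-induction transients of the exocytosis event rate and binding rate.

    The amplitudes are multiplicative: at the pulse peak the rate is
    ``(1 + A) x`` basal.  ``A_UB`` differs between the plain model (30, chosen
    to nearly saturate the slots) and the cooperative model (5, where
    cooperativity supplies the extra gain).
    """

    A_exo: float = 5.0
    tau_exo1: float = 25.0
    tau_exo2: float = 60.0
    A_UB: float = 30.0
    A_UB_coop: float = 5.0
    tau_UB1: float = 5.0
    tau_UB2: float = 60.0

    def exo_pulse(self):
        return PulseSpec(C=1.0, A=self.A_exo, tau1=self.tau_exo1,
                         tau2=self.tau_exo2)

    def ub_pulse(self, cooperative=False):
        A = self.A_UB_coop if cooperative else self.A_UB
        return PulseSpec(C=1.0, A=A, tau1=self.tau_UB1, tau2=self.tau_UB2)


@dataclass
class SLTPParams:
    """Structural-plasticity (sLTP) parameters.

    The long-term relative volume change of a spine with initial volume
    ``V0`` is ``dV_long(V0) = (a exp(V0/b) + c)/100`` with ``b < 0``: small
    spines grow strongly and spines above ~0.3 um^3 show no lasting change.
    ``a``, ``b``, ``c`` default to the averaged fit over the bundled
    size-dependence constraint sets (see :mod:`ampar_trafficking.sltp`).

    The exocytosis event size relaxes toward ``k_inRE V_spine / k_outRE``,
    modelling the recycling-endosome pool tracking spine volume.
    """

    a: float | None = None          # %, amplitude of the size dependence
    b: float | None = None          # um^3, decay constant (negative)
    c: float | None = None          # %, large-spine offset
    tau_short1: float = 5.0         # s, rise of the transient volume phase
    tau_short2: float = 250.0       # s, decay of the transient phase
    tau_long1: float = 500.0        # s, rise of the sustained phase
    tau_long2: float = 3000.0       # s, decay of the sustained phase (50 min)
    short_amp_factor: float = 1.75  # transient amplitude = 1 + 1.75 dV_long
    k_inRE: float = 0.1             # #/s, recycling-endosome supply
    l_ltp: bool = False             # late-phase LTP: sustained phase persists

    _L_LTP_TAU = 1.0e9

    def __post_init__(self):
        if self.a is None or self.b is None or self.c is None:
            from .sltp import default_size_dependence
            fit = default_size_dependence()
            self.a = fit.a if self.a is None else self.a
            self.b = fit.b if self.b is None else self.b
            self.c = fit.c if self.c is None else self.c
        if self.l_ltp:
            self.tau_long2 = self._L_LTP_TAU

    def derive_k_outRE(self, V_spine0, S_exo_star):
        """RE export rate pinning ``S_exo* = S_exo0`` at the basal volume."""
        if S_exo_star <= 0:
            raise ValueError("S_exo_star must be > 0")
        return self.k_inRE * V_spine0 / S_exo_star


@dataclass
class CoopParams:
    """Stochastic cooperative-binding lattice parameters.

    A receptor in an empty slot binds at ``k_UB (alpha chi + 1) U/A`` and an
    occupied slot releases at ``k_BU (1 - chi)``, where ``chi`` is the
    occupied fraction of the 8 surrounding lattice sites (fixed denominator 8,
    also at edges; open boundaries).
    """

    alpha: float = 16.0
    k_UB: float = 0.0005       # um^2/(# s)
    k_BU: float = 0.1          # 1/s
    dt: float = 0.2            # s, Bernoulli step
    seed: int | None = None

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0.0 < self.dt <= 0.5):
            raise ValueError("lattice step dt should lie in (0, 0.5] s")
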