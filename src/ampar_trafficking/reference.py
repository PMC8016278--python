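"""Stand-in reference E-LTP curves for the parameter-sampling stage.

The sampling stage compares simulated bound-receptor time courses against
reference EPSP decay curves (with exocytosis intact, and with exocytosis
blocked).  The underlying experimental points are not tabulated anywhere, so
this module generates stand-in references from the same double-transient
family used for the rate pulses: a short induction phase plus a long-lasting
phase, parameterised so that the curves respect the reported envelopes
(E-LTP decays over 1-6 h; with exocytosis blocked it decays within
10-20 min; the induction rise takes under a minute).

All invented coefficients live in ``DEFAULT_REFERENCE``; everything else in
the package is anchored to published parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import PulseSpec

__all__ = ["ReferenceCurve", "DEFAULT_REFERENCE", "epsp_reference",
           "to_receptor_counts", "synth_noisy_curves"]


@dataclass
class ReferenceCurve:
    """Double-transient EPSP reference (% of baseline) for one condition."""

    condition: str                 # "E-LTP" or "k_exo=0"
    C_short: float
    A_short: float
    tau_short1: float
    tau_short2: float
    C_long: float
    A_long: float
    tau_long1: float
    tau_long2: float
    T: float                       # measurement duration for the cost, s

    def value(self, t):
        short = PulseSpec(C=self.C_short, A=self.A_short,
                          tau1=self.tau_short1, tau2=self.tau_short2)
        out = short.value(t)
        if self.A_long > 0 or self.C_long > 0:
            long = PulseSpec(C=self.C_long, A=self.A_long,
                             tau1=self.tau_long1, tau2=self.tau_long2)
            out = out + long.value(t)
        return out

    def grid(self, dt=1.0):
        t = np.arange(0.0, self.T + dt / 2, dt)
        return t, self.value(t)


# Stand-in coefficients (not experimental data): baseline 100% at t=0,
# induction peak ~220% inside the first minutes, decay back toward baseline
# on the 1-6 h scale (E-LTP) or within 10-20 min (blocked exocytosis).
DEFAULT_REFERENCE = {
    "E-LTP": ReferenceCurve(
        condition="E-LTP", C_short=100.0, A_short=90.0,
        tau_short1=20.0, tau_short2=600.0,
        C_long=0.0, A_long=65.0, tau_long1=60.0, tau_long2=9000.0,
        T=7200.0),
    "k_exo=0": ReferenceCurve(
        condition="k_exo=0", C_short=100.0, A_short=110.0,
        tau_short1=20.0, tau_short2=300.0,
        C_long=0.0, A_long=0.0, tau_long1=60.0, tau_long2=9000.0,
        T=1800.0),
}


def epsp_reference(t, curve: ReferenceCurve):
    """Reference EPSP (% of baseline) at time(s) ``t``."""
    return curve.value(np.asarray(t, dtype=float))


def to_receptor_counts(values_pct, B_star):
    """Convert % of baseline EPSP to bound-receptor counts (B_ref)."""
    if B_star <= 0:
        raise ValueError("B_star must be positive")
    return np.asarray(values_pct, dtype=float) / 100.0 * B_star


def synth_noisy_curves(curve: ReferenceCurve, noise_sd, n, seed, dt=1.0):
    """``n`` Gaussian-perturbed samples of the reference curve (for tests).

    Returns (t, array of shape (n, len(t))).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t, ref = curve.grid(dt=dt)
    rng = np.random.default_rng(seed)
    noisy = ref[None, :] + rng.normal(0.0, noise_sd, size=(n, ref.size))
    return t, noisy


def reference_table(dt=1.0):
    """Tidy frame of both default reference conditions (t_s, pct, condition)."""
    frames = []
    for name, curve in DEFAULT_REFERENCE.items():
        t, v = curve.grid(dt=dt)
        frames.append(pd.DataFrame(
            {"t_s": t, "pct_baseline": v, "condition": name}))
    return pd.concat(frames, ignore_index=True)
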