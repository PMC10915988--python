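"""Receptor models: AMPA, phasic GABA-A, tonic extrasynaptic GABA-A, and
GABA-B with a nonlinear G-protein cascade.

Ionotropic receptors (AMPA, GABA-A) follow a peak-normalised
bi-exponential conductance gate.  GABA-B uses a two-stage cascade —
transmitter binds the receptor (fraction ``r``), which drives a G-protein
pool ``s``, and the K+ channel opens as ``s^n / (s^n + K_d)`` — which
makes single presynaptic spikes nearly silent while bursts produce a
large, slow IPSP.  Tonic GABA-A is a constant Cl- conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._kernel import GB_K1, GB_K2, GB_K3, GB_K4, GB_KD, GB_N, E_K

T_UNIT = 0.1  # cleft transmitter per release (a.u.)

__all__ = [
    "ReceptorKind",
    "SynapseSpec",
    "SynapseState",
    "GABABState",
    "biexp_peak_time",
    "synaptic_current",
    "gabab_update",
    "gabab_conductance_fraction",
    "tonic_gabaa_current",
]


class ReceptorKind(str, Enum):
    AMPA = "AMPA"
    GABAA = "GABAA"
    GABAA_tonic = "GABAA_tonic"
    GABAB = "GABAB"


@dataclass
class SynapseSpec:
    receptor: ReceptorKind
    g_max: float            # nS
    E_rev: float            # mV
    rise_tau: float = 0.5   # ms
    decay_tau: float = 5.0  # ms
    latency: float = 1.0    # ms
    weight: float = 1.0

    def __post_init__(self):
        self.receptor = ReceptorKind(self.receptor)
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.latency <= 0:
            raise ValueError("latency must be > 0")
        if self.decay_tau <= self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")


@dataclass
class SynapseState:
    """Bi-exponential gate state: two decaying traces, gate = norm*(d - r)."""

    rise: float = 0.0
    decay: float = 0.0


@dataclass
class GABABState:
    r: float = 0.0  # activated receptor fraction
    s: float = 0.0  # G-protein concentration (a.u.)

    def __post_init__(self):
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [0,1]")
        if self.s < 0:
            raise ValueError("s must be >= 0")


def biexp_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the peak of g(t) = e^{-t/tau_d} - e^{-t/tau_r}."""
    return rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def _gate(spec: SynapseSpec, state: SynapseState) -> float:
    tp = biexp_peak_time(spec.rise_tau, spec.decay_tau)
    norm = 1.0 / (np.exp(-tp / spec.decay_tau) - np.exp(-tp / spec.rise_tau))
    return norm * (state.decay - state.rise)


def deliver_event(state: SynapseState, weight: float = 1.0) -> None:
    state.rise += weight
    state.decay += weight


def advance(spec: SynapseSpec, state: SynapseState, dt: float) -> None:
    state.rise *= np.exp(-dt / spec.rise_tau)
    state.decay *= np.exp(-dt / spec.decay_tau)


def synaptic_current(spec: SynapseSpec, state, V_post: float, t: float = 0.0) -> float:
    """Instantaneous synaptic current in nA (positive = outward).

    For ionotropic kinds ``I = g_max * weight * gate * (V - E_rev)`` with
    the bi-exponential gate; for GABA-B the channel fraction is
    ``s^n / (s^n + K_d)`` and the reversal is E_K.
    """
    if spec.receptor is ReceptorKind.GABAB:
        frac = gabab_conductance_fraction(state)
        g = spec.g_max * spec.weight * frac
        i = g * (V_post - E_K)
    elif spec.receptor is ReceptorKind.GABAA_tonic:
        return tonic_gabaa_current(spec.g_max * spec.weight, V_post, spec.E_rev)
    else:
        g = spec.g_max * spec.weight * _gate(spec, state)
        i = g * (V_post - spec.E_rev)
    i *= 1e-3  # nS * mV -> nA
    if not np.isfinite(i):
        raise FloatingPointError("non-finite synaptic current")
    return float(i)


def gabab_conductance_fraction(state: GABABState) -> float:
    sn = state.s ** GB_N
    return sn / (sn + GB_KD)


def gabab_update(state: GABABState, transmitter_pulse: bool, dt: float) -> GABABState:
    """Advance the G-protein cascade by one step.

    ``transmitter_pulse`` marks steps during which transmitter is present
    in the cleft (set for ~1 ms following each presynaptic spike).  The
    cleft concentration per release, ``T_UNIT``, matches the per-spike
    transmitter increment a single default-weight connection contributes
    in the network kernel, so single releases barely engage the cascade
    while bursts drive it strongly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    T = T_UNIT if transmitter_pulse else 0.0
    r = state.r + dt * (GB_K1 * T * (1.0 - state.r) - GB_K2 * state.r)
    s = state.s + dt * (GB_K3 * state.r - GB_K4 * state.s)
    return GABABState(r=min(max(r, 0.0), 1.0), s=max(s, 0.0))


def tonic_gabaa_current(g_eGABAa: float, V: float, E_Cl: float) -> float:
    """Always-on extrasynaptic GABA-A current, nA (g in nS)."""
    if g_eGABAa < 0:
        raise ValueError("tonic conductance must be >= 0")
    return float(g_eGABAa * (V - E_Cl) * 1e-3)
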