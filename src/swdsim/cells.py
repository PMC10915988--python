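"""Single-compartment neuron models for the 11 cell classes of the network.

Cortical excitatory classes (RS, IB, EF, RIB, ND, plus the substitutable
strongly-bursting SIB variant) and fast-spiking interneurons (FS) use
Traub-Miles spike currents with a slow K+ adaptation current; the
bursting classes additionally carry a low-threshold T-type Ca2+ current.
Thalamocortical relay neurons (TC_FO, TC_HO) carry relay-type T current,
I_h, I_CAN and a K+ leak that sets their resting polarisation; reticular
neurons (NRT_FO, NRT_HO) carry reticular-type T current, a persistent
Na+ current and a slow Ca2+-gated I_CAN whose build-up over repeated
bursts withdraws their output on a seconds timescale.

Maximal conductances are tuned so that each class expresses its defining
firing signature under a standard current-clamp protocol (see
``signature_protocol`` and ``classify_firing_signature``); network results
are expressed as relative scalings of these densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from . import kinetics as kin
from . import _kernel as K

__all__ = [
    "CellType",
    "CellParameters",
    "CellState",
    "VoltageTrace",
    "FiringSignature",
    "default_parameters",
    "load_cell_parameters",
    "gating_steady_state",
    "membrane_derivative",
    "simulate_current_clamp",
    "classify_firing_signature",
    "signature_protocol",
    "pack_parameters",
]

gating_steady_state = kin.gating_steady_state


class CellType(str, Enum):
    RS = "RS"
    IB = "IB"
    EF = "EF"
    RIB = "RIB"
    ND = "ND"
    SIB = "SIB"
    FS = "FS"
    TC_FO = "TC_FO"
    TC_HO = "TC_HO"
    NRT_FO = "NRT_FO"
    NRT_HO = "NRT_HO"


THALAMIC_RELAY = {CellType.TC_FO, CellType.TC_HO}
RETICULAR = {CellType.NRT_FO, CellType.NRT_HO}
CORTICAL_EXC = {CellType.RS, CellType.IB, CellType.EF, CellType.RIB, CellType.ND, CellType.SIB}


class FiringSignature(str, Enum):
    regular_spiking = "regular_spiking"
    intrinsic_burst = "intrinsic_burst"
    fast_spiking = "fast_spiking"
    rebound_burst = "rebound_burst"
    repetitive_burst = "repetitive_burst"
    none = "none"


@dataclass
class CellParameters:
    """Conductance densities (mS/cm^2), capacitance (uF/cm^2), reversals (mV)."""

    cell_type: CellType
    membrane_capacitance: float = 1.0
    g_Na: float = 50.0
    g_K: float = 5.0
    g_leak: float = 0.05
    E_leak: float = -70.0
    g_KL: float = 0.0
    g_T: float = 0.0
    g_CAN: float = 0.0
    g_NaP: float = 0.0
    g_h: float = 0.0
    g_M: float = 0.0
    VT: float = -55.0           # spike-current threshold shift
    tau_M_max: float = 1000.0   # peak I_M time constant (ms)
    E_GABAA: float = -75.0      # phasic GABA-A reversal
    E_Cl: float = -75.0         # tonic GABA-A reversal
    g_tonic: float = 0.0        # extrasynaptic GABA-A conductance
    tau_Ca: float = 150.0       # Ca2+ pool decay (ms)
    ca_gain: float = 1e-4       # Ca2+ influx per unit inward T current
    kd_CAN: float = 1.5e-3      # half-activation [Ca2+] of I_CAN (mM)
    tau_CAN: float = 200.0      # I_CAN activation lag (ms)
    g_GABAB_max: float = 0.0    # maximal GABA-B conductance density
    # current-clamp harness defaults (uA/cm^2)
    step_amplitude: float = 1.0
    hyper_amplitude: float = -1.0

    def __post_init__(self):
        self.cell_type = CellType(self.cell_type)
        for name in ("g_Na", "g_K", "g_leak", "g_KL", "g_T", "g_CAN",
                     "g_NaP", "g_h", "g_M", "g_tonic", "g_GABAB_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cell_type in THALAMIC_RELAY | RETICULAR:
            if self.g_T <= 0:
                raise ValueError(f"{self.cell_type.value}: g_T must be > 0")
            if self.g_CAN <= 0:
                raise ValueError(f"{self.cell_type.value}: g_CAN must be > 0")
        if self.cell_type in RETICULAR and self.g_NaP <= 0:
            raise ValueError(f"{self.cell_type.value}: g_NaP must be > 0")

    @property
    def it_kind(self) -> int:
        if self.cell_type in RETICULAR:
            return 2
        return 1

    def scaled(self, **factors) -> "CellParameters":
        """Return a copy with named conductances multiplied by a factor."""
        changes = {k: getattr(self, k) * v for k, v in factors.items()}
        return replace(self, **changes)


@dataclass
class CellState:
    """Instantaneous state of one neuron."""

    V: float
    gating: dict = field(default_factory=dict)
    Ca_i: float = K.CA_REST
    last_spike_time: Optional[float] = None

    def __post_init__(self):
        for name, x in self.gating.items():
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gating variable {name} outside [0,1]: {x}")
        if self.Ca_i <= 0:
            raise ValueError("Ca_i must be > 0")


@dataclass
class VoltageTrace:
    t: np.ndarray           # ms
    V: np.ndarray           # mV
    spike_times: np.ndarray  # ms
    dt: float
    I_inj: Optional[np.ndarray] = None


def resting_state(params: CellParameters, V: float = -70.0) -> CellState:
    gating = {}
    VT = params.VT
    gating["m_Na"] = float(kin._na_m(V, VT)[0])
    gating["h_Na"] = float(kin._na_h(V, VT)[0])
    gating["n_K"] = float(kin._k_n(V, VT)[0])
    gating["p_M"] = float(kin._m_p_inf(V))
    if params.it_kind == 2:
        gating["m_T"] = float(kin._t_nrt_m_inf(V))
        gating["h_T"] = float(kin._t_nrt_h_inf(V))
    else:
        gating["m_T"] = float(kin._t_tc_m_inf(V))
        gating["h_T"] = float(kin._t_tc_h_inf(V))
    gating["m_h"] = float(kin._h_m_inf(V))
    gating["m_NaP"] = float(kin._nap_m_inf(V))
    gating["m_CAN"] = 0.0
    return CellState(V=V, gating=gating)


def membrane_derivative(state: CellState, params: CellParameters,
                        I_syn: float = 0.0, I_inj: float = 0.0) -> dict:
    """Reference right-hand side of the current-balance equation.

    Returns a dict with ``dV`` (mV/ms) and ``d<gate>`` entries.  Currents
    follow I_x = g_x * gates * (V - E_x); only currents with nonzero
    maximal conductance contribute.  Raises ``FloatingPointError`` naming
    the offending current on any non-finite term.
    """
    V = state.V
    g = state.gating
    VT = params.VT
    terms = {}
    terms["I_Na"] = params.g_Na * g["m_Na"] ** 3 * g["h_Na"] * (V - K.E_NA)
    terms["I_K"] = params.g_K * g["n_K"] ** 4 * (V - K.E_K)
    terms["I_M"] = params.g_M * g["p_M"] * (V - K.E_K)
    terms["I_T"] = params.g_T * g["m_T"] ** 2 * g["h_T"] * (V - K.E_T)
    terms["I_h"] = params.g_h * g["m_h"] * (V - K.E_H)
    terms["I_NaP"] = params.g_NaP * g["m_NaP"] * (V - K.E_NA)
    terms["I_CAN"] = params.g_CAN * g.get("m_CAN", 0.0) * (V - K.E_CAN)
    terms["I_leak"] = params.g_leak * (V - params.E_leak)
    terms["I_KL"] = params.g_KL * (V - K.E_K)
    terms["I_tonic"] = params.g_tonic * (V - params.E_Cl)
    for name, val in terms.items():
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite term in {name}: {val}")
    dV = -(sum(terms.values()) + I_syn - I_inj) / params.membrane_capacitance

    out = {"dV": float(dV)}
    it_prefix = "I_T_NRT" if params.it_kind == 2 else "I_T"
    pairs = {
        "m_Na": ("I_Na", "m"), "h_Na": ("I_Na", "h"), "n_K": ("I_K", "n"),
        "p_M": ("I_M", "p"), "m_T": (it_prefix, "m"), "h_T": (it_prefix, "h"),
        "m_h": ("I_h", "m"), "m_NaP": ("I_NaP", "m"),
    }
    for gate, (cur, var) in pairs.items():
        if gate not in g:
            continue
        if cur.startswith("I_Na") or cur == "I_K":
            # threshold-shifted spike currents
            shifted = V - (VT - (-55.0))
            inf = kin.gating_steady_state(cur, var, shifted)
            tau = kin.gating_time_constant(cur, var, shifted)
        else:
            inf = kin.gating_steady_state(cur, var, V)
            tau = kin.gating_time_constant(cur, var, V)
        out["d" + gate] = (inf - g[gate]) / tau
    return out


def pack_parameters(params: CellParameters) -> np.ndarray:
    """Flatten a CellParameters into the kernel parameter row."""
    row = np.zeros(K.NP)
    row[K.IP_C] = params.membrane_capacitance
    row[K.IP_GNA] = params.g_Na
    row[K.IP_GK] = params.g_K
    row[K.IP_GL] = params.g_leak
    row[K.IP_EL] = params.E_leak
    row[K.IP_GKL] = params.g_KL
    row[K.IP_GT] = params.g_T
    row[K.IP_GCAN] = params.g_CAN
    row[K.IP_GNAP] = params.g_NaP
    row[K.IP_GH] = params.g_h
    row[K.IP_GM] = params.g_M
    row[K.IP_EGABAA] = params.E_GABAA
    row[K.IP_ECL] = params.E_Cl
    row[K.IP_GTONIC] = params.g_tonic
    row[K.IP_TAUCA] = params.tau_Ca
    row[K.IP_CAGAIN] = params.ca_gain
    row[K.IP_KDCAN] = params.kd_CAN
    row[K.IP_TAUCAN] = params.tau_CAN
    row[K.IP_GBBAR] = params.g_GABAB_max
    return row


def simulate_current_clamp(params: CellParameters, protocol, dt: float = 0.025,
                           V0: float = -70.0) -> VoltageTrace:
    """Integrate one neuron under a piecewise-constant injected current.

    ``protocol`` is a sequence of ``(amplitude_uA_cm2, duration_ms)``
    steps.  Deterministic given inputs.  Raises ``RuntimeError`` on
    numerical blow-up.
    """
    if dt > 0.05 or dt <= 0:
        raise ValueError("dt must lie in (0, 0.05] ms")
    segs = [(float(a), float(d)) for a, d in protocol]
    if not all(np.isfinite(a) and d > 0 for a, d in segs):
        raise ValueError("protocol amplitudes must be finite, durations > 0")
    n_steps = int(round(sum(d for _, d in segs) / dt))
    I = np.zeros(n_steps)
    k0 = 0
    for a, d in segs:
        k1 = k0 + int(round(d / dt))
        I[k0:k1] = a
        k0 = k1
    A, B = kin.build_gating_tables(params.VT, params.tau_M_max, params.it_kind, dt)
    row = pack_parameters(params)
    V, spikes, _, blow = K.run_single_cell(row, A, B, dt, I, V0, False)
    if blow:
        raise RuntimeError(
            f"integration failure for {params.cell_type.value}: |V| exceeded bounds")
    t = np.arange(n_steps) * dt
    return VoltageTrace(t=t, V=V, spike_times=spikes, dt=dt, I_inj=I)


# ---------------------------------------------------------------------------
# firing-signature classification
# ---------------------------------------------------------------------------

BURST_ISI = 10.0          # ms, max ISI inside a burst
REBOUND_WINDOW = 350.0    # ms after release from hyperpolarisation
HYPER_LEVEL = -75.0       # mV, qualifying hyperpolarisation


def _bursts(spike_times: np.ndarray):
    """Group spikes into bursts (>=2 spikes, ISI <= BURST_ISI)."""
    groups = []
    cur = [spike_times[0]] if len(spike_times) else []
    for t0, t1 in zip(spike_times[:-1], spike_times[1:]):
        if t1 - t0 <= BURST_ISI:
            cur.append(t1)
        else:
            groups.append(cur)
            cur = [t1]
    if cur:
        groups.append(cur)
    return [g for g in groups if len(g) >= 2], groups


def classify_firing_signature(trace: VoltageTrace,
                              spike_times: Optional[np.ndarray] = None) -> FiringSignature:
    """Classify a current-clamp response into its firing signature.

    Criteria: a burst is >=2 spikes at ISIs <= 10 ms; a rebound burst is a
    burst starting within 350 ms of release from a >=100 ms period below
    -75 mV; repetitive bursting is >=3 bursts; an intrinsic burst is a
    burst at response onset followed by non-burst firing or silence;
    fast spiking is high-rate tonic firing with ISI CV < 0.2 and < 20%
    adaptation; everything else with sustained firing is regular spiking.
    """
    if trace.t.size == 0:
        raise ValueError("empty voltage trace")
    if trace.t[-1] < 1000.0:
        raise ValueError("trace must cover at least 1 s")
    st = np.asarray(trace.spike_times if spike_times is None else spike_times, dtype=float)
    if st.size == 0:
        return FiringSignature.none

    bursts, groups = _bursts(st)

    # rebound: release from sustained *imposed* hyperpolarisation, i.e. a
    # period both below HYPER_LEVEL and clearly below the pre-stimulus
    # baseline.  The baseline is the upper envelope (90th percentile) of
    # the subthreshold voltage early in the trace, which is robust to
    # intrinsic subthreshold oscillations.
    n_base = min(int(400.0 / trace.dt), trace.t.size)
    v0 = trace.V[:n_base]
    sub = v0[v0 < -50.0]
    baseline = float(np.percentile(sub, 90)) if sub.size else float(np.median(v0))
    below = (trace.V <= HYPER_LEVEL) & (trace.V <= baseline - 4.0)
    if below.any():
        edges = np.flatnonzero(np.diff(below.astype(int)) == -1)
        run_start = np.flatnonzero(np.diff(np.r_[0, below.astype(int)]) == 1)
        # a qualifying release must coincide with the withdrawal of an
        # injected hyperpolarising current, so that intrinsic oscillations
        # whose troughs dip below the threshold do not count as rebounds
        jumps = None
        if trace.I_inj is not None:
            dI = np.diff(trace.I_inj)
            up = (dI > 1e-12) & (trace.I_inj[:-1] < -1e-12)
            jumps = trace.t[1:][up]
        for e in edges:
            starts = run_start[run_start <= e]
            if starts.size and (e - starts[-1]) * trace.dt >= 100.0:
                t_rel = trace.t[e]
                if jumps is not None and not np.any(np.abs(jumps - t_rel) <= 30.0):
                    continue
                for b in bursts:
                    if 0.0 <= b[0] - t_rel <= REBOUND_WINDOW:
                        return FiringSignature.rebound_burst

    if len(bursts) >= 3:
        return FiringSignature.repetitive_burst
    if bursts:
        first_group_is_burst = len(groups[0]) >= 2
        if first_group_is_burst:
            return FiringSignature.intrinsic_burst
        return FiringSignature.repetitive_burst

    if st.size >= 6:
        isi = np.diff(st)
        cv = isi.std() / isi.mean()
        # adaptation over the steady response
        adapt = isi[-1] / isi[0] if isi[0] > 0 else np.inf
        rate = 1000.0 * st.size / (trace.t[-1] - st[0] + 1e-9)
        if cv < 0.2 and adapt < 1.2 and rate > 40.0:
            return FiringSignature.fast_spiking
    if st.size >= 4:
        return FiringSignature.regular_spiking
    return FiringSignature.none


def signature_protocol(cell_type: CellType, params: CellParameters):
    """Standard protocol and intended signature for a cell class."""
    ct = CellType(cell_type)
    if ct in THALAMIC_RELAY or ct in RETICULAR:
        proto = [(0.0, 500.0), (params.hyper_amplitude, 500.0), (0.0, 600.0)]
        return proto, FiringSignature.rebound_burst
    proto = [(0.0, 500.0), (params.step_amplitude, 1500.0)]
    expected = {
        CellType.RS: FiringSignature.regular_spiking,
        CellType.IB: FiringSignature.intrinsic_burst,
        CellType.EF: FiringSignature.intrinsic_burst,
        CellType.RIB: FiringSignature.repetitive_burst,
        CellType.ND: FiringSignature.repetitive_burst,
        CellType.SIB: FiringSignature.repetitive_burst,
        CellType.FS: FiringSignature.fast_spiking,
    }[ct]
    return proto, expected


# ---------------------------------------------------------------------------
# shipped parameter sets
# ---------------------------------------------------------------------------

def load_cell_parameters(cell_type) -> CellParameters:
    """Load the shipped parameter file for one cell class."""
    ct = CellType(cell_type)
    ref = resources.files("swdsim") / "configs" / "cells" / f"{ct.value}.yaml"
    data = yaml.safe_load(ref.read_text())
    data["cell_type"] = ct
    return CellParameters(**data)


def default_parameters() -> dict:
    """All 11 shipped parameter sets, keyed by CellType."""
    return {ct: load_cell_parameters(ct) for ct in CellType}
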