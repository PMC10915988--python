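"""Time-stepped network integration with perturbation scheduling.

The engine flattens a ``NetworkSpec`` into per-neuron parameter arrays,
pre-computes gating tables per cell type, and hands everything to the
compiled fixed-step kernel.  Conductance perturbations are applied
multiplicatively to the named population from their onset onward.  The
EEG proxy is the negated sum of AMPA, GABA-A and GABA-B synaptic
currents onto cortical excitatory neurons, averaged into 1 ms bins and
mean-subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel as K
from .cells import CellType, pack_parameters
from .kinetics import build_gating_tables, N_GATES, V_GRID_MIN, V_GRID_STEP
from .network import NetworkSpec, resolve_populations

__all__ = [
    "SimulationConfig",
    "PerturbationEvent",
    "SimulationResult",
    "run_simulation",
    "apply_perturbation",
    "compute_eeg",
    "CONDUCTANCE_KINDS",
]

#: perturbable conductances -> kernel kind codes
CONDUCTANCE_KINDS = {
    "g_KL": 0, "g_T": 1, "g_CAN": 2, "g_eGABAa": 3,
    "g_GABAa": 4, "g_AMPA": 5, "g_GABAb": 6,
}

#: kinds that scale an intrinsic parameter column (checked against baseline)
_INTRINSIC_COLS = {0: K.IP_GKL, 1: K.IP_GT, 2: K.IP_GCAN, 3: K.IP_GTONIC}


@dataclass
class SimulationConfig:
    duration: float                  # ms
    dt: float = 0.025                # ms
    seed: int = 0
    state_label: str = "sleep_wake_transition"
    record_voltage_ids: tuple = ()
    eeg_rate: float = 1000.0         # Hz; fixed by the 1 ms kernel binning
    max_rate_hz: float = 300.0       # per-neuron spike capacity estimate

    def __post_init__(self):
        if not (0 < self.dt <= 0.05):
            raise ValueError("dt must lie in (0, 0.05] ms")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.state_label not in ("wake", "sleep_wake_transition"):
            raise ValueError("state_label must be 'wake' or 'sleep_wake_transition'")


@dataclass
class PerturbationEvent:
    population: str
    conductance: str
    scale: float
    onset: float = 0.0   # ms

    def __post_init__(self):
        if self.conductance not in CONDUCTANCE_KINDS:
            raise ValueError(
                f"unknown conductance {self.conductance!r}; "
                f"known: {sorted(CONDUCTANCE_KINDS)}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0 (0 blocks the conductance)")


@dataclass
class SimulationResult:
    spike_times: np.ndarray     # ms, chronological
    spike_ids: np.ndarray
    eeg: np.ndarray             # mean-subtracted, eeg_rate samples/s
    eeg_rate: float
    voltages: dict              # neuron id -> 1 kHz trace
    perturbation_log: list
    config: SimulationConfig
    network_hash: str
    neurons: "object" = None    # the network's neuron table

    @property
    def duration(self) -> float:
        return self.config.duration

    def spikes_by_neuron(self, ids) -> dict:
        out = {}
        for i in np.atleast_1d(ids):
            out[int(i)] = self.spike_times[self.spike_ids == i]
        return out

    def population_spike_times(self, network_or_ids, population: str = None) -> np.ndarray:
        if population is None:
            ids = np.asarray(network_or_ids)
        else:
            ids = network_or_ids.population_ids(population)
        mask = np.isin(self.spike_ids, ids)
        return self.spike_times[mask]


def apply_perturbation(network_state: dict, event: PerturbationEvent) -> dict:
    """Scale the named conductance of every member of a population.

    ``network_state`` holds the packed arrays (``P``: parameter rows,
    ``gain``: postsynaptic receptor gains, ``pop_of``: population name
    per neuron).  Multiplicative, idempotent per event; a scale of 0
    removes the current entirely.  Raises on a conductance the
    population does not express (e.g. g_eGABAa on cortical cells).
    """
    pops = resolve_populations(event.population)
    idx = np.flatnonzero(np.isin(network_state["pop_of"], pops))
    if idx.size == 0:
        raise ValueError(f"population {event.population!r} has no members")
    kind = CONDUCTANCE_KINDS[event.conductance]
    state = {k: (v.copy() if isinstance(v, np.ndarray) else v)
             for k, v in network_state.items()}
    if kind in _INTRINSIC_COLS:
        col = _INTRINSIC_COLS[kind]
        if not np.any(state["P"][idx, col] > 0):
            raise ValueError(
                f"population {event.population!r} does not express "
                f"{event.conductance}")
        state["P"][idx, col] *= event.scale
    else:
        gcol = {4: 1, 5: 0, 6: 2}[kind]
        state["gain"][idx, gcol] *= event.scale
    return state


def _perturbation_index(event: PerturbationEvent, neurons) -> np.ndarray:
    pops = resolve_populations(event.population)
    return neurons.loc[neurons.population.isin(pops), "id"].to_numpy()


def compute_eeg(raw_sum: np.ndarray) -> np.ndarray:
    """Mean-subtract the kernel's summed synaptic-current trace."""
    raw_sum = np.asarray(raw_sum, dtype=float)
    if raw_sum.size == 0:
        raise ValueError("no cortical synaptic currents recorded")
    return raw_sum - raw_sum.mean()


def _initial_state(P, type_tables, type_id, seed):
    rng = np.random.default_rng((seed ^ 0x9E3779B9) % 2 ** 31)
    N = P.shape[0]
    V0 = -70.0 + 4.0 * rng.standard_normal(N)
    gates0 = np.empty((N, N_GATES))
    AT = type_tables[0]
    for i in range(N):
        f = (V0[i] - V_GRID_MIN) / V_GRID_STEP
        i0 = int(np.clip(f, 0, AT.shape[2] - 2))
        w = f - i0
        a = AT[type_id[i], :, i0]
        gates0[i] = a + (AT[type_id[i], :, i0 + 1] - a) * w
    return V0, gates0


def run_simulation(network: NetworkSpec, config: SimulationConfig,
                   perturbations=()) -> SimulationResult:
    """Integrate the network and return spikes, EEG and voltage traces."""
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    neurons = network.neurons
    N = len(neurons)
    ids = neurons.id.to_numpy()
    if not np.array_equal(ids, np.arange(N)):
        raise ValueError("neuron ids must be contiguous from 0")

    state_cfg = network.config.get("states", {}).get(config.state_label, {})
    gkl_factor = float(state_cfg.get("g_KL_factor", 1.0))
    drive_factor = float(state_cfg.get("drive_factor", 1.0))

    P = np.empty((N, K.NP))
    for i, row in enumerate(neurons.itertuples()):
        P[i] = pack_parameters(network.cell_params[row.id])
    P[:, K.IP_GKL] *= gkl_factor

    # gating tables per distinct cell type
    type_keys = sorted(set(neurons.cell_type))
    key_index = {k: j for j, k in enumerate(type_keys)}
    type_id = np.array([key_index[t] for t in neurons.cell_type], dtype=np.int64)
    tabsA, tabsB = [], []
    for tkey in type_keys:
        cp = network.cell_params[int(neurons.loc[neurons.cell_type == tkey, "id"].iloc[0])]
        A, B = build_gating_tables(cp.VT, cp.tau_M_max, cp.it_kind, dt)
        tabsA.append(A)
        tabsB.append(B)
    AT = np.stack(tabsA)
    BT = np.stack(tabsB)

    # connections -> CSR by presynaptic neuron
    conn = network.connections
    rec_code = conn.receptor.map({"AMPA": 0, "GABAA": 1, "GABAB": 2}).to_numpy()
    order = np.argsort(conn.pre_id.to_numpy(), kind="stable")
    pre = conn.pre_id.to_numpy()[order].astype(np.int64)
    post = conn.post_id.to_numpy()[order].astype(np.int64)
    rec = rec_code[order].astype(np.int64)
    w = conn.weight.to_numpy()[order].astype(float)
    dsteps = np.maximum(1, np.round(conn.latency.to_numpy()[order] / dt)).astype(np.int64)
    conn_ptr = np.zeros(N + 1, dtype=np.int64)
    np.add.at(conn_ptr, pre + 1, 1)
    conn_ptr = np.cumsum(conn_ptr)
    L = int(dsteps.max()) + 1 if len(dsteps) else 2
    buf = np.zeros((L, N, 3))

    gain = np.ones((N, 3))

    # background drive
    bg_rate = np.zeros(N)
    bg_w = np.zeros(N)
    for group, spec in network.config.get("background", {}).items():
        gidx = np.flatnonzero(neurons.population.isin(resolve_populations(group)))
        bg_rate[gidx] = spec["rate"] * drive_factor / 1000.0  # events per ms
        bg_w[gidx] = spec["weight"]

    # perturbation schedule
    events = sorted(perturbations, key=lambda e: e.onset)
    plog = []
    p_step, p_kind, p_scale, p_idx_parts = [], [], [], []
    pop_of = neurons.population.to_numpy()
    probe = {"P": P, "gain": gain, "pop_of": pop_of}
    for ev in events:
        if ev.onset >= config.duration:
            raise ValueError(f"perturbation onset {ev.onset} beyond duration")
        apply_perturbation(probe, ev)  # validation only (on copies)
        idx = _perturbation_index(ev, neurons)
        p_step.append(int(round(ev.onset / dt)))
        p_kind.append(CONDUCTANCE_KINDS[ev.conductance])
        p_scale.append(ev.scale)
        p_idx_parts.append(idx)
        plog.append({"population": ev.population, "conductance": ev.conductance,
                     "scale": ev.scale, "onset": ev.onset})
    p_ptr = np.zeros(len(events) + 1, dtype=np.int64)
    for j, part in enumerate(p_idx_parts):
        p_ptr[j + 1] = p_ptr[j] + len(part)
    p_idx = (np.concatenate(p_idx_parts).astype(np.int64)
             if p_idx_parts else np.empty(0, dtype=np.int64))

    eeg_mask = neurons.population.str.endswith("_E").to_numpy().astype(np.int64)
    vrec_ids = np.asarray(config.record_voltage_ids, dtype=np.int64)

    V0, gates0 = _initial_state(P, (AT, BT), type_id, config.seed)

    cap = int(N * config.duration / 1000.0 * config.max_rate_hz) + 1000
    spk_t = np.empty(cap)
    spk_id = np.empty(cap, dtype=np.int64)

    eeg_raw, vrec, n_spk, status, fail_t, fail_id = K.run_network(
        P, type_id, AT, BT, dt, n_steps,
        conn_ptr, post, rec, w, dsteps,
        buf, gain, bg_rate, bg_w,
        np.asarray(p_step, dtype=np.int64), np.asarray(p_kind, dtype=np.int64),
        np.asarray(p_scale, dtype=float), p_ptr, p_idx,
        eeg_mask, vrec_ids, config.seed % 2 ** 31,
        V0, gates0, spk_t, spk_id,
    )
    if status == 1:
        raise RuntimeError(
            f"numerical instability at t = {fail_t:.2f} ms in neuron {fail_id}")
    if status == 2:
        import warnings
        warnings.warn("spike capacity exceeded; spike record truncated")

    voltages = {int(i): vrec[j] for j, i in enumerate(vrec_ids)}
    return SimulationResult(
        spike_times=spk_t[:n_spk].copy(), spike_ids=spk_id[:n_spk].copy(),
        eeg=compute_eeg(eeg_raw), eeg_rate=1000.0,
        voltages=voltages, perturbation_log=plog, config=config,
        network_hash=network.content_hash(), neurons=neurons,
    )
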