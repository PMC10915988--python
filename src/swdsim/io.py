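"""Reading and writing simulation results.

Results go to HDF5 (``/spikes/<population>`` as ragged time/id pairs,
``/eeg`` at 1 kHz, ``/voltages/<id>``, ``/meta`` attributes) or to plain
CSV (spikes: ``neuron_id,time_ms``; EEG: ``time_ms,value``), so that
simulated and synthetic data are interchangeable inputs to the analysis
stack.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .engine import SimulationConfig, SimulationResult

__all__ = [
    "write_result_h5",
    "read_result_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_eeg_csv",
    "read_eeg_csv",
]


def write_result_h5(path, result: SimulationResult, network=None) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("spikes")
        g.create_dataset("times", data=result.spike_times)
        g.create_dataset("ids", data=result.spike_ids)
        if network is not None:
            pops = network.neurons.population.to_numpy().astype("S")
            fh.create_dataset("population_of", data=pops)
        fh.create_dataset("eeg", data=result.eeg)
        vg = fh.create_group("voltages")
        for i, trace in result.voltages.items():
            vg.create_dataset(str(i), data=trace)
        meta = fh.create_group("meta")
        meta.attrs["eeg_rate"] = result.eeg_rate
        meta.attrs["duration"] = result.config.duration
        meta.attrs["dt"] = result.config.dt
        meta.attrs["seed"] = result.config.seed
        meta.attrs["state_label"] = result.config.state_label
        meta.attrs["network_hash"] = result.network_hash
        meta.attrs["perturbations"] = json.dumps(result.perturbation_log)


def read_result_h5(path) -> SimulationResult:
    with h5py.File(path, "r") as fh:
        meta = fh["meta"].attrs
        cfg = SimulationConfig(duration=float(meta["duration"]), dt=float(meta["dt"]),
                               seed=int(meta["seed"]), state_label=str(meta["state_label"]))
        voltages = {int(k): v[...] for k, v in fh["voltages"].items()}
        return SimulationResult(
            spike_times=fh["spikes/times"][...],
            spike_ids=fh["spikes/ids"][...],
            eeg=fh["eeg"][...], eeg_rate=float(meta["eeg_rate"]),
            voltages=voltages,
            perturbation_log=json.loads(meta["perturbations"]),
            config=cfg, network_hash=str(meta["network_hash"]),
        )


def write_spikes_csv(path, spike_ids, spike_times) -> None:
    pd.DataFrame({"neuron_id": np.asarray(spike_ids, dtype=int),
                  "time_ms": np.asarray(spike_times, dtype=float)}).to_csv(path, index=False)


def read_spikes_csv(path):
    df = pd.read_csv(path)
    return df.neuron_id.to_numpy(), df.time_ms.to_numpy()


def write_eeg_csv(path, eeg, rate: float = 1000.0) -> None:
    t = np.arange(len(eeg)) / rate * 1000.0
    pd.DataFrame({"time_ms": t, "value": np.asarray(eeg, dtype=float)}).to_csv(path, index=False)


def read_eeg_csv(path):
    df = pd.read_csv(path)
    t = df.time_ms.to_numpy()
    rate = 1000.0 / np.median(np.diff(t))
    return df.value.to_numpy(), rate
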