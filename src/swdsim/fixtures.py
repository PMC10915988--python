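"""Synthetic ground-truth generators for testing the analysis stack.

``generate_synthetic_eeg`` writes spike-and-wave seizures — each cycle a
sharp Gaussian transient ("spike") followed by a slower half-sine
("wave") — into a pink-noise interictal background, returning the exact
ictal intervals and spike-peak times.  ``generate_locked_spikes`` emits
per-population spike trains phase-locked to those cycles with
configurable lags, jitter and firing modes.  These are test instruments,
not biophysical simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import IctalSegmentation

__all__ = ["SyntheticSWDSpec", "generate_synthetic_eeg", "generate_locked_spikes"]


@dataclass
class SyntheticSWDSpec:
    swd_frequency: float = 4.0        # Hz
    n_seizures: int = 3
    seizure_durations: tuple = (10.0,)     # s, cycled over seizures
    interictal_durations: tuple = (15.0,)  # s, cycled; also leads the trace
    spike_amplitude: float = 5.0      # a.u.
    wave_amplitude: float = 2.0       # a.u.
    noise_sd: float = 0.5             # a.u., pink-noise SD
    sampling_rate: float = 1000.0     # Hz
    spike_width_ms: float = 12.0      # Gaussian sigma of the sharp transient
    population_lags: dict = field(default_factory=dict)   # name -> ms (neg = leads)
    firing_mode: dict = field(default_factory=dict)       # name -> mode dict
    jitter_ms: float = 0.0
    n_neurons_per_population: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.swd_frequency <= 0:
            raise ValueError("swd_frequency must be > 0")
        if any(d <= 0 for d in self.seizure_durations) or \
           any(d <= 0 for d in self.interictal_durations):
            raise ValueError("durations must be > 0")


def _pink_noise(n, rng):
    """1/f-shaped Gaussian noise, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / (x.std() + 1e-300)


def generate_synthetic_eeg(spec: SyntheticSWDSpec):
    """Synthesise an EEG trace with known spike-and-wave seizures.

    Returns ``(eeg, segmentation)`` where the segmentation holds the
    exact ground-truth ictal intervals, spike-peak times, cycle
    boundaries and frequency.
    """
    fs = spec.sampling_rate
    rng = np.random.default_rng(spec.seed)
    period_s = 1.0 / spec.swd_frequency

    seiz = [spec.seizure_durations[i % len(spec.seizure_durations)]
            for i in range(spec.n_seizures)]
    inter = [spec.interictal_durations[i % len(spec.interictal_durations)]
             for i in range(spec.n_seizures + 1)]
    total_s = sum(seiz) + sum(inter)
    n = int(round(total_s * fs))
    eeg = np.zeros(n)
    if spec.noise_sd > 0:
        eeg += spec.noise_sd * _pink_noise(n, rng)

    intervals, spike_lists, cycle_lists, freqs = [], [], [], []
    t_cursor = inter[0]
    tgrid = np.arange(n) / fs
    sigma_s = spec.spike_width_ms / 1000.0
    for k, dur in enumerate(seiz):
        n_cycles = int(np.floor(dur / period_s + 1e-9))
        spikes = []
        for c in range(n_cycles):
            t_spike = t_cursor + c * period_s + 0.5 * period_s
            spikes.append(t_spike * 1000.0)
            # sharp positive transient
            w = np.abs(tgrid - t_spike) < 5 * sigma_s
            eeg[w] += spec.spike_amplitude * np.exp(
                -0.5 * ((tgrid[w] - t_spike) / sigma_s) ** 2)
            # slow negative half-sine wave filling the rest of the cycle
            w0 = t_spike + 2 * sigma_s
            w1 = t_spike + period_s - 2 * sigma_s
            m = (tgrid >= w0) & (tgrid < w1)
            eeg[m] -= spec.wave_amplitude * np.sin(
                np.pi * (tgrid[m] - w0) / (w1 - w0))
        spikes = np.asarray(spikes)
        half = 0.5 * period_s * 1000.0
        mids = 0.5 * (spikes[:-1] + spikes[1:])
        bounds = np.r_[spikes[0] - half, mids, spikes[-1] + half]
        intervals.append((t_cursor * 1000.0, (t_cursor + dur) * 1000.0))
        spike_lists.append(spikes)
        cycle_lists.append(bounds)
        freqs.append(spec.swd_frequency)
        t_cursor += dur + inter[k + 1]

    seg = IctalSegmentation(ictal_intervals=intervals, swd_spike_times=spike_lists,
                            cycle_boundaries=cycle_lists, dominant_frequency=freqs)
    return eeg, seg


def generate_locked_spikes(spec: SyntheticSWDSpec, segmentation: IctalSegmentation):
    """Per-population spike trains locked to the SWD cycles.

    Each population ``name`` fires according to ``spec.population_lags``
    (ms relative to the cycle spike peak, negative = leads) and
    ``spec.firing_mode`` entries like ``{"mode": "burst"}`` (3 APs at
    4 ms ISI), ``{"mode": "tonic"}`` (single AP) or
    ``{"mode": "silent"}``; optional key ``"p_fire"`` thins cycles.
    Returns ``{population: {neuron_index: spike_times_ms}}``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    out = {}
    for name, lag in spec.population_lags.items():
        mode_cfg = dict(spec.firing_mode.get(name, {"mode": "tonic"}))
        mode = mode_cfg.get("mode", "tonic")
        p_fire = float(mode_cfg.get("p_fire", 1.0))
        trains = {i: [] for i in range(spec.n_neurons_per_population)}
        if mode != "silent":
            for spikes in segmentation.swd_spike_times:
                for t_spike in spikes:
                    for i in range(spec.n_neurons_per_population):
                        if rng.random() > p_fire:
                            continue
                        t0 = t_spike + lag + (spec.jitter_ms * rng.standard_normal()
                                              if spec.jitter_ms > 0 else 0.0)
                        if mode == "burst":
                            trains[i].extend([t0, t0 + 4.0, t0 + 8.0])
                        else:
                            trains[i].append(t0)
        out[name] = {i: np.asarray(sorted(v)) for i, v in trains.items()}
    return out
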