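"""Topographic construction of the six-sector corticothalamic network.

The default network holds 900 neurons: four cortical layers (L2/3, L4,
L5, L6), each divided into an excitatory subsector of 100 cells (a mix
of RS, IB, EF, RIB and ND classes) and an inhibitory subsector of 50 FS
interneurons, plus a first-order and a higher-order thalamic sector,
each with 100 thalamocortical relay neurons reciprocally coupled to 50
reticular (NRT) neurons.

Neurons occupy pseudo-random positions on a one-dimensional row per
subsector; the rows stack into the model's two-dimensional sheet.
Projections are topographic: each source neuron contacts the targets
whose normalised positions fall within a projection radius ``P``
(``radius_P`` neighbours each side of its matched location), never
itself, and at most once per target.  A divisor ``scale`` shrinks every
subsector (and radius) proportionally for desk-scale runs.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cells import CellParameters, CellType, load_cell_parameters
from .synapses import ReceptorKind

__all__ = [
    "SubsectorSpec",
    "ProjectionSpec",
    "NetworkSpec",
    "place_neurons",
    "build_projection",
    "build_default_network",
    "substitute_sib",
    "load_network_config",
    "CORTICAL_LAYERS",
    "POPULATIONS",
]

CORTICAL_LAYERS = ("L23", "L4", "L5", "L6")
POPULATIONS = (
    "L23_E", "L23_I", "L4_E", "L4_I", "L5_E", "L5_I", "L6_E", "L6_I",
    "TC_FO", "NRT_FO", "TC_HO", "NRT_HO",
)

#: named groups accepted wherever a population is addressed
POPULATION_GROUPS = {
    "cortex": [p for p in POPULATIONS if p.startswith("L")],
    "cortex_E": [p for p in POPULATIONS if p.endswith("_E")],
    "cortex_I": [p for p in POPULATIONS if p.endswith("_I")],
    "TC": ["TC_FO", "TC_HO"],
    "NRT": ["NRT_FO", "NRT_HO"],
    "thalamus": ["TC_FO", "NRT_FO", "TC_HO", "NRT_HO"],
    "all": list(POPULATIONS),
}


def resolve_populations(name: str) -> list:
    if name in POPULATION_GROUPS:
        return list(POPULATION_GROUPS[name])
    if name in POPULATIONS:
        return [name]
    raise KeyError(f"unknown population {name!r}; known: {POPULATIONS + tuple(POPULATION_GROUPS)}")


@dataclass
class SubsectorSpec:
    name: str
    composition: dict          # CellType -> count
    layer: str = ""

    @property
    def excitatory_count(self) -> int:
        return sum(n for ct, n in self.composition.items()
                   if CellType(ct) not in (CellType.FS,))

    @property
    def inhibitory_count(self) -> int:
        return sum(n for ct, n in self.composition.items()
                   if CellType(ct) in (CellType.FS,))

    @property
    def total(self) -> int:
        return sum(self.composition.values())


@dataclass
class ProjectionSpec:
    source: str
    target: str
    radius_P: int
    receptor: ReceptorKind
    weight: float
    latency_range: tuple = (1.0, 3.0)

    def __post_init__(self):
        self.receptor = ReceptorKind(self.receptor)
        if self.radius_P < 1:
            raise ValueError("radius_P must be >= 1")
        if self.latency_range[0] <= 0:
            raise ValueError("latencies must be > 0")


@dataclass
class NetworkSpec:
    neurons: pd.DataFrame          # id, population, cell_type, x
    connections: pd.DataFrame      # pre_id, post_id, receptor, weight, latency_ms
    params: dict                   # population -> dict of parameter overrides
    cell_params: dict              # neuron id -> CellParameters
    config: dict
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def population_ids(self, name: str) -> np.ndarray:
        pops = resolve_populations(name)
        return self.neurons.loc[self.neurons.population.isin(pops), "id"].to_numpy()

    def content_hash(self) -> str:
        buf = io.BytesIO()
        self.neurons.to_csv(buf, index=False)
        self.connections.to_csv(buf, index=False)
        for i in sorted(self.cell_params):
            buf.write(repr(self.cell_params[i]).encode())
        return hashlib.sha256(buf.getvalue()).hexdigest()[:16]

    def export_connections_csv(self, path) -> None:
        self.connections.rename(columns={"latency": "latency_ms"}).to_csv(path, index=False)


def load_network_config(path=None) -> dict:
    if path is None:
        ref = resources.files("swdsim") / "configs" / "network.yaml"
        return yaml.safe_load(ref.read_text())
    with open(path) as fh:
        return yaml.safe_load(fh)


def place_neurons(spec: SubsectorSpec, seed: int, id_offset: int = 0) -> pd.DataFrame:
    """Assign pseudo-random positions and cell types within a subsector.

    Positions are uniform draws on [0, 1) sorted along the row; the
    composition's cell types are randomly permuted over the slots.
    Deterministic for a fixed seed.
    """
    total = spec.total
    if total <= 0:
        raise ValueError("subsector must contain at least one neuron")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.random(total))
    types = np.concatenate([
        np.repeat(CellType(ct).value, n) for ct, n in sorted(spec.composition.items())
    ])
    rng.shuffle(types)
    ids = np.arange(id_offset, id_offset + total)
    if len(set(ids)) != total:
        raise ValueError("duplicate neuron ids")
    return pd.DataFrame({
        "id": ids, "population": spec.name, "cell_type": types, "x": x,
    })


def build_projection(spec: ProjectionSpec, source: pd.DataFrame,
                     target: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Realise one topographic projection as connection rows.

    Each source contacts the ``radius_P`` nearest targets on each side of
    its matched (normalised) position — at most ``2 * radius_P + 1``
    contacts — skipping itself, with one synapse per (pre, post) pair.
    Latencies are drawn uniformly from the configured range.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target populations must be non-empty")
    nt = len(target)
    P = spec.radius_P
    if 2 * P + 1 > nt:
        warnings.warn(
            f"projection {spec.source}->{spec.target}: radius {P} exceeds "
            f"target extent {nt}; clipping")
    rng = np.random.default_rng(seed)
    tx = target.x.to_numpy()
    t_ids = target.id.to_numpy()
    rows = []
    for sid, sx in zip(source.id.to_numpy(), source.x.to_numpy()):
        center = int(np.searchsorted(tx, sx))
        lo = max(0, min(center - P, nt - (2 * P + 1)))
        hi = min(nt, lo + 2 * P + 1)
        for j in range(lo, hi):
            if t_ids[j] == sid:
                continue
            rows.append((sid, t_ids[j]))
    if not rows:
        return pd.DataFrame(columns=["pre_id", "post_id", "receptor", "weight", "latency"])
    arr = np.asarray(rows)
    lat = rng.uniform(spec.latency_range[0], spec.latency_range[1], size=len(arr))
    df = pd.DataFrame({
        "pre_id": arr[:, 0], "post_id": arr[:, 1],
        "receptor": spec.receptor.value, "weight": spec.weight,
        "latency": np.round(lat, 3),
    })
    return df.drop_duplicates(subset=["pre_id", "post_id"])


def _scaled(n: int, scale: float) -> int:
    return max(1, int(round(n / scale)))


def build_default_network(config: dict = None, seed: int = 0,
                          scale: float = 1.0) -> NetworkSpec:
    """Build the full corticothalamic network from the shipped config.

    ``scale`` divides every subsector count (and projection radius) for
    desk-scale work; structural invariants are preserved at any scale.
    """
    cfg = load_network_config() if config is None else config
    rng = np.random.default_rng(seed)

    frames = []
    offset = 0
    for pop_cfg in cfg["populations"]:
        comp = {k: _scaled(v, scale) for k, v in pop_cfg["composition"].items()}
        spec = SubsectorSpec(name=pop_cfg["name"], composition=comp,
                             layer=pop_cfg.get("layer", ""))
        sub_seed = int(rng.integers(2 ** 31))
        df = place_neurons(spec, seed=sub_seed, id_offset=offset)
        offset += spec.total
        frames.append(df)
    neurons = pd.concat(frames, ignore_index=True)

    pop_names = set(neurons.population)
    conn_frames = []
    for proj_cfg in cfg["projections"]:
        for rec, w in proj_cfg["receptors"].items():
            if proj_cfg["source"] not in pop_names or proj_cfg["target"] not in pop_names:
                raise KeyError(
                    f"projection references unknown population "
                    f"{proj_cfg['source']}->{proj_cfg['target']}")
            spec = ProjectionSpec(
                source=proj_cfg["source"], target=proj_cfg["target"],
                radius_P=max(1, int(round(proj_cfg["radius_P"] / scale))),
                receptor=rec, weight=w,
                latency_range=tuple(proj_cfg.get("latency_range", [1.0, 3.0])),
            )
            sub_seed = int(rng.integers(2 ** 31))
            conn_frames.append(build_projection(
                spec,
                neurons[neurons.population == spec.source],
                neurons[neurons.population == spec.target],
                seed=sub_seed,
            ))
    connections = pd.concat(conn_frames, ignore_index=True)

    params = {p: dict(cfg.get("overrides", {}).get(p, {})) for p in pop_names}
    cell_params = {}
    for row in neurons.itertuples():
        base = load_cell_parameters(row.cell_type)
        over = params.get(row.population, {})
        if over:
            from dataclasses import replace
            base = replace(base, **over)
        cell_params[row.id] = base

    return NetworkSpec(neurons=neurons, connections=connections, params=params,
                       cell_params=cell_params, config=cfg, seed=seed)


def substitute_sib(network: NetworkSpec, layers, fraction: float,
                   seed: int = 0) -> NetworkSpec:
    """Replace a fraction of IB cells in the named layers by SIB cells.

    Connectivity is untouched; only the cell parameters (and recorded
    cell type) of the chosen neurons change.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0,1]")
    layers = [l.replace("/", "") for l in layers]
    for l in layers:
        if l not in ("L5", "L6"):
            raise ValueError("SIB substitution is defined for L5/L6 only")
    neurons = network.neurons.copy()
    cell_params = dict(network.cell_params)
    rng = np.random.default_rng(seed)
    for layer in layers:
        pop = f"{layer}_E"
        mask = (neurons.population == pop) & (neurons.cell_type == CellType.IB.value)
        ids = neurons.loc[mask, "id"].to_numpy()
        k = int(round(fraction * len(ids)))
        chosen = np.sort(rng.choice(ids, size=k, replace=False))
        neurons.loc[neurons.id.isin(chosen), "cell_type"] = CellType.SIB.value
        sib = load_cell_parameters(CellType.SIB)
        from dataclasses import replace as _replace
        over = network.params.get(pop, {})
        for i in chosen:
            cell_params[i] = _replace(sib, **{k: v for k, v in over.items()
                                              if hasattr(sib, k)})
    return NetworkSpec(neurons=neurons, connections=network.connections,
                       params=network.params, cell_params=cell_params,
                       config=network.config, seed=network.seed)
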