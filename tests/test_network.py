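"""Topographic network construction and its structural invariants."""

import numpy as np
import pandas as pd
import pytest

from swdsim.cells import CellType
from swdsim.network import (ProjectionSpec, SubsectorSpec, build_default_network,
                            build_projection, place_neurons, substitute_sib)


class TestPlaceNeurons:
    def test_same_seed_identical(self):
        spec = SubsectorSpec("L4_E", {"RS": 8, "IB": 2})
        a = place_neurons(spec, seed=5)
        b = place_neurons(spec, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_layer_counts_match_composition(self):
        spec = SubsectorSpec("L4_E", {"RS": 80, "IB": 10, "EF": 10})
        df = place_neurons(spec, seed=0)
        assert len(df) == 100
        assert spec.excitatory_count == 100 and spec.inhibitory_count == 0
        inh = SubsectorSpec("L4_I", {"FS": 50})
        assert inh.inhibitory_count == 50

    def test_different_seeds_same_counts_different_layout(self):
        spec = SubsectorSpec("L5_E", {"RS": 10, "IB": 10})
        a = place_neurons(spec, seed=1)
        b = place_neurons(spec, seed=2)
        assert sorted(a.cell_type) == sorted(b.cell_type)
        assert not (a.cell_type.to_numpy() == b.cell_type.to_numpy()).all() or \
            not np.allclose(a.x, b.x)


def _pops(n_src=20, n_tgt=20, seed=0):
    rng = np.random.default_rng(seed)
    src = pd.DataFrame({"id": np.arange(n_src), "population": "A",
                        "cell_type": "RS", "x": np.sort(rng.random(n_src))})
    tgt = pd.DataFrame({"id": np.arange(100, 100 + n_tgt), "population": "B",
                        "cell_type": "RS", "x": np.sort(rng.random(n_tgt))})
    return src, tgt


class TestBuildProjection:
    def test_degenerate_radius_hits_topographic_partner(self):
        src, tgt = _pops(10, 10)
        spec = ProjectionSpec("A", "B", radius_P=1, receptor="AMPA", weight=0.01)
        rows = build_projection(spec, src, tgt, seed=0)
        # every source contacts at most 3 nearest targets, centred topographically
        assert rows.groupby("pre_id").size().max() <= 3

    def test_self_projection_has_no_autapse(self):
        src, _ = _pops(12, 12)
        spec = ProjectionSpec("A", "A", radius_P=6, receptor="AMPA", weight=0.01)
        rows = build_projection(spec, src, src, seed=0)
        assert (rows.pre_id != rows.post_id).all()

    def test_pair_uniqueness(self):
        src, tgt = _pops(15, 8)
        spec = ProjectionSpec("A", "B", radius_P=4, receptor="GABAA", weight=0.01)
        rows = build_projection(spec, src, tgt, seed=3)
        assert not rows.duplicated(subset=["pre_id", "post_id"]).any()

    def test_radius_exceeding_extent_warns_and_clips(self):
        src, tgt = _pops(5, 3)
        spec = ProjectionSpec("A", "B", radius_P=10, receptor="AMPA", weight=0.01)
        with pytest.warns(UserWarning, match="clipping"):
            rows = build_projection(spec, src, tgt, seed=0)
        assert rows.groupby("pre_id").size().max() <= 3

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("radius", [1, 3, 7])
    def test_invariants_over_seeds_and_radii(self, seed, radius):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        src, _ = _pops(n, n, seed=seed)
        spec = ProjectionSpec("A", "A", radius_P=radius, receptor="AMPA", weight=0.01)
        rows = build_projection(spec, src, src, seed=seed)
        assert (rows.pre_id != rows.post_id).all()
        assert not rows.duplicated(subset=["pre_id", "post_id"]).any()
        # topographic containment: contacts stay within the radius window
        order = {i: r for r, i in enumerate(src.id)}
        for pre, post in zip(rows.pre_id, rows.post_id):
            assert abs(order[pre] - order[post]) <= 2 * radius + 1


class TestDefaultNetwork:
    def test_total_neuron_count_is_900(self, full_network):
        assert full_network.n_neurons == 900

    def test_eight_cortical_subsectors(self, full_network):
        cortical = [p for p in full_network.neurons.population.unique()
                    if p.startswith("L")]
        assert len(cortical) == 8
        for layer in ("L23", "L4", "L5", "L6"):
            exc = (full_network.neurons.population == f"{layer}_E").sum()
            inh = (full_network.neurons.population == f"{layer}_I").sum()
            assert (exc, inh) == (100, 50)

    def test_no_autapses_and_unique_pairs(self, full_network):
        conn = full_network.connections
        assert (conn.pre_id != conn.post_id).all()
        per_receptor = conn.groupby("receptor").apply(
            lambda df: df.duplicated(subset=["pre_id", "post_id"]).any(),
            include_groups=False)
        assert not per_receptor.any()

    def test_reciprocal_tc_nrt_loop(self, full_network):
        conn = full_network.connections
        tc = set(full_network.population_ids("TC_FO"))
        nrt = set(full_network.population_ids("NRT_FO"))
        fwd = conn[conn.pre_id.isin(tc) & conn.post_id.isin(nrt)]
        back = conn[conn.pre_id.isin(nrt) & conn.post_id.isin(tc)]
        assert len(fwd) > 0 and len(back) > 0
        assert set(back.receptor) >= {"GABAA", "GABAB"}

    def test_bit_reproducible_given_seed(self):
        a = build_default_network(seed=3, scale=5.0)
        b = build_default_network(seed=3, scale=5.0)
        assert a.content_hash() == b.content_hash()

    def test_scaled_down_preserves_invariants(self, desk_network):
        assert desk_network.n_neurons == 180
        conn = desk_network.connections
        assert (conn.pre_id != conn.post_id).all()
        assert not conn.groupby("receptor").apply(
            lambda df: df.duplicated(subset=["pre_id", "post_id"]).any(),
            include_groups=False).any()

    def test_l5_l6_contain_ib_cells(self, full_network):
        for layer in ("L5_E", "L6_E"):
            sub = full_network.neurons[full_network.neurons.population == layer]
            assert (sub.cell_type == "IB").sum() > 0

    def test_connection_export(self, desk_network, tmp_path):
        path = tmp_path / "conn.csv"
        desk_network.export_connections_csv(path)
        df = pd.read_csv(path)
        assert {"pre_id", "post_id", "receptor", "weight", "latency_ms"} <= set(df.columns)


class TestSubstituteSib:
    def test_fraction_zero_changes_nothing(self, desk_network):
        out = substitute_sib(desk_network, ("L5",), fraction=0.0, seed=0)
        assert (out.neurons.cell_type == desk_network.neurons.cell_type).all()

    def test_fraction_one_l5_only(self, desk_network):
        out = substitute_sib(desk_network, ("L5",), fraction=1.0, seed=0)
        l5 = out.neurons[out.neurons.population == "L5_E"]
        l6 = out.neurons[out.neurons.population == "L6_E"]
        assert (l5.cell_type == "IB").sum() == 0
        assert (l5.cell_type == "SIB").sum() > 0
        assert (l6.cell_type == "SIB").sum() == 0

    def test_same_seed_same_substitution(self, desk_network):
        a = substitute_sib(desk_network, ("L5", "L6"), fraction=0.5, seed=9)
        b = substitute_sib(desk_network, ("L5", "L6"), fraction=0.5, seed=9)
        assert (a.neurons.cell_type == b.neurons.cell_type).all()

    def test_connectivity_untouched(self, desk_network):
        out = substitute_sib(desk_network, ("L5",), fraction=1.0, seed=0)
        pd.testing.assert_frame_equal(out.connections, desk_network.connections)

    def test_fraction_out_of_range(self, desk_network):
        with pytest.raises(ValueError):
            substitute_sib(desk_network, ("L5",), fraction=1.5)
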