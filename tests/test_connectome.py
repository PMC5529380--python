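"""Structural tests of the generated EB-PB connectome."""

import pytest

from ebpb.config import default_config
from ebpb.connectome import (EB_WEDGE_ORDER, N_WEDGES, RegionID, WiringError,
                             build_connectome, build_type_catalogue,
                             dual_of_wedge, dual_regions, eb, infer_synapses,
                             pb, shifter_chains, validate_connectome)


def classes(cat):
    out = {}
    for t in cat:
        out.setdefault(t.neuron_class, []).append(t)
    return out


class TestCatalogue:
    def test_counts(self, connectome):
        by = classes(connectome.types)
        assert len(by["EIP"]) == 18
        assert len(by["PEI"]) == 16
        assert len(by["PEN"]) == 16
        assert sum(len(by[r]) for r in ("R_EIP", "R_PEI", "R_PEN")) == 3
        assert len(connectome.types) == 53

    def test_atypical_eip_types_innervate_single_seam_wedge(self, connectome):
        assert connectome.type_named("EIP", 0).eb_dendrites() == {eb("R8")}
        assert connectome.type_named("EIP", 17).eb_dendrites() == {eb("L8")}

    def test_typical_eip_shape(self, connectome):
        for k in range(1, 17):
            t = connectome.type_named("EIP", k)
            dend = {r.position for r in t.eb_dendrites()}
            assert len(dend) == 3
            adjacent = sum((p + 1) % N_WEDGES in dend for p in dend)
            assert adjacent == 2  # three consecutive wedges (circular)
            pb_axons = [r for r in t.axonal_regions if r.neuropil == "PB"]
            assert len(pb_axons) == 1

    def test_pei_pen_shapes(self, connectome):
        for cls, lo, hi in (("PEI", 0, 7), ("PEN", 1, 8)):
            for k in range(16):
                t = connectome.type_named(cls, k)
                (d,) = list(t.dendritic_regions)
                assert d.neuropil == "PB" and lo <= int(d.label[1:]) <= hi
                assert len(t.eb_axons()) == 2

    def test_ring_neurons_blanket_the_ring(self, connectome):
        for cls in ("R_EIP", "R_PEI", "R_PEN"):
            t = connectome.type_named(cls, 0)
            assert len(t.eb_axons()) == 16

    def test_dual_tiling_covers_all_wedges_once(self):
        duals = dual_regions(0)
        wedges = [w for pair in duals for w in pair]
        assert len(wedges) == 16 and len(set(wedges)) == 16
        named = {frozenset((a.label, b.label)) for a, b in duals}
        # the anatomically named duals
        assert frozenset(("R2", "R3")) in named
        assert frozenset(("L2", "L3")) in named
        assert frozenset(("R8", "L8")) in named

    def test_alternative_tiling_config(self):
        cfg = default_config().replace(dual_offset=1)
        named = {frozenset((a.label, b.label)) for a, b in dual_regions(1)}
        assert frozenset(("R8", "L8")) not in named
        cat = build_type_catalogue(cfg)  # still constructs
        assert len(cat) == 53

    def test_deterministic(self, connectome):
        again = build_connectome(default_config())
        assert [t.name for t in again.types] == [t.name for t in connectome.types]
        assert [(s.key(), s.G_max_nS) for s in again.synapses] == \
               [(s.key(), s.G_max_nS) for s in connectome.synapses]


class TestSynapses:
    def test_worked_clockwise_chain(self, connectome):
        c = connectome
        assert c.synapse(("EIP", 5), ("PEN", 5)).neuropil == "PB"
        assert c.synapse(("PEN", 5), ("EIP", 6)).neuropil == "EB"
        assert c.synapse(("EIP", 6), ("PEN", 6)) is not None
        assert c.synapse(("PEN", 6), ("EIP", 7)) is not None

    def test_worked_counterclockwise_chain(self, connectome):
        c = connectome
        assert c.synapse(("EIP", 12), ("PEN", 10)) is not None
        assert c.synapse(("PEN", 10), ("EIP", 11)) is not None
        assert c.synapse(("EIP", 11), ("PEN", 9)) is not None
        assert c.synapse(("PEN", 9), ("EIP", 10)) is not None

    def test_pei11_overlap_counts(self, connectome):
        assert connectome.synapse(("PEI", 11), ("EIP", 12)).overlap_count == 2
        assert connectome.synapse(("PEI", 11), ("EIP", 4)).overlap_count == 1

    def test_overlap_proportional_weights(self, connectome):
        w2 = connectome.synapse(("PEI", 10), ("EIP", 11))
        w1 = connectome.synapse(("PEI", 11), ("EIP", 4))
        assert w2.overlap_count == 2 and w1.overlap_count == 1
        assert w2.G_max_nS == pytest.approx(2 * w1.G_max_nS)

    def test_seam_connections_tripled(self, connectome):
        base = connectome.base_weights[("PEN", "EIP")]
        for pre, post in ((("PEN", 8), ("EIP", 0)), (("PEN", 7), ("EIP", 17))):
            s = connectome.synapse(pre, post)
            assert s.overlap_count == 1
            assert s.G_max_nS == pytest.approx(3 * base)

    def test_receptor_assignment(self, connectome):
        for s in connectome.synapses:
            if s.pre.neuron_class.startswith("R_"):
                assert s.receptor == "GABA_A"
            else:
                assert s.receptor == "NMDA"

    def test_cring_symmetry(self, connectome):
        keys = {(s.pre.name, s.post.name) for s in connectome.synapses}
        for pre, post in list(keys):
            if pre.startswith("EIP") and post.startswith("PEI"):
                assert (post, pre) in keys

    def test_pring_asymmetry(self, connectome):
        keys = {(s.pre.name, s.post.name) for s in connectome.synapses}
        for pre, post in list(keys):
            if pre.startswith("EIP") and post.startswith("PEN"):
                assert (post, pre) not in keys

    def test_shifter_chains_close_over_all_duals(self, connectome):
        chains = shifter_chains(connectome)
        for label, names in chains.items():
            pens = [n for n in names if n.startswith("PEN")]
            assert len(pens) == 8
            duals = {dual_of_wedge(w)
                     for p in pens
                     for w in connectome.type_named("PEN", int(p[3:])).eb_axons()}
            assert duals == set(range(8))
        cw_pens = {int(n[3:]) for n in chains["CW"] if n.startswith("PEN")}
        ccw_pens = {int(n[3:]) for n in chains["CCW"] if n.startswith("PEN")}
        assert cw_pens == set(range(8))
        assert ccw_pens == set(range(8, 16))

    def test_pen_groups_on_opposite_hemispheres(self, connectome):
        sides = {j: next(iter(connectome.type_named("PEN", j).dendritic_regions)).label[0]
                 for j in range(16)}
        assert {sides[j] for j in range(8)} == {"R"}
        assert {sides[j] for j in range(8, 16)} == {"L"}

    def test_bilateral_pei_input_per_dual(self, connectome):
        for d in range(8):
            feeders = [t for t in connectome.types if t.neuron_class == "PEI"
                       and dual_of_wedge(next(iter(t.eb_axons()))) == d]
            assert sorted(next(iter(t.dendritic_regions)).label[0]
                          for t in feeders) == ["L", "R"]

    def test_pen_removal_leaves_reciprocal_feedback_graph(self, connectome):
        # with the shifter removed, every EB->PB projection edge is paired
        # with a PB->EB feedback edge (the pure EIP<->PEI feedback network)
        sub = connectome.subset(("EIP", "PEI"))
        keys = {(s.pre.name, s.post.name) for s in sub.synapses}
        for pre, post in keys:
            if pre.startswith("EIP"):
                assert (post, pre) in keys

    def test_validation_catches_broken_symmetry(self, connectome):
        cat = list(connectome.types)
        syn = infer_synapses(cat, validate=False)
        broken = [s for s in syn
                  if not (s.pre.name == "PEI5" and s.post.name.startswith("EIP"))]
        with pytest.raises(WiringError):
            validate_connectome(cat, broken)


class TestExport:
    def test_edge_list_roundtrip(self, connectome, tmp_path):
        path = tmp_path / "edges.tsv"
        connectome.write_edge_list(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(connectome.synapses) + 1
        header = lines[0].split("\t")
        assert header[:2] == ["pre_class", "pre_index"]
        first = dict(zip(header, lines[1].split("\t")))
        assert float(first["G_max_nS"]) > 0

    def test_graphml_export(self, connectome, tmp_path):
        import networkx as nx
        path = tmp_path / "conn.graphml"
        connectome.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 53


class TestRegionID:
    def test_validation(self):
        with pytest.raises(ValueError):
            RegionID("EB", "R0")   # EB wedges are 1..8
        with pytest.raises(ValueError):
            RegionID("PB", "R9")
        with pytest.raises(ValueError):
            RegionID("XX", "R1")
        assert pb("R0").neuropil == "PB"

    def test_positions_cover_circle(self):
        assert sorted(eb(w).position for w in EB_WEDGE_ORDER) == list(range(16))
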