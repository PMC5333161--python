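import math

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from corrpath.clustering import (ClusterAssignment, GENE_AXIS,
                                 METABOLITE_AXIS, hierarchical_cluster)
from corrpath.errors import InputError, LookupError_
from corrpath.io import Dataset
from corrpath.pathway import (PALETTE, assign_bin, between_condition_r,
                              comparative_map, export_cluster_gene_list,
                              render_map, style_by_cluster, to_networkx,
                              unmapped_entities, variation_table,
                              write_graphml)
from corrpath.simulate import Condition, SyntheticConfig, generate

from conftest import make_profile, pearson_oracle


def fake_assignment(labels, axis):
    # styling only needs the label map; the tree is a placeholder
    ids = sorted(labels) if len(labels) >= 2 else ["zz1", "zz2"]
    tree = hierarchical_cluster(ids, np.arange(len(ids), dtype=float)[:, None])
    return ClusterAssignment(axis=axis, labels=dict(labels), linkage=tree,
                             order=tree.leaf_order())


class TestAssignBin:
    @pytest.mark.parametrize("r, expected", [
        (0.95, "strong_pos"),
        (-0.7, "strong_neg"),
        (0.25, "weak_pos"),
        (0.9, "pos"),        # boundary attaches to the inner bin
        (0.5, "weak_pos"),
        (0.0, "weak_pos"),
        (-0.5, "neg"),
        (-0.2, "neg"),
        (1.0, "strong_pos"),
        (-1.0, "strong_neg"),
        (float("nan"), "na"),
    ])
    def test_partition(self, r, expected):
        assert assign_bin(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            assign_bin(1.5)

    def test_monotone_on_grid(self):
        order = {"strong_neg": 0, "neg": 1, "weak_pos": 2, "pos": 3,
                 "strong_pos": 4}
        grid = np.linspace(-1, 1, 2001)
        ranks = [order[assign_bin(r)] for r in grid]
        assert ranks == sorted(ranks)


class TestStyleByCluster:
    def test_cluster_and_absence_colors(self, toy_map):
        met = fake_assignment({"GLC": "A", "G6P": "B", "PYR": "unassigned"},
                              METABOLITE_AXIS)
        gene = fake_assignment({"Hk1": "A", "Pkm": "B"}, GENE_AXIS)
        sm = style_by_cluster(toy_map, met, gene)
        assert sm.node_styles["GLC"]["fill"] == PALETTE["orange"]
        assert sm.node_styles["G6P"]["fill"] == PALETTE["light_blue"]
        assert sm.node_styles["PYR"]["fill"] == PALETTE["white"]   # unassigned
        assert sm.node_styles["LAC"]["fill"] == PALETTE["white"]   # unmeasured
        assert sm.edge_styles["e1"]["stroke"] == PALETTE["orange"]
        assert sm.edge_styles["e2"]["stroke"] == PALETTE["light_blue"]
        assert sm.edge_styles["e3"]["stroke"] == PALETTE["grey"]   # unmeasured

    def test_conflicting_isozyme_clusters_grey_with_log(self, toy_map, caplog):
        from corrpath.io import PathwayEdge
        toy_map.edges["e5"] = PathwayEdge(id="e5", source="PYR", target="LAC",
                                          genes=("Ldha", "Ldhb"))
        met = fake_assignment({}, METABOLITE_AXIS)
        gene = fake_assignment({"Ldha": "A", "Ldhb": "B"}, GENE_AXIS)
        with caplog.at_level("WARNING"):
            sm = style_by_cluster(toy_map, met, gene)
        assert sm.edge_styles["e5"]["stroke"] == PALETTE["grey"]
        assert "conflicting clusters" in caplog.text


class TestBetweenConditionR:
    def test_identical_and_negated(self, two_condition_dataset):
        d = two_condition_dataset
        assert between_condition_r(d, "M1", "0mM", "5mM") == pytest.approx(1.0)
        assert between_condition_r(d, "M2", "0mM", "5mM") == pytest.approx(-1.0)

    def test_constant_profile_gives_nan(self, two_condition_dataset):
        assert math.isnan(between_condition_r(two_condition_dataset,
                                              "M3", "0mM", "5mM"))

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(8)
        ds = Dataset()
        a = rng.uniform(1, 50, 6)
        b = rng.uniform(1, 50, 6)
        ds.add(make_profile("X", times=range(6), reps=[(v,) for v in a]))
        ds.add(make_profile("X", times=range(6), reps=[(v,) for v in b],
                            cond="5mM"))
        r = between_condition_r(ds, "X", "0mM", "5mM")
        assert r == pytest.approx(pearson_oracle(list(a), list(b)), abs=1e-12)

    def test_missing_entity_is_lookup_error(self, two_condition_dataset):
        with pytest.raises(LookupError_):
            between_condition_r(two_condition_dataset, "M9", "0mM", "5mM")


class TestComparativeMap:
    @pytest.fixture
    def dose_setup(self, toy_map):
        """Toy map whose nodes/edge genes are measured under 3 conditions."""
        ds = Dataset()
        rng = np.random.default_rng(3)
        base = {"GLC": rng.uniform(1, 9, 6), "G6P": rng.uniform(1, 9, 6),
                "PYR": rng.uniform(1, 9, 6)}
        flat = np.full(6, 4.0)
        for cond in ("0mM", "5mM"):
            for m, v in base.items():
                ds.add(make_profile(m, times=range(6), reps=[(x,) for x in v],
                                    cond=cond))
            ds.add(make_profile("LAC", times=range(6),
                                reps=[(x,) for x in flat], cond=cond))
            ds.add(make_profile("Ldha", kind="gene", times=range(4),
                                reps=[1, 3, 2, 5], units="FPKM", cond=cond))
        return toy_map, ds

    def test_self_comparison_law(self, dose_setup):
        pmap, ds = dose_setup
        sm, table = comparative_map(pmap, ds, "0mM", "0mM")
        bins = dict(zip(table.entity_id, table.bin))
        assert bins["LAC"] == "na"           # constant profile
        for e in ("GLC", "G6P", "PYR", "Ldha"):
            assert bins[e] == "strong_pos"
        assert sm.node_styles["LAC"]["fill"] == PALETTE["white"]
        assert sm.node_styles["CIT"]["fill"] == PALETTE["white"]   # unmeasured
        assert sm.edge_styles["e1"]["stroke"] == PALETTE["grey"]   # Hk1 absent

    def test_strong_bin_enlarges_glyphs(self, dose_setup):
        pmap, ds = dose_setup
        sm, _ = comparative_map(pmap, ds, "0mM", "0mM")
        assert sm.node_styles["PYR"]["size"] == pytest.approx(14.0 * 1.6)
        assert sm.edge_styles["e3"]["width"] == pytest.approx(2.0 * 2.5)

    def test_unmapped_entities_sidecar(self, dose_setup):
        pmap, ds = dose_setup
        ds.add(make_profile("ORPHAN", times=range(6), reps=[1, 2, 3, 4, 5, 6]))
        assert "ORPHAN" in unmapped_entities(pmap, ds)

    @pytest.mark.parametrize("seed", range(20))
    def test_dose_monotonicity_of_strong_pos_counts(self, seed, toy_map):
        """A weaker perturbation must retain at least as many strongly
        positively correlated entities as a stronger one."""
        cfg = SyntheticConfig(n_metabolites=10, n_genes=6, noise_cv=0.05,
                              seed=seed, include_culture=False,
                              conditions=[Condition("ctrl", 0.0),
                                          Condition("low", 0.3),
                                          Condition("high", 0.7)])
        ds, _ = generate(cfg)

        def n_strong(cond):
            rs = [between_condition_r(ds, e, "ctrl", cond)
                  for e in ds.entities()]
            return sum(assign_bin(r) == "strong_pos" for r in rs)

        assert n_strong("low") >= n_strong("high")


class TestVariationTable:
    def _table(self, bins):
        return pd.DataFrame([{"entity_id": e, "kind": k, "r": 0.0, "bin": b}
                             for e, k, b in bins])

    def test_red_green_variation(self):
        ab = self._table([("PYR", "metabolite", "pos")])
        ac = self._table([("PYR", "metabolite", "weak_pos")])
        out = variation_table(ab, ac)
        assert list(out.pattern) == ["red/green"]
        assert out.entities[0] == "PYR"

    def test_identical_bins_group_under_same_pattern(self):
        ab = self._table([("A", "gene", "neg"), ("B", "gene", "neg")])
        out = variation_table(ab, ab)
        assert list(out.pattern) == ["blue/blue"]
        assert out.entities[0] == "A;B"

    def test_three_distinct_variations_three_groups(self):
        ab = self._table([("A", "gene", "pos"), ("B", "metabolite", "neg"),
                          ("C", "metabolite", "na")])
        ac = self._table([("A", "gene", "weak_pos"), ("B", "metabolite", "pos"),
                          ("C", "metabolite", "neg")])
        out = variation_table(ab, ac)
        assert len(out) == 3
        joined = ";".join(out.entities)
        for e in "ABC":
            assert joined.count(e) == 1  # exact coverage

    def test_entity_set_mismatch_rejected(self):
        ab = self._table([("A", "gene", "pos")])
        ac = self._table([("B", "gene", "pos")])
        with pytest.raises(InputError):
            variation_table(ab, ac)


class TestGeneListExport:
    def test_sorted_one_per_line(self, tmp_path):
        assign = fake_assignment({"Ldha": "A", "Cs": "A", "Pkm": "B"},
                                 GENE_AXIS)
        out = export_cluster_gene_list(assign, "A", tmp_path / "genes.txt")
        assert out.read_text() == "Cs\nLdha\n"

    def test_empty_cluster_gives_empty_file(self, tmp_path):
        assign = fake_assignment({"Ldha": "A", "Cs": "B"}, GENE_AXIS)
        out = export_cluster_gene_list(assign, "unassigned",
                                       tmp_path / "genes.txt")
        assert out.read_text() == ""

    def test_metabolite_axis_rejected(self, tmp_path):
        assign = fake_assignment({"PYR": "A", "CIT": "B"}, METABOLITE_AXIS)
        with pytest.raises(InputError):
            export_cluster_gene_list(assign, "A", tmp_path / "x.txt")


class TestRenderMap:
    def test_svg_contains_palette_hexes(self, toy_map, tmp_path):
        met = fake_assignment({"GLC": "A", "G6P": "B"}, METABOLITE_AXIS)
        gene = fake_assignment({"Hk1": "A"}, GENE_AXIS)
        sm = style_by_cluster(toy_map, met, gene)
        svg = render_map(sm, tmp_path / "m.svg").read_text()
        assert svg.count('<circle') == 5
        for hexcode in (PALETTE["orange"], PALETTE["light_blue"],
                        PALETTE["white"], PALETTE["grey"]):
            assert hexcode in svg

    def test_seeded_layout_is_deterministic(self, toy_map, tmp_path):
        from corrpath.io import PathwayMap, PathwayNode, PathwayEdge
        pmap = PathwayMap(name="nolayout")
        for n in ("A", "B", "C"):
            pmap.nodes[n] = PathwayNode(id=n)   # no coordinates
        pmap.edges["e"] = PathwayEdge(id="e", source="A", target="B")
        met = fake_assignment({}, METABOLITE_AXIS)
        gene = fake_assignment({}, GENE_AXIS)
        sm = style_by_cluster(pmap, met, gene)
        s1 = render_map(sm, tmp_path / "a.svg", seed=42).read_text()
        s2 = render_map(sm, tmp_path / "b.svg", seed=42).read_text()
        assert s1 == s2

    def test_graphml_round_trip_preserves_styles(self, toy_map, tmp_path):
        met = fake_assignment({"GLC": "A"}, METABOLITE_AXIS)
        gene = fake_assignment({"Hk1": "A"}, GENE_AXIS)
        sm = style_by_cluster(toy_map, met, gene)
        path = write_graphml(sm, tmp_path / "m.graphml")
        g = nx.read_graphml(path)
        ref = to_networkx(sm)
        assert g.number_of_nodes() == ref.number_of_nodes()
        assert g.number_of_edges() == ref.number_of_edges()
        assert g.nodes["GLC"]["fill"] == PALETTE["orange"]
        assert g.edges["GLC", "G6P"]["stroke"] == PALETTE["orange"]
        assert g.edges["GLC", "G6P"]["width"] == pytest.approx(2.0)
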