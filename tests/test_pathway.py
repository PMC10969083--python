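from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gfabric import (
    AnalysisConfig,
    GeneSet,
    classify_pairs,
    compute_wpr,
    coordination_degree,
    coupling_table,
    export_fabric_network,
    inter_pathway_coord,
    intra_pathway_coord,
    read_sif,
    remodeling_ratio,
    write_sif,
)
from gfabric.pathway import CouplingRecord
from gfabric.simulate import Block, FabricSpec, generate


def _pair_df(records):
    return pd.DataFrame(
        records, columns=["gene_i", "gene_j", "condition", "cor", "n_points", "cls"]
    )


class TestWpr:
    def test_all_zero(self):
        assert compute_wpr([0.0, 0.0, 0.0]) == 0.0

    def test_rms(self):
        assert compute_wpr([3.0, -4.0]) == pytest.approx(np.sqrt(12.5))

    def test_sign_invariant(self):
        wirs = [1.5, -2.0, 0.3]
        assert compute_wpr(wirs) == compute_wpr([abs(w) for w in wirs])

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            compute_wpr([])


class TestCouplingRecordArithmetic:
    @pytest.mark.parametrize(
        "syn, ant, ind, n_pairs, expected",
        [
            (302, 246, 54, 55 * 54, 16.63),  # glycolysis intra, reference diet
            (732, 404, 138, 75 * 74, 17.98),  # contraction intra, reference
            (514, 68, 168, 75 * 74, 7.46),  # contraction intra, experimental
            (496, 311, 94, 4125, 17.28),  # glycolysis-contraction inter, reference
            (309, 110, 127, 4125, 7.08),  # inter, experimental
        ],
    )
    def test_printed_coordination_degrees(self, syn, ant, ind, n_pairs, expected):
        rec = CouplingRecord("A", "B", "N", syn, ant, ind, n_pairs)
        assert round(rec.coord, 2) == expected

    def test_all_unclassified_is_zero(self):
        assert CouplingRecord("A", "A", "N", 0, 0, 0, 90).coord == 0.0


class TestIntraInter:
    def _fixture(self):
        genes_a = ["a1", "a2", "a3"]
        genes_b = ["b1", "b2"]
        rows = []
        cls_map = {
            ("a1", "a2"): "synergistic",
            ("a1", "a3"): "antagonistic",
            ("a2", "a3"): "independent",
            ("a1", "b1"): "synergistic",
            ("a1", "b2"): "unclassified",
            ("a2", "b1"): "independent",
            ("a2", "b2"): "synergistic",
            ("a3", "b1"): "unclassified",
            ("a3", "b2"): "antagonistic",
            ("b1", "b2"): "synergistic",
        }
        for (gi, gj), cls in cls_map.items():
            rows.append((gi, gj, "N", 0.5, 4, cls))
        return (
            _pair_df(rows),
            GeneSet("A", "a", frozenset(genes_a)),
            GeneSet("B", "b", frozenset(genes_b)),
            set(genes_a + genes_b),
        )

    def test_intra_counts_and_ordered_pair_denominator(self):
        pairs, set_a, _, quant = self._fixture()
        rec = intra_pathway_coord(pairs, set_a, "N", quant)
        assert (rec.n_syn, rec.n_ant, rec.n_ind) == (1, 1, 1)
        assert rec.n_pairs == 3 * 2
        assert rec.coord == pytest.approx(100 * 1 / 6)

    def test_inter_counts_and_denominator(self):
        pairs, set_a, set_b, quant = self._fixture()
        rec = inter_pathway_coord(pairs, set_a, set_b, "N", quant)
        assert (rec.n_syn, rec.n_ant, rec.n_ind) == (2, 1, 1)
        assert rec.n_pairs == 3 * 2
        assert rec.coord == pytest.approx(100 * 2 / 6)

    def test_overlapping_sets_drop_self_pairs(self):
        pairs, set_a, _, quant = self._fixture()
        overlap = GeneSet("O", "o", frozenset({"a1", "b1"}))
        rec = inter_pathway_coord(pairs, set_a, overlap, "N", quant)
        assert rec.n_pairs == 3 * 2 - 1  # a1 shared

    def test_singleton_disjoint_sets_fully_coupled(self):
        pairs = _pair_df([("x", "y", "N", 0.99, 4, "synergistic")])
        rec = inter_pathway_coord(
            pairs,
            GeneSet("X", "x", frozenset({"x"})),
            GeneSet("Y", "y", frozenset({"y"})),
            "N",
            {"x", "y"},
        )
        assert rec.coord == 100.0

    def test_too_few_members_error(self):
        pairs, set_a, _, quant = self._fixture()
        with pytest.raises(ValueError):
            intra_pathway_coord(pairs, GeneSet("S", "s", frozenset({"a1"})), "N", quant)

    def test_union_coord_is_pair_weighted_combination(self):
        # brute-force consistency on a small synthetic fabric
        spec = FabricSpec(
            n_genes=10,
            blocks=(Block(genes=tuple(range(5)), rho=0.99),),
            seed=31,
        )
        ds, truth = generate(spec)
        cfg = AnalysisConfig()
        pairs = classify_pairs(ds, "N", cfg)
        names = truth.genes["gene"].tolist()
        set_a = GeneSet("A", "a", frozenset(names[:5]))
        set_b = GeneSet("B", "b", frozenset(names[5:]))
        union = GeneSet("U", "u", frozenset(names))
        quant = set(names)
        ra = intra_pathway_coord(pairs, set_a, "N", quant)
        rb = intra_pathway_coord(pairs, set_b, "N", quant)
        rab = inter_pathway_coord(pairs, set_a, set_b, "N", quant)
        ru = intra_pathway_coord(pairs, union, "N", quant)
        # distinct-pair universes add up: G(G-1)/2 = 5*4/2 + 5*4/2 + 25
        num_union = ru.n_syn + ru.n_ant - ru.n_ind
        assert num_union == (
            (ra.n_syn + ra.n_ant - ra.n_ind)
            + (rb.n_syn + rb.n_ant - rb.n_ind)
            + (rab.n_syn + rab.n_ant - rab.n_ind)
        )
        # and the denominator-weighted coords agree
        weighted = (
            ra.coord * ra.n_pairs + rb.coord * rb.n_pairs + rab.coord * rab.n_pairs
        ) / ru.n_pairs
        assert ru.coord == pytest.approx(weighted)


class TestRemodeling:
    def test_printed_decoupling_ratios(self):
        assert round(remodeling_ratio(13.82, 2.91), 2) == -4.75
        assert round(remodeling_ratio(10.50, 2.83), 2) == -3.71

    def test_equal_coordination_is_unit(self):
        assert abs(remodeling_ratio(5.0, 5.0)) == 1.0

    def test_increase_is_positive(self):
        assert remodeling_ratio(2.0, 8.0) == pytest.approx(4.0)

    def test_zero_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            remodeling_ratio(5.0, 0.0)


class TestConditionSwap:
    def test_swap_exchanges_coordination_everywhere(self):
        spec = FabricSpec(
            n_genes=12,
            blocks=(Block(genes=tuple(range(6)), rho=0.95),),
            seed=32,
        )
        ds, truth = generate(spec)
        cfg = AnalysisConfig()
        pairs = pd.concat(
            [classify_pairs(ds, c, cfg) for c in ("N", "L")], ignore_index=True
        )
        swapped = pairs.assign(
            condition=pairs["condition"].map({"N": "L", "L": "N"})
        )
        names = truth.genes["gene"].tolist()
        sets = [
            GeneSet("A", "a", frozenset(names[:6])),
            GeneSet("B", "b", frozenset(names[6:])),
        ]
        base = coupling_table(pairs, sets, ("N", "L"), set(names))
        flip = coupling_table(swapped, sets, ("N", "L"), set(names))
        for (_, rb), (_, rf) in zip(
            base.sort_values(["set_a", "set_b", "condition"]).iterrows(),
            flip.sort_values(["set_a", "set_b", "condition"], ascending=[True, True, False]).iterrows(),
        ):
            assert rb["coord"] == pytest.approx(rf["coord"])


class TestSynergismRecovery:
    def test_imposed_block_correlation_is_recalled(self):
        blocks = tuple(Block(genes=(2 * i, 2 * i + 1), rho=0.995) for i in range(100))
        spec = FabricSpec(n_genes=200, cv_range=(0.05, 0.5), blocks=blocks, seed=33)
        ds, truth = generate(spec)
        pairs = [
            (truth.genes.loc[2 * i, "gene"], truth.genes.loc[2 * i + 1, "gene"])
            for i in range(100)
        ]
        cls = classify_pairs(ds, "N", AnalysisConfig(), pairs)
        assert (cls["cls"] == "synergistic").mean() >= 0.70

    def test_antagonistic_sign_pattern(self):
        blocks = (Block(genes=(0, 1), rho=0.995, signs=(1, -1)),)
        spec = FabricSpec(
            n_genes=2, cv_range=(0.3, 0.3), spots_per_gene=(0, 0, 1.0),
            blocks=blocks, seed=34,
        )
        ds, _ = generate(spec)
        cls = classify_pairs(ds, "N", AnalysisConfig(), [("G00000", "G00001")])
        assert cls["cls"].iloc[0] == "antagonistic"


class TestNetworkExport:
    def _pairs(self):
        return _pair_df(
            [
                ("g1", "g2", "N", 0.99, 4, "synergistic"),
                ("g1", "g3", "N", -0.97, 4, "antagonistic"),
                ("g2", "g3", "N", 0.02, 4, "independent"),
                ("g1", "g4", "N", 0.40, 4, "unclassified"),
            ]
        )

    def test_single_synergistic_edge(self):
        edges, nodes = export_fabric_network(
            self._pairs().iloc[[0]], "N"
        )
        assert edges.to_numpy().tolist() == [["g1", "syn", "g2"]]
        assert nodes["call"].tolist() == ["none", "none"]

    def test_significant_edges_only(self):
        edges, _ = export_fabric_network(self._pairs(), "N")
        assert sorted(edges["cls"]) == ["ant", "syn"]

    def test_anchor_against_set_synergisms(self):
        # one hub gene imposed synergistic with a block of 18 partners
        blocks = (Block(genes=tuple(range(19)), rho=0.995),)
        spec = FabricSpec(
            n_genes=19, cv_range=(0.2, 0.4), spots_per_gene=(0, 0, 1.0),
            blocks=blocks, seed=35,
        )
        ds, truth = generate(spec)
        names = truth.genes["gene"].tolist()
        hub = names[0]
        cls = classify_pairs(
            ds, "N", AnalysisConfig(), [(hub, g) for g in names[1:]]
        )
        edges, _ = export_fabric_network(cls, "N")
        assert (edges["cls"] == "syn").sum() == 18

    def test_sif_round_trip(self, tmp_path):
        edges, _ = export_fabric_network(self._pairs(), "N", include_independent=True)
        f = tmp_path / "net.sif"
        write_sif(edges, f)
        back = read_sif(f)
        assert sorted(map(tuple, back.to_numpy())) == sorted(
            map(tuple, edges.to_numpy())
        )
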