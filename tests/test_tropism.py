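"""Atlas abundance scores, tropism labels, and the gene dendrogram."""

import numpy as np
import pandas as pd
import pytest

from reprotome import (
    ArgumentError,
    GeneSet,
    LookupMissingError,
    assign_tropism,
    cns_abundance,
    endocrine_abundance,
    generate_atlas,
    generate_experiment,
    hierarchical_cluster,
)
from reprotome.tropism import AtlasMatrix

from conftest import small_config


def make_atlas(rows: dict, categories: dict) -> AtlasMatrix:
    tissues = list(categories)
    df = pd.DataFrame(rows, index=tissues).T
    return AtlasMatrix(values=df, tissue_category=categories)


CATS = {
    "islet": "endocrine", "pituitary": "endocrine",
    "cortex": "cns", "cerebellum": "cns",
    "liver": "other", "kidney": "other", "lung": "other", "spleen": "other",
}


class TestAbundanceScores:
    def test_uniform_profile_scores_one(self):
        atlas = make_atlas({"G1": [5.0] * 8}, CATS)
        assert endocrine_abundance("G1", atlas) == pytest.approx(1.0)
        assert cns_abundance("G1", atlas) == pytest.approx(1.0)

    def test_ninety_ten_profile_scores_nine(self):
        # endocrine tissues at 90, all six others at 10
        atlas = make_atlas({"G1": [90.0, 90.0] + [10.0] * 6}, CATS)
        assert endocrine_abundance("G1", atlas) == pytest.approx(9.0)

    def test_zero_outside_expression_uses_floor_not_division_error(self):
        atlas = make_atlas({"G1": [4.0, 4.0] + [0.0] * 6}, CATS)
        score = endocrine_abundance("G1", atlas)
        assert np.isfinite(score) and score > 1e5

    def test_missing_gene_raises_lookup_error(self):
        atlas = make_atlas({"G1": [1.0] * 8}, CATS)
        with pytest.raises(LookupMissingError, match="GHOST"):
            endocrine_abundance("GHOST", atlas)

    def test_lookup_is_case_insensitive(self):
        atlas = make_atlas({"Ins1": [90.0, 90.0] + [10.0] * 6}, CATS)
        assert endocrine_abundance("INS1", atlas) == pytest.approx(9.0)


class TestAssignTropism:
    # enough background tissues that a gene high in both endocrine and cns
    # tissues can still clear tau = 3 on both abundance scores
    CATS12 = dict(CATS, **{f"tissue{i}": "other" for i in range(4)})

    def _three_way_atlas(self):
        return make_atlas(
            {
                "ENDO1": [80.0, 80.0, 2.0, 2.0] + [2.0] * 8,
                "ENDO2": [60.0, 70.0, 3.0, 2.0] + [2.0] * 8,
                "CNS1": [2.0, 2.0, 80.0, 80.0] + [2.0] * 8,
                "BOTH1": [50.0, 50.0, 50.0, 50.0] + [2.0] * 8,
                "FLAT1": [5.0] * 12,
            },
            self.CATS12,
        )

    def test_labels_match_construction(self):
        res = assign_tropism(GeneSet.from_ids("q", ["ENDO1", "ENDO2", "CNS1", "BOTH1", "FLAT1"]),
                             self._three_way_atlas())
        lab = res.assignments["label"]
        assert lab["ENDO1"] == "A" and lab["ENDO2"] == "A"
        assert lab["CNS1"] == "B"
        assert lab["BOTH1"] == "C"
        assert lab["FLAT1"] == "MISC"

    def test_composition_sums_to_one_and_matches_counts(self):
        res = assign_tropism(GeneSet.from_ids("q", ["ENDO1", "ENDO2", "CNS1", "BOTH1", "FLAT1"]),
                             self._three_way_atlas())
        assert sum(res.composition.values()) == pytest.approx(1.0)
        assert res.composition["A"] == pytest.approx(2 / 5)
        assert res.composition["MISC"] == pytest.approx(1 / 5)

    def test_each_gene_gets_exactly_one_label(self):
        res = assign_tropism(GeneSet.from_ids("q", ["ENDO1", "CNS1"]), self._three_way_atlas())
        assert set(res.assignments["label"]) <= {"A", "B", "C", "MISC"}
        assert res.assignments.index.is_unique

    def test_labels_invariant_under_global_rescale(self):
        atlas = self._three_way_atlas()
        scaled = AtlasMatrix(atlas.values * 37.5, dict(atlas.tissue_category))
        q = GeneSet.from_ids("q", ["ENDO1", "ENDO2", "CNS1", "BOTH1", "FLAT1"])
        r1, r2 = assign_tropism(q, atlas), assign_tropism(q, scaled)
        assert r1.assignments["label"].equals(r2.assignments["label"])

    def test_empty_query_rejected(self):
        with pytest.raises(ArgumentError):
            assign_tropism(GeneSet.from_ids("q", []), self._three_way_atlas())

    def test_gene_absent_from_atlas_rejected(self):
        with pytest.raises(LookupMissingError):
            assign_tropism(GeneSet.from_ids("q", ["ENDO1", "NOPE"]), self._three_way_atlas())

    def test_synthetic_atlas_blocks_recovered(self):
        cfg = small_config(n_transcripts=600, target_enriched_size=60,
                           reprogramming_fraction_f=0.5, n_activated_offpath=30)
        _, truth = generate_experiment(cfg)
        atlas = generate_atlas(cfg, truth)
        up = GeneSet.from_ids("up", truth.activated_ids)
        res = assign_tropism(up, atlas)
        want = {"endocrine": "A", "cns": "B", "shared": "C", "background": "MISC"}
        lab = res.assignments["label"]
        for g in truth.activated_ids:
            assert lab[g.upper()] == want[truth.tissue_block[g]]


class TestHierarchicalCluster:
    def test_identical_profiles_merge_first_at_zero_distance(self):
        atlas = make_atlas(
            {
                "A1": [9.0, 8.0, 1.0, 1.0, 2.0, 2.0, 1.0, 2.0],
                "A2": [9.0, 8.0, 1.0, 1.0, 2.0, 2.0, 1.0, 2.0],
                "B1": [1.0, 1.0, 9.0, 8.0, 2.0, 2.0, 1.0, 2.0],
            },
            CATS,
        )
        Z, order, newick, _ = hierarchical_cluster(atlas)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # A1, A2 after sorting
        assert newick.endswith(";") and "B1" in newick

    def test_endocrine_pair_joins_before_cns_gene(self):
        atlas = make_atlas(
            {
                "E1": [80.0, 70.0, 2.0, 3.0, 2.0, 2.0, 3.0, 2.0],
                "E2": [60.0, 75.0, 3.0, 2.0, 3.0, 2.0, 2.0, 3.0],
                "N1": [2.0, 3.0, 80.0, 70.0, 2.0, 3.0, 2.0, 2.0],
            },
            CATS,
        )
        Z, order, _, _ = hierarchical_cluster(atlas)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        # leaf order keeps the correlated pair adjacent
        assert abs(order.index("E1") - order.index("E2")) == 1

    def test_result_invariant_to_input_row_order(self):
        rows = {
            "E1": [80.0, 70.0, 2.0, 3.0, 2.0, 2.0, 3.0, 2.0],
            "N1": [2.0, 3.0, 80.0, 70.0, 2.0, 3.0, 2.0, 2.0],
            "E2": [60.0, 75.0, 3.0, 2.0, 3.0, 2.0, 2.0, 3.0],
            "M1": [5.0, 6.0, 5.0, 4.0, 5.0, 6.0, 5.0, 4.0],
        }
        a1 = make_atlas(rows, CATS)
        a2 = make_atlas(dict(reversed(list(rows.items()))), CATS)
        z1, o1, n1, _ = hierarchical_cluster(a1)
        z2, o2, n2, _ = hierarchical_cluster(a2)
        np.testing.assert_allclose(z1, z2)
        assert o1 == o2 and n1 == n2

    def test_single_gene_rejected(self):
        atlas = make_atlas({"G1": [1.0] * 8}, CATS)
        with pytest.raises(ArgumentError):
            hierarchical_cluster(atlas)
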