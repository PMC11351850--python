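import numpy as np
import pandas as pd
import pytest

from dielortho.cross_species import (
    build_flip_records,
    classify_pattern,
    collapse_to_reference,
    diel_coincidence,
    merge_flip_records,
    ortholog_pair_de,
    rank_candidates,
    rest_phase_coincidence,
)
from dielortho.io import GoTable
from dielortho.orthology import OrthologMap

from conftest import make_design

NICHES = {"AN": "diurnal", "DR": "nocturnal"}


def de_table(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "adj_p", "significant"])
    df["log10_adj_p"] = np.log10(df["adj_p"].clip(lower=1e-300))
    return df


def two_species_design():
    return make_design(species="AN", niche="diurnal") + make_design(
        species="DR", niche="nocturnal"
    )


class TestClassifyPattern:
    def test_flip(self):
        assert classify_pattern(-3.1, True, 2.6, True) == "flipped"

    def test_concordant_directions(self):
        assert classify_pattern(3.0, True, 4.0, True) == "concordant_night"
        assert classify_pattern(-3.0, True, -4.0, True) == "concordant_day"

    def test_single_species_strong_threshold(self):
        assert classify_pattern(-6.0, True, 0.5, False) == "single_species_strong"
        assert classify_pattern(-4.0, True, 0.5, False) == "not_shared"

    def test_not_shared_when_neither_significant(self):
        assert classify_pattern(1.0, False, -1.0, False) == "not_shared"

    def test_species_label_swap_maps_concordant_classes(self):
        for lfc_a, lfc_b in [(3.0, 4.0), (-3.0, -4.0), (-3.0, 4.0)]:
            orig = classify_pattern(lfc_a, True, lfc_b, True)
            swapped = classify_pattern(lfc_b, True, lfc_a, True)
            assert orig == swapped  # class depends on signs, not species order


class TestDielCoincidence:
    def test_active_phase_flip_is_coincident(self):
        ok, note = diel_coincidence({"AN": -3.0, "DR": 3.0}, NICHES)
        assert ok and note == ""

    def test_anticoincident_flip(self):
        ok, _ = diel_coincidence({"AN": 3.0, "DR": -3.0}, NICHES)
        assert not ok

    def test_zero_fold_change_is_undefined(self):
        ok, note = diel_coincidence({"AN": 0.0, "DR": 3.0}, NICHES)
        assert not ok and note == "undefined"

    def test_rest_phase_reading_is_the_mirror(self):
        assert rest_phase_coincidence({"AN": 3.0, "DR": -3.0}, NICHES)[0]
        assert not rest_phase_coincidence({"AN": -3.0, "DR": 3.0}, NICHES)[0]


class TestCollapse:
    def omap(self):
        return OrthologMap(
            by_species={
                "AN": {"a1": "G1", "a2": "G1", "a3": "G2", "a4": "G3"},
                "DR": {"d1": "G1", "d2": "G2", "d3": "G3"},
            }
        )

    def test_smallest_adj_p_wins(self):
        de = {
            "AN": de_table([["a1", 2.0, 0.04, True], ["a2", 5.0, 0.01, True]]),
            "DR": de_table([["d1", -1.0, 0.5, False]]),
        }
        collapsed, report = collapse_to_reference(de, self.omap())
        assert collapsed.loc["G1", "transcript_AN"] == "a2"
        assert collapsed.loc["G1", "log2fc_AN"] == 5.0

    def test_unmapped_transcripts_tallied(self):
        de = {"AN": de_table([["a1", 2.0, 0.04, True], ["zz", 1.0, 0.9, False]]),
              "DR": de_table([["d1", 1.0, 0.9, False]])}
        _, report = collapse_to_reference(de, self.omap())
        assert report["AN"]["n_unmapped"] == 1
        assert report["AN"]["n_mapped"] == 1

    def test_hand_checked_toy_collapse(self):
        # 6 transcripts over 3 genes; representatives chosen by smallest adj_p,
        # ties by larger |lfc|
        de = {
            "AN": de_table(
                [
                    ["a1", 2.0, 0.010, True],
                    ["a2", -4.0, 0.010, True],  # tie on adj_p -> larger |lfc| wins
                    ["a3", 1.0, 0.200, False],
                    ["a4", 6.0, 0.001, True],
                ]
            ),
            "DR": de_table([["d1", 3.0, 0.02, True], ["d2", 0.5, 0.7, False]]),
        }
        collapsed, _ = collapse_to_reference(de, self.omap())
        assert len(collapsed) == 3
        assert collapsed.loc["G1", "transcript_AN"] == "a2"
        assert collapsed.loc["G2", "transcript_AN"] == "a3"
        assert collapsed.loc["G3", "transcript_AN"] == "a4"
        assert bool(collapsed.loc["G3", "significant_DR"]) is False  # d3 absent


class TestFlipRecordsAndPairs:
    def build(self):
        de = {
            "AN": de_table(
                [["a1", -3.0, 0.001, True], ["a3", 2.5, 0.004, True], ["a4", -6.0, 0.001, True]]
            ),
            "DR": de_table(
                [["d1", 3.0, 0.002, True], ["d2", 3.1, 0.003, True], ["d3", 0.2, 0.9, False]]
            ),
        }
        omap = OrthologMap(
            by_species={
                "AN": {"a1": "G1", "a3": "G2", "a4": "G3"},
                "DR": {"d1": "G1", "d2": "G2", "d3": "G3"},
            },
            pairwise={("AN", "a1", "DR", "d1"), ("AN", "a3", "DR", "d2")},
        )
        return de, omap

    def test_patterns_and_coincidence(self):
        de, omap = self.build()
        collapsed, _ = collapse_to_reference(de, omap)
        recs = build_flip_records(collapsed, two_species_design())
        assert recs.loc["G1", "pattern"] == "flipped"
        assert bool(recs.loc["G1", "diel_coincident"])
        assert recs.loc["G2", "pattern"] == "concordant_night"
        assert recs.loc["G3", "pattern"] == "single_species_strong"

    def test_pair_records_and_merge(self):
        de, omap = self.build()
        collapsed, _ = collapse_to_reference(de, omap)
        recs = build_flip_records(collapsed, two_species_design())
        pairs = ortholog_pair_de(de, omap, two_species_design())
        assert set(pairs.index) == {"G1", "G2"}  # both transcripts significant
        merged = merge_flip_records(recs, pairs)
        assert merged.loc["G1", "source"] == "reference_collapse+ortholog_pair"
        assert not merged.index.duplicated().any()

    def test_reference_free_pair_emitted(self):
        de = {
            "AN": de_table([["a9", -4.0, 0.001, True]]),
            "DR": de_table([["d9", 4.0, 0.001, True]]),
        }
        omap = OrthologMap(by_species={"AN": {}, "DR": {}},
                           pairwise={("AN", "a9", "DR", "d9")})
        pairs = ortholog_pair_de(de, omap, two_species_design())
        assert len(pairs) == 1
        assert pairs.index[0] == "a9|d9"
        assert pairs.iloc[0]["source"] == "ortholog_pair"


class TestRankCandidates:
    def go(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["G1", "G2"],
                "go_id": ["GO:0000001", "GO:0000002"],
                "go_namespace": ["BP", "BP"],
            }
        )
        return GoTable(records=rec, category_map={"GO:0000001": "circadian"})

    def records(self):
        return pd.DataFrame(
            {
                "log2fc_AN": [-3.0, -2.5, -4.0],
                "adj_p_AN": [1e-8, 1e-4, 1e-3],
                "log2fc_DR": [3.0, 2.5, 4.0],
                "adj_p_DR": [1e-8, 1e-4, 0.5],
                "pattern": ["flipped", "flipped", "not_shared"],
                "diel_coincident": [True, True, False],
                "min_adj_p": [1e-8, 1e-4, 1e-3],
                "evidence": [-16.0, -8.0, -3.0],
            },
            index=pd.Index(["G1", "G2", "G3"], name="ref_gene"),
        )

    def test_scores_count_true_criteria(self):
        out = rank_candidates(self.records(), self.go())
        by_gene = out.set_index("ref_gene")
        assert by_gene.loc["G1", "score"] == 3  # DE both + coincident + circadian GO
        assert by_gene.loc["G2", "score"] == 2  # no functional category
        assert by_gene.loc["G3", "score"] == 0

    def test_rank_order_score_then_evidence(self):
        out = rank_candidates(self.records(), self.go())
        assert out["ref_gene"].tolist() == ["G1", "G2", "G3"]
        assert out["rank"].tolist() == [1, 2, 3]

    def test_evidence_orders_equal_scores(self):
        recs = self.records().drop(index="G3")
        go = GoTable(
            records=pd.DataFrame(
                {
                    "gene_id": ["G1", "G2"],
                    "go_id": ["GO:0000001", "GO:0000001"],
                    "go_namespace": ["BP", "BP"],
                }
            ),
            category_map={"GO:0000001": "circadian"},
        )
        out = rank_candidates(recs, go)
        assert out["ref_gene"].tolist() == ["G1", "G2"]  # stronger evidence first
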