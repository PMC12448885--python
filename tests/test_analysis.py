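"""Heatmaps, residue aggregation, SoF classification, concordance."""

import numpy as np
import pandas as pd
import pytest

import satbind as sb
from satbind.analysis import (
    AnalysisError,
    classify_sof,
    external_concordance,
    heatmap_matrix,
    rank_auc,
    read_residue_attributes,
    residue_aggregate,
    write_residue_attributes,
)


class TestResidueAggregate:
    @pytest.mark.parametrize(
        "scores,expected_sum,expected_n",
        [
            ({"A": 1.0, "C": 0.5, "D": 0.0}, 0.0, 0),  # nothing negative
            ({"A": -2.0, "C": -3.0, "D": 1.0}, -5.0, 2),
            ({a: -5.0 for a in "ACDEFGHIKLMNPQRSTVW"}, -95.0, 19),  # all floored
        ],
    )
    def test_sums_only_negative_substitutions(
        self, score_table_factory, scores, expected_sum, expected_n
    ):
        table = score_table_factory({(50, "Y", a): s for a, s in scores.items()})
        res = residue_aggregate(table)
        row = res[res["pos"] == 50].iloc[0]
        assert row["residue_score"] == pytest.approx(expected_sum)
        assert row["n_substitutions"] == expected_n

    def test_missing_variants_excluded(self, score_table_factory):
        table = score_table_factory(
            {(50, "Y", "A"): -2.0, (50, "Y", "C"): np.nan},
            status={(50, "Y", "C"): "missing"},
        )
        res = residue_aggregate(table)
        assert res[res["pos"] == 50]["residue_score"].iloc[0] == pytest.approx(-2.0)

    def test_monotone_in_substitution_scores(self, score_table_factory):
        base = {(50, "Y", "A"): -1.0, (50, "Y", "C"): 0.5}
        r0 = residue_aggregate(score_table_factory(base))["residue_score"].iloc[0]
        worse = {**base, (50, "Y", "C"): -0.5}
        r1 = residue_aggregate(score_table_factory(worse))["residue_score"].iloc[0]
        assert r1 <= r0


class TestSofClassification:
    GRID = [
        ((-5.0, -5.0), "both_lost"),
        ((-5.0, 0.0), "A_specific_loss"),
        ((-2.0, -0.5), "A_specific_loss"),
        ((0.0, -5.0), "B_specific_loss"),
        ((0.0, 0.0), "both_retained"),
        ((-1.0, -0.9), "both_retained"),
        ((-1.5, 0.0), "indeterminate"),
        ((-5.0, -1.5), "indeterminate"),
        ((-1.2, -1.8), "indeterminate"),
    ]

    @pytest.mark.parametrize("pair,expected", GRID)
    def test_grid_of_paired_scores(self, score_table_factory, pair, expected):
        sa, sbb = pair
        ta = score_table_factory({(10, "Y", "A"): sa})
        tb = score_table_factory({(10, "Y", "A"): sbb})
        calls = classify_sof(ta, tb)
        assert calls["sof_class"].iloc[0] == expected

    def test_partition_every_variant_classified_once(self, score_table_factory):
        rng = np.random.default_rng(5)
        keys = [(p, "Y", a) for p in range(1, 30) for a in "ACD"]
        ta = score_table_factory({k: rng.uniform(-6, 1) for k in keys})
        tb = score_table_factory({k: rng.uniform(-6, 1) for k in keys})
        calls = classify_sof(ta, tb)
        assert len(calls) == len(keys)
        assert set(calls["sof_class"]) <= set(sb.analysis.SOF_CLASSES)

    def test_missing_variants_skipped(self, score_table_factory):
        ta = score_table_factory({(10, "Y", "A"): -5.0, (11, "Y", "A"): np.nan},
                                 status={(11, "Y", "A"): "missing"})
        tb = score_table_factory({(10, "Y", "A"): 0.0, (11, "Y", "A"): 0.0})
        calls = classify_sof(ta, tb)
        assert len(calls) == 1

    def test_inverted_thresholds_rejected(self, score_table_factory):
        t = score_table_factory({(10, "Y", "A"): 0.0})
        with pytest.raises(AnalysisError):
            classify_sof(t, t, tau_loss=-1.0, tau_ret=-2.0)


class TestConcordance:
    def _tables(self, score_table_factory, scores):
        t = score_table_factory(scores)
        return t, t

    def test_perfect_separation_gives_auc_one(self, score_table_factory):
        scores = {(p, "Y", "A"): (-5.0 if p < 20 else 0.0) for p in range(1, 40)}
        ta, tb = self._tables(score_table_factory, scores)
        ann = pd.DataFrame(
            [(p, "A", "pathogenic" if p < 20 else "benign") for p in range(1, 40)],
            columns=["pos", "alt", "label"],
        )
        rep = external_concordance(ta, tb, ann, ["pathogenic"], ["benign"])
        assert rep.auc["score_min"] == 1.0

    def test_numeric_annotation_equal_to_score_gives_spearman_one(
        self, score_table_factory
    ):
        scores = {(p, "Y", "A"): -0.1 * p for p in range(1, 50)}
        ta, tb = self._tables(score_table_factory, scores)
        ann = pd.DataFrame(
            [(p, "A", -0.1 * p) for p in range(1, 50)], columns=["pos", "alt", "value"]
        )
        rep = external_concordance(ta, tb, ann)
        assert rep.spearman["score_min"] == pytest.approx(1.0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(-3, 1, 40), rng.normal(0, 1, 40)
        assert rank_auc(a, b) == pytest.approx(rank_auc(np.exp(a), np.exp(b)))

    def test_vus_with_binding_loss_flagged(self, score_table_factory):
        scores = {(1, "Y", "A"): -5.0, (2, "Y", "A"): 0.0}
        ta, tb = self._tables(score_table_factory, scores)
        ann = pd.DataFrame(
            [(1, "A", "VUS"), (2, "A", "VUS")], columns=["pos", "alt", "label"]
        )
        rep = external_concordance(ta, tb, ann)
        assert rep.flagged_vus["pos"].tolist() == [1]

    def test_empty_annotation_join_rejected(self, score_table_factory):
        ta, tb = self._tables(score_table_factory, {(1, "Y", "A"): 0.0})
        ann = pd.DataFrame([(99, "C", "benign")], columns=["pos", "alt", "label"])
        with pytest.raises(AnalysisError):
            external_concordance(ta, tb, ann)


class TestHeatmapMatrix:
    def test_default_design_shape_and_masks(self, demo_design, mini_design):
        rng = np.random.default_rng(3)
        rows = []
        for k in demo_design.variants:
            rows.append(("missense", k.pos, k.wt_aa, k.alt_aa, rng.normal(-1, 1),
                         0.1, "scored", 3, "1", 0.0))
        frame = pd.DataFrame(rows, columns=[
            "class", "pos", "wt", "alt", "score", "se", "status",
            "n_replicates", "fragments", "offset"])
        frame.loc[0, ["score", "status"]] = [-5.0, "floored"]
        frame.loc[1, ["score", "status"]] = [np.nan, "missing"]
        table = sb.ScoreTable("A", frame)
        mat, mask = heatmap_matrix(table, demo_design)
        assert mat.shape == (214, 20)
        assert (mask.apply(lambda col: col == "wt").sum(axis=1) == 1).all()
        floored = frame.iloc[0]
        assert mat.loc[floored["pos"], floored["alt"]] == -5.0
        assert mask.loc[floored["pos"], floored["alt"]] == "floored"
        missing = frame.iloc[1]
        assert mask.loc[missing["pos"], missing["alt"]] == "na"

    def test_render_smoke(self, score_table_factory, mini_design, tmp_path):
        scores = {
            (k.pos, k.wt_aa, k.alt_aa): -1.0 for k in mini_design.variants[:100]
        }
        mat, mask = heatmap_matrix(score_table_factory(scores), mini_design)
        out = tmp_path / "hm.png"
        sb.analysis.plot_heatmap(mat, mask, out)
        assert out.stat().st_size > 0


class TestResidueAttributes:
    def test_two_residues_two_lines_and_round_trip(self, tmp_path):
        res = pd.DataFrame({"pos": [1646, 1700], "residue_score": [-3.25, 0.0]})
        p1 = tmp_path / "a.defattr"
        write_residue_attributes(res, "binding_loss", p1)
        name, back = read_residue_attributes(p1)
        assert name == "binding_loss"
        assert len(back) == 2
        p2 = tmp_path / "b.defattr"
        write_residue_attributes(back, name, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_attribute_name_rejected(self, tmp_path):
        res = pd.DataFrame({"pos": [1], "residue_score": [-1.0]})
        with pytest.raises(AnalysisError):
            write_residue_attributes(res, "", tmp_path / "x.defattr")
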