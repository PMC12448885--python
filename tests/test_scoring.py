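"""Log-ratio scoring, replicate combination, normalization, curation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satbind as sb
from satbind.scoring import (
    ScoringError,
    ScoringParams,
    combine_replicates,
    normalize_fragments,
    replicate_score,
)

counts_st = st.integers(0, 10_000)


class TestReplicateScore:
    @pytest.mark.parametrize(
        "c_sel,c_non,w_sel,w_non,expected",
        [
            (100, 100, 100, 100, 0.0),
            (10, 100, 100, 100, math.log(10.5 / 100.5)),  # ~ -2.259
            (0, 999, 999, 999, math.log(0.5 / 999.5)),  # ~ -7.600
        ],
    )
    def test_stated_examples(self, c_sel, c_non, w_sel, w_non, expected):
        s, se = replicate_score(c_sel, c_non, w_sel, w_non)
        assert s == pytest.approx(expected, abs=1e-12)
        assert se > 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ScoringError):
            replicate_score(-1, 10, 10, 10)

    @given(c=counts_st, w_sel=counts_st, w_non=counts_st)
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_selective_count(self, c, w_sel, w_non):
        lo, _ = replicate_score(c, 100, w_sel, w_non)
        hi, _ = replicate_score(c + 1, 100, w_sel, w_non)
        assert hi > lo

    @given(c=counts_st, w_sel=counts_st, w_non=counts_st)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_input_count(self, c, w_sel, w_non):
        lo, _ = replicate_score(100, c + 1, w_sel, w_non)
        hi, _ = replicate_score(100, c, w_sel, w_non)
        assert hi > lo

    @given(
        c_sel=st.integers(1, 1000), c_non=st.integers(1, 1000),
        w=st.integers(1, 1000), k=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_depth_quasi_invariance(self, c_sel, c_non, w, k):
        """Scaling every count by k moves the score by at most the
        pseudocount perturbation bound."""
        p = 0.5
        s1, _ = replicate_score(c_sel, c_non, w, w)
        s2, _ = replicate_score(k * c_sel, k * c_non, k * w, k * w)
        bound = sum(
            abs(math.log((c + p) / (k * c + p)) - math.log((w + p) / (k * w + p)))
            for c in (c_sel, c_non)
        )
        assert abs(s2 - s1) <= bound + 1e-12


class TestCombineReplicates:
    def test_equal_se_reduces_to_mean(self):
        s, se = combine_replicates([(-1.0, 0.3), (-2.0, 0.3), (-3.0, 0.3)])
        assert s == pytest.approx(-2.0)
        assert se > 0

    def test_single_replicate_is_identity(self):
        assert combine_replicates([(-2.0, 0.3)]) == (-2.0, 0.3)

    @given(
        scores=st.lists(st.floats(-6, 2), min_size=2, max_size=5),
        ses=st.lists(st.floats(0.05, 1.0), min_size=5, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_combined_score_within_replicate_range(self, scores, ses):
        pairs = list(zip(scores, ses))
        s, _ = combine_replicates(pairs)
        assert min(scores) - 1e-9 <= s <= max(scores) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            combine_replicates([])


def _frag_frame(scores: dict, se=0.1, scored=True) -> pd.DataFrame:
    rows = [("missense", pos, "Y", alt, s) for (pos, alt), s in scores.items()]
    df = pd.DataFrame(rows, columns=["class", "pos", "wt", "alt", "score"])
    df["se"] = se
    df["n_replicates"] = 3
    df["sel_detected"] = scored
    df["input_ok"] = True
    return df


class TestNormalizeFragments:
    def test_identical_overlap_scores_give_zero_offsets(self):
        shared = {(p, a): -1.0 for p in range(70, 76) for a in "ACDE"}
        left = _frag_frame({**{(p, "K"): 0.0 for p in range(1, 70)}, **shared})
        right = _frag_frame({**shared, **{(p, "K"): 0.0 for p in range(76, 140)}})
        _, offsets = normalize_fragments({1: left, 2: right})
        assert offsets == {1: 0.0, 2: 0.0}

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(12)
        true = {(p, a): rng.normal(-1, 1) for p in range(70, 76) for a in "ACDEFGHIKL"}
        left = _frag_frame(true)
        right = _frag_frame({k: v + 1.3 for k, v in true.items()})
        unified, offsets = normalize_fragments({1: left, 2: right})
        assert offsets[2] == pytest.approx(-1.3, abs=0.05)
        # overlap variants end at the mean of the aligned scores
        merged = unified.set_index(["pos", "alt"])["score"]
        for (p, a), v in true.items():
            assert merged[(p, a)] == pytest.approx(v, abs=0.05)

    def test_chained_shifts_accumulate(self):
        base = {(p, a): -0.5 for p in range(1, 40) for a in "ACD"}
        f1 = _frag_frame(base)
        f2 = _frag_frame({k: v + 1.0 for k, v in base.items()})
        f3 = _frag_frame({k: v + 2.0 for k, v in base.items()})
        _, offsets = normalize_fragments({1: f1, 2: f2, 3: f3})
        assert offsets[1] == 0.0
        assert offsets[2] == pytest.approx(-1.0)
        assert offsets[3] == pytest.approx(-2.0)

    def test_sparse_overlap_falls_back_to_zero(self, caplog):
        left = _frag_frame({(70, "A"): -1.0, (1, "K"): 0.0})
        right = _frag_frame({(70, "A"): -3.0, (99, "K"): 0.0})
        with caplog.at_level("WARNING"):
            _, offsets = normalize_fragments({1: left, 2: right})
        assert offsets[2] == 0.0
        assert any("overlap" in r.message for r in caplog.records)


class TestCurationAndEndToEnd:
    def test_undetected_in_selection_floored_at_minus_five(self, hand_counts, mini_design):
        counts = hand_counts({(103, "T", "W"): ([50, 60, 40], [0, 0, 0])})
        table = sb.score_bait(counts, params=ScoringParams())
        row = table.lookup(103, "W")
        assert row["status"] == "floored"
        assert row["score"] == -5.0

    def test_detected_in_any_replicate_stays_scored(self, hand_counts):
        counts = hand_counts({(103, "T", "W"): ([50, 60, 40], [0, 3, 0])})
        row = sb.score_bait(counts).lookup(103, "W")
        assert row["status"] == "scored"
        assert row["score"] < 0  # strongly depleted but not floored

    def test_absent_from_input_pool_is_missing(self, hand_counts):
        counts = hand_counts({(103, "T", "W"): ([0, 0, 0], [0, 0, 0])})
        row = sb.score_bait(counts).lookup(103, "W")
        assert row["status"] == "missing"
        assert np.isnan(row["score"])

    def test_marked_wt_scores_exactly_zero(self, mini_screen):
        _, counts = mini_screen
        table = sb.score_bait(counts, bait="A")
        wt = table.frame[table.frame["class"] == "marked_wt"].iloc[0]
        assert wt["score"] == 0.0
        assert wt["status"] == "scored"

    def test_every_library_variant_gets_exactly_one_status(
        self, mini_design, mini_screen
    ):
        _, counts = mini_screen
        table = sb.score_bait(counts, mini_design, bait="A")
        mis = table.missense()
        assert len(mis) == len(mini_design.variants)
        keys = list(zip(mis["pos"], mis["alt"]))
        assert len(set(keys)) == len(keys)
        assert set(mis["status"]) <= {"scored", "floored", "missing"}

    def test_ground_truth_rank_recovery_on_mini_screen(self, mini_design, mini_screen):
        from scipy import stats

        effects, counts = mini_screen
        table = sb.score_bait(counts, mini_design, bait="A")
        merged = table.missense().merge(
            effects.for_bait("A"), on=["pos", "wt", "alt"]
        )
        ok = merged[(merged["status"] == "scored") & (merged["b"] > 0)]
        rho = stats.spearmanr(ok["score"], np.log(ok["b"])).statistic
        assert rho > 0.3  # shallow screen: noisy but clearly informative
        # the damaged tier separates cleanly from the neutral tier
        crit = merged[merged["pos"].isin([105, 110])]["score"]
        neut = merged[~merged["pos"].isin([105, 110])]["score"]
        assert crit.median() < neut.median() - 1.0
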