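"""Depletion/enrichment scoring of screen count tables.

The score of a variant in one replicate is a WT-referenced log-ratio of its
frequency between the selective and the non-selective pool,

    s_r = ln((c_sel + p) / (w_sel + p)) - ln((c_non + p) / (w_non + p)),

with pseudocount p = 0.5, where w are the counts of the marked-WT spike-in
in the same sample — so library-size normalization cancels and the WT score
is exactly zero.  The standard error follows Poisson count propagation,

    se_r = sqrt(1/(c_sel+p) + 1/(c_non+p) + 1/(w_sel+p) + 1/(w_non+p)).

Replicates are combined by random-effects meta-analysis (method-of-moments
between-replicate variance, clamped at zero).  Because the domain is
sequenced in overlapping amplicon fragments, per-fragment score tables are
stitched onto a common scale using the variants at residues shared by
adjacent fragments (median pairwise difference, accumulated left to right).
Finally, the curation rule: variants well represented in the input pool but
undetected in every selective sample are floored at a fixed score (default
-5, "complete loss of binding"); variants absent from the input pool are
reported as missing rather than floored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import LibraryDesign, VariantKey
from .simulate import NONSELECTIVE, SELECTIVE

__all__ = [
    "ScoringParams",
    "ScoreTable",
    "replicate_score",
    "combine_replicates",
    "score_fragment",
    "normalize_fragments",
    "apply_floor",
    "score_bait",
]

log = logging.getLogger(__name__)

KEY_COLS = ["class", "pos", "wt", "alt"]

STATUS_SCORED = "scored"
STATUS_FLOORED = "floored"
STATUS_MISSING = "missing"


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringParams:
    pseudocount: float = 0.5
    floor: float = -5.0
    min_input_count: int = 10
    combine: str = "random_effects"  # or "mean"
    overlap_estimator: str = "median"  # or "mean"
    min_overlap_scored: int = 5


@dataclass
class ScoreTable:
    """Unified per-bait score table.

    ``frame`` columns: class, pos, wt, alt, score, se, status, n_replicates,
    fragments (provenance string, e.g. "1" or "1+2"), offset (normalization
    offset applied).  ``offsets`` maps fragment index -> cumulative offset.
    """

    bait: str
    frame: pd.DataFrame
    offsets: dict[int, float] = field(default_factory=dict)
    floor: float = -5.0

    def missense(self) -> pd.DataFrame:
        return self.frame[self.frame["class"] == "missense"]

    def lookup(self, pos: int, alt: str) -> pd.Series:
        sub = self.frame[(self.frame["pos"] == pos) & (self.frame["alt"] == alt)]
        if not len(sub):
            raise KeyError(f"{pos}{alt}")
        return sub.iloc[0]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Per-replicate score
# ---------------------------------------------------------------------------

def replicate_score(c_sel, c_non, w_sel, w_non, pseudocount: float = 0.5):
    """WT-referenced log-ratio score and its standard error for one
    replicate.  Accepts scalars or arrays."""
    p = pseudocount
    arrs = [np.asarray(x, dtype=float) for x in (c_sel, c_non, w_sel, w_non)]
    if any((a < 0).any() for a in arrs):
        raise ScoringError("negative counts")
    cs, cn, ws, wn = arrs
    s = np.log((cs + p) / (ws + p)) - np.log((cn + p) / (wn + p))
    se = np.sqrt(1 / (cs + p) + 1 / (cn + p) + 1 / (ws + p) + 1 / (wn + p))
    if np.isscalar(c_sel) or np.ndim(c_sel) == 0:
        return float(s), float(se)
    return s, se


def combine_replicates(scores, ses=None, method: str = "random_effects"):
    """Combine per-replicate (score, se) pairs into one (score, se).

    Random-effects weighting with a method-of-moments between-replicate
    variance (clamped at zero); with equal standard errors this reduces to
    the arithmetic mean.  ``scores``/``ses`` may be 1-D (one variant) or 2-D
    with shape (n_replicates, n_variants).

    A list of (s, se) tuples is also accepted as the single argument.
    """
    if ses is None:
        pairs = list(scores)
        if not pairs:
            raise ScoringError("no replicates")
        scores = np.array([p[0] for p in pairs], dtype=float)
        ses = np.array([p[1] for p in pairs], dtype=float)
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    se = np.atleast_2d(np.asarray(ses, dtype=float))
    scalar = np.ndim(scores) <= 1
    if scalar:
        s, se = s.T, se.T  # (R, 1)
    R = s.shape[0]
    if R == 0:
        raise ScoringError("no replicates")
    if R == 1:
        out_s, out_se = s[0], se[0]
    elif method == "mean":
        out_s = s.mean(axis=0)
        out_se = np.sqrt((se**2).sum(axis=0)) / R
    else:
        w = 1.0 / se**2
        sw = w.sum(axis=0)
        s_fe = (w * s).sum(axis=0) / sw
        q = (w * (s - s_fe) ** 2).sum(axis=0)
        c = sw - (w**2).sum(axis=0) / sw
        with np.errstate(invalid="ignore", divide="ignore"):
            tau2 = np.maximum(0.0, (q - (R - 1)) / c)
        wstar = 1.0 / (se**2 + tau2)
        out_s = (wstar * s).sum(axis=0) / wstar.sum(axis=0)
        out_se = np.sqrt(1.0 / wstar.sum(axis=0))
    if scalar:
        return float(out_s[0]), float(out_se[0])
    return out_s, out_se


# ---------------------------------------------------------------------------
# Per-fragment scoring
# ---------------------------------------------------------------------------

def score_fragment(
    counts: pd.DataFrame, params: ScoringParams = ScoringParams()
) -> pd.DataFrame:
    """Score every scoreable class of one (bait, fragment) count table.

    Returns a frame keyed by (class, pos, wt, alt) with per-variant combined
    score/se plus detection flags used later by the curation rule:
    ``sel_detected`` (selective count > 0 in any replicate) and ``input_ok``
    (non-selective count >= min_input_count in any replicate).
    ``apparent_wt`` reads are excluded from scoring by design: they are an
    unresolvable mixture of true WT and variants mutated in other fragments.
    """
    sub = counts[counts["class"] != VariantKey.APPARENT_WT]
    if not (sub["class"] == VariantKey.MARKED_WT).any():
        raise ScoringError("no marked_wt counts in sample; cannot reference scores")
    piv = sub.pivot_table(
        index=KEY_COLS, columns=["condition", "replicate"],
        values="count", aggfunc="sum", fill_value=0,
    )
    reps = sorted({r for (_, r) in piv.columns})
    full_cols = pd.MultiIndex.from_product([[NONSELECTIVE, SELECTIVE], reps])
    piv = piv.reindex(columns=full_cols, fill_value=0)
    wt_key = (VariantKey.MARKED_WT, 0, "", "")
    wt_row = piv.loc[wt_key]

    s_mat, se_mat = [], []
    for r in reps:
        s_r, se_r = replicate_score(
            piv[(SELECTIVE, r)].to_numpy(),
            piv[(NONSELECTIVE, r)].to_numpy(),
            wt_row[(SELECTIVE, r)],
            wt_row[(NONSELECTIVE, r)],
            params.pseudocount,
        )
        s_mat.append(s_r)
        se_mat.append(se_r)
    s, se = combine_replicates(np.array(s_mat), np.array(se_mat), params.combine)

    sel = piv[SELECTIVE].to_numpy()
    non = piv[NONSELECTIVE].to_numpy()
    out = piv.index.to_frame(index=False)
    out["score"] = s
    out["se"] = se
    out["n_replicates"] = len(reps)
    out["sel_detected"] = (sel > 0).any(axis=1)
    out["input_ok"] = (non >= params.min_input_count).any(axis=1)
    out["rep_scores"] = list(np.array(s_mat).T)
    out["rep_ses"] = list(np.array(se_mat).T)
    return out


# ---------------------------------------------------------------------------
# Cross-fragment normalization
# ---------------------------------------------------------------------------

def normalize_fragments(
    frag_tables: dict[int, pd.DataFrame],
    design: LibraryDesign | None = None,
    params: ScoringParams = ScoringParams(),
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Stitch per-fragment score tables onto a common scale.

    Fragment 1 is the anchor.  For each junction the offset is the
    median (or mean) over missense variants scored in both fragments of
    (left score - right score); offsets accumulate left to right and are
    added to downstream fragments.  Variants present in two fragments get
    the mean of their two aligned scores.  Returns the unified frame (still
    carrying detection flags) and the per-fragment offsets.
    """
    order = sorted(frag_tables)
    est = np.median if params.overlap_estimator == "median" else np.mean
    offsets: dict[int, float] = {order[0]: 0.0}
    for left, right in zip(order, order[1:]):
        lt = frag_tables[left]
        rt = frag_tables[right]
        shared = lt[(lt["class"] == "missense") & lt["sel_detected"] & lt["input_ok"]].merge(
            rt[(rt["class"] == "missense") & rt["sel_detected"] & rt["input_ok"]],
            on=KEY_COLS, suffixes=("_l", "_r"),
        )
        if len(shared) < params.min_overlap_scored:
            log.warning(
                "junction %d-%d: only %d scored overlap variants (<%d); "
                "falling back to offset 0",
                left, right, len(shared), params.min_overlap_scored,
            )
            delta = 0.0
        else:
            delta = float(est(shared["score_l"].to_numpy() - shared["score_r"].to_numpy()))
        offsets[right] = offsets[left] + delta

    aligned = []
    for idx in order:
        t = frag_tables[idx].copy()
        # the marked-WT anchors zero on every fragment's scale, so offsets
        # shift library variants only; spike-in classes stay as scored
        is_lib = (t["class"] == "missense").to_numpy()
        t.loc[is_lib, "score"] = t.loc[is_lib, "score"] + offsets[idx]
        t["fragment"] = idx
        t["offset"] = np.where(is_lib, offsets[idx], 0.0)
        aligned.append(t)
    allf = pd.concat(aligned, ignore_index=True)

    allf["se2"] = allf["se"] ** 2
    g = allf.groupby(KEY_COLS, sort=False)
    unified = g.agg(
        score=("score", "mean"),
        se2=("se2", "sum"),
        n_replicates=("n_replicates", "max"),
        sel_detected=("sel_detected", "max"),
        input_ok=("input_ok", "max"),
        frag_min=("fragment", "min"),
        frag_max=("fragment", "max"),
        k=("fragment", "size"),
        offset=("offset", "mean"),
    ).reset_index()
    unified["se"] = np.sqrt(unified["se2"]) / unified["k"]
    span = {
        (lo, hi): "+".join(str(i) for i in range(lo, hi + 1))
        for lo, hi in set(zip(unified["frag_min"], unified["frag_max"]))
    }
    unified["fragments"] = [
        span[(lo, hi)] for lo, hi in zip(unified["frag_min"], unified["frag_max"])
    ]
    unified["sel_detected"] = unified["sel_detected"].astype(bool)
    unified["input_ok"] = unified["input_ok"].astype(bool)
    unified = unified.drop(columns=["se2", "frag_min", "frag_max", "k"])
    return unified, offsets


# ---------------------------------------------------------------------------
# Curation: floor and missing
# ---------------------------------------------------------------------------

def apply_floor(
    unified: pd.DataFrame,
    design: LibraryDesign | None = None,
    params: ScoringParams = ScoringParams(),
) -> pd.DataFrame:
    """Apply the dropout curation rule on the final (normalized) scale.

    * selective count zero in every sample, input well represented
      -> status ``floored``, score = floor constant (complete loss);
    * input never reaching ``min_input_count`` -> status ``missing``
      (library dropout, not binding loss);
    * otherwise ``scored``.

    When a design is given, library variants absent from the counts are
    appended as ``missing`` so every variant carries exactly one status.
    """
    out = unified.copy()
    floored = ~out["sel_detected"] & out["input_ok"]
    missing = ~out["input_ok"]
    out["status"] = STATUS_SCORED
    out.loc[floored, "status"] = STATUS_FLOORED
    out.loc[floored, "score"] = params.floor
    out.loc[floored, "se"] = np.nan
    out.loc[missing, "status"] = STATUS_MISSING
    out.loc[missing, ["score", "se"]] = np.nan

    if design is not None:
        have = set(zip(out["pos"], out["alt"]))
        absent = [
            ("missense", k.pos, k.wt_aa, k.alt_aa)
            for k in design.variants
            if (k.pos, k.alt_aa) not in have
        ]
        if absent:
            extra = pd.DataFrame(absent, columns=KEY_COLS)
            extra["status"] = STATUS_MISSING
            out = pd.concat([out, extra], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# End-to-end per-bait scoring
# ---------------------------------------------------------------------------

def score_bait(
    counts: pd.DataFrame,
    design: LibraryDesign | None = None,
    params: ScoringParams = ScoringParams(),
    bait: str | None = None,
) -> ScoreTable:
    """Count table (one bait) -> unified, normalized, curated ScoreTable."""
    if bait is None:
        baits = counts["bait"].unique()
        if len(baits) != 1:
            raise ScoringError(f"expected one bait, got {list(baits)}")
        bait = str(baits[0])
    sub = counts[counts["bait"] == bait]
    frag_tables = {
        int(frag): score_fragment(g, params) for frag, g in sub.groupby("fragment")
    }
    if not frag_tables:
        raise ScoringError(f"no counts for bait {bait}")
    unified, offsets = normalize_fragments(frag_tables, design, params)
    final = apply_floor(unified, design, params)
    cols = [
        "class", "pos", "wt", "alt", "score", "se", "status",
        "n_replicates", "fragments", "offset",
    ]
    final = final.reindex(columns=cols)
    final = final.sort_values(["class", "pos", "alt"], kind="stable").reset_index(drop=True)
    return ScoreTable(bait, final, offsets, params.floor)
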