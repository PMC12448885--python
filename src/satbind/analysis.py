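"""Downstream analysis of binding-score tables.

Covers the figure-level products of a paired-bait screen: the position x
amino-acid heatmap matrix, per-residue aggregation for painting scores onto
a structure, separation-of-function classification of paired-bait scores,
and concordance of the combined binding statistic with external annotations
(numeric functionality scores or categorical clinical classes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import AA_ORDER, LibraryDesign
from .scoring import STATUS_FLOORED, STATUS_MISSING, STATUS_SCORED, ScoreTable

__all__ = [
    "residue_aggregate",
    "classify_sof",
    "SOF_CLASSES",
    "external_concordance",
    "ConcordanceReport",
    "heatmap_matrix",
    "plot_heatmap",
    "write_residue_attributes",
    "read_residue_attributes",
]

log = logging.getLogger(__name__)

SOF_CLASSES = (
    "both_lost",
    "A_specific_loss",
    "B_specific_loss",
    "both_retained",
    "indeterminate",
)


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Per-residue aggregation (structure mapping)
# ---------------------------------------------------------------------------

def residue_aggregate(
    table: ScoreTable,
    design: LibraryDesign | None = None,
    tau: float = 0.0,
) -> pd.DataFrame:
    """Per-position sum of the substitution scores that negatively affected
    binding (score < ``tau``); substitutions at or above ``tau`` and
    missing-status variants contribute nothing.

    Returns a frame with columns (pos, residue_score, n_substitutions);
    ``residue_score`` is <= 0 for the default tau = 0.
    """
    mis = table.missense()
    ok = mis[mis["status"] != STATUS_MISSING]
    neg = ok[ok["score"] < tau]
    agg = neg.groupby("pos").agg(
        residue_score=("score", "sum"), n_substitutions=("score", "size")
    )
    if design is not None:
        idx = range(design.domain.start_pos, design.domain.end_pos + 1)
    else:
        idx = sorted(mis["pos"].unique())
    agg = agg.reindex(idx, fill_value=0.0)
    agg["n_substitutions"] = agg["n_substitutions"].fillna(0).astype(int)
    return agg.rename_axis("pos").reset_index()


# ---------------------------------------------------------------------------
# Separation-of-function classification
# ---------------------------------------------------------------------------

def classify_sof(
    table_a: ScoreTable,
    table_b: ScoreTable,
    tau_loss: float = -2.0,
    tau_ret: float = -1.0,
) -> pd.DataFrame:
    """Classify paired-bait scores of every variant scored in both tables.

    loss means score <= tau_loss, retained means score >= tau_ret; scores in
    the open band between the thresholds are indeterminate on that axis.
    Returns columns (pos, wt, alt, score_a, score_b, sof_class).  Variants
    missing in either table are skipped (count logged).
    """
    if tau_loss >= tau_ret:
        raise AnalysisError(f"tau_loss ({tau_loss}) must be < tau_ret ({tau_ret})")
    a = table_a.missense()[["pos", "wt", "alt", "score", "status"]]
    b = table_b.missense()[["pos", "wt", "alt", "score", "status"]]
    merged = a.merge(b, on=["pos", "wt", "alt"], suffixes=("_a", "_b"))
    usable = merged[
        (merged["status_a"] != STATUS_MISSING) & (merged["status_b"] != STATUS_MISSING)
    ].copy()
    n_skip = len(merged) - len(usable)
    if n_skip:
        log.info("classify_sof: skipped %d variants missing in either table", n_skip)

    sa = usable["score_a"].to_numpy()
    sb = usable["score_b"].to_numpy()
    lost_a, ret_a = sa <= tau_loss, sa >= tau_ret
    lost_b, ret_b = sb <= tau_loss, sb >= tau_ret
    cls = np.full(len(usable), "indeterminate", dtype=object)
    cls[lost_a & lost_b] = "both_lost"
    cls[lost_a & ret_b] = "A_specific_loss"
    cls[lost_b & ret_a] = "B_specific_loss"
    cls[ret_a & ret_b] = "both_retained"
    usable["sof_class"] = cls
    return usable[["pos", "wt", "alt", "score_a", "score_b", "sof_class"]].reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Concordance with external annotations
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Agreement between combined binding scores and external annotations."""

    n_joined: int
    spearman: dict[str, float] = field(default_factory=dict)
    spearman_p: dict[str, float] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)
    label_summaries: pd.DataFrame | None = None
    flagged_vus: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        doc = {
            "n_joined": self.n_joined,
            "spearman": self.spearman,
            "spearman_p": self.spearman_p,
            "auc": self.auc,
            "label_summaries": (
                None
                if self.label_summaries is None
                else self.label_summaries.to_dict(orient="records")
            ),
            "flagged_vus": (
                None
                if self.flagged_vus is None
                else self.flagged_vus.to_dict(orient="records")
            ),
            "notes": self.notes,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def rank_auc(pos_scores, neg_scores) -> float:
    """AUC separating two groups, computed from the rank-sum statistic."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def external_concordance(
    table_a: ScoreTable,
    table_b: ScoreTable,
    annotations: pd.DataFrame,
    group_pos: list[str] | None = None,
    group_neg: list[str] | None = None,
    tau_loss: float = -2.0,
    vus_label: str = "VUS",
) -> ConcordanceReport:
    """Compare per-variant binding scores with an external annotation table.

    ``annotations`` must carry (pos, alt) plus either a numeric ``value``
    column or a categorical ``label`` column.  The combined binding statistic
    is min(score_A, score_B): loss of either interaction counts as loss.
    For numeric annotations a Spearman rank correlation is reported per bait
    and for the combined score; for categorical ones, a rank-sum AUC between
    ``group_pos`` and ``group_neg`` labels, per-label score summaries, and
    the list of ``vus_label`` variants with combined score <= tau_loss.
    """
    a = table_a.missense()[["pos", "wt", "alt", "score", "status"]]
    b = table_b.missense()[["pos", "wt", "alt", "score", "status"]]
    scores = a.merge(b, on=["pos", "wt", "alt"], suffixes=("_a", "_b"))
    scores = scores[
        (scores["status_a"] != STATUS_MISSING) & (scores["status_b"] != STATUS_MISSING)
    ]
    joined = scores.merge(annotations, on=["pos", "alt"], how="inner")
    if not len(joined):
        raise AnalysisError("no variants overlap the annotation table")
    joined = joined.copy()
    joined["score_min"] = np.minimum(joined["score_a"], joined["score_b"])

    report = ConcordanceReport(n_joined=len(joined))
    if "value" in joined.columns:
        vals = joined["value"].to_numpy(float)
        for name in ("score_a", "score_b", "score_min"):
            rho, p = stats.spearmanr(joined[name].to_numpy(float), vals)
            report.spearman[name] = float(rho)
            report.spearman_p[name] = float(p)
    if "label" in joined.columns:
        summaries = (
            joined.groupby("label")["score_min"]
            .agg(n="size", mean="mean", median="median")
            .reset_index()
        )
        report.label_summaries = summaries
        if group_pos and group_neg:
            gp = joined[joined["label"].isin(group_pos)]
            gn = joined[joined["label"].isin(group_neg)]
            if len(gp) and len(gn):
                # group_pos is the binding-loss-like class: AUC is the
                # probability that it scores BELOW group_neg, so perfect
                # separation (pathogenic floored, benign at 0) gives 1.0
                for name in ("score_a", "score_b", "score_min"):
                    report.auc[name] = rank_auc(gn[name], gp[name])
            else:
                msg = "a comparison group is empty after the join; AUC omitted"
                report.notes.append(msg)
                log.warning(msg)
        vus = joined[
            (joined["label"] == vus_label) & (joined["score_min"] <= tau_loss)
        ]
        report.flagged_vus = vus[
            ["pos", "wt", "alt", "score_a", "score_b", "score_min", "label"]
        ].reset_index(drop=True)
    return report


# ---------------------------------------------------------------------------
# Heatmap matrix
# ---------------------------------------------------------------------------

def heatmap_matrix(
    table: ScoreTable, design: LibraryDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position x 20 amino-acid score matrix plus a status mask.

    Rows are absolute positions, columns the fixed amino-acid order.  The
    mask marks each cell ``wt`` (the position's wild-type residue), ``na``
    (missing), ``floored`` (dropout at the floor score) or ``scored``.
    """
    positions = list(range(design.domain.start_pos, design.domain.end_pos + 1))
    mat = pd.DataFrame(np.nan, index=positions, columns=list(AA_ORDER))
    mask = pd.DataFrame("na", index=positions, columns=list(AA_ORDER))
    for pos in positions:
        mask.loc[pos, design.domain.aa_at(pos)] = "wt"
    mis = table.missense()
    for row in mis.itertuples(index=False):
        if row.status == STATUS_MISSING:
            continue
        mat.loc[row.pos, row.alt] = row.score
        mask.loc[row.pos, row.alt] = (
            "floored" if row.status == STATUS_FLOORED else "scored"
        )
    mat.index.name = "pos"
    mask.index.name = "pos"
    return mat, mask


def plot_heatmap(mat: pd.DataFrame, mask: pd.DataFrame, path, title: str = "") -> None:
    """Render the score matrix: diverging colours, dark grey for floored
    cells, a dot on the WT cell of each row."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, max(4, len(mat) / 12)))
    data = np.ma.masked_invalid(mat.to_numpy(float))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.9")
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-5, vmax=5)
    floored = (mask.to_numpy() == "floored")
    ys, xs = np.nonzero(floored)
    ax.scatter(xs, ys, marker="s", s=4, color="0.35", linewidths=0)
    wy, wx = np.nonzero(mask.to_numpy() == "wt")
    ax.scatter(wx, wy, marker=".", s=3, color="black")
    ax.set_xticks(range(len(mat.columns)), mat.columns, fontsize=6)
    step = max(1, len(mat) // 30)
    ax.set_yticks(range(0, len(mat), step), mat.index[::step], fontsize=6)
    ax.set_xlabel("substitution")
    ax.set_ylabel("residue")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="binding score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Per-residue attribute export (defattr convention)
# ---------------------------------------------------------------------------

def write_residue_attributes(residues: pd.DataFrame, attr_name: str, path) -> None:
    """Write a per-residue attribute file in the defattr convention: a
    header naming the attribute, then one line per residue
    ``\\t:<pos>\\t<value>`` — suitable for painting onto a structure."""
    if not attr_name:
        raise AnalysisError("attribute name must be non-empty")
    if not len(residues):
        raise AnalysisError("empty residue table")
    with open(path, "w") as fh:
        fh.write(f"attribute: {attr_name}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for row in residues.itertuples(index=False):
            fh.write(f"\t:{int(row.pos)}\t{row.residue_score:.6g}\n")


def read_residue_attributes(path) -> tuple[str, pd.DataFrame]:
    """Parse a defattr-convention file back into (attr_name, frame)."""
    name = ""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("attribute:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("\t:"):
                loc, val = line.strip().split("\t")
                rows.append((int(loc.lstrip(":")), float(val)))
    return name, pd.DataFrame(rows, columns=["pos", "residue_score"])
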