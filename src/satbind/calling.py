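"""Codon-level variant calling for fixed-length amplicon reads.

Each read is assigned to a fragment by primer-anchor matching, trimmed, and
compared codon-by-codon to the WT fragment reference — no alignment is
performed, because amplicons are fixed-length by design.  The classification
decodes the spike-in scheme:

* all expected synonymous marker codons present, no amino-acid change
  -> ``marked_wt`` (the sole WT reference used in scoring);
* a plain-WT read -> ``apparent_wt`` — an unresolvable mixture of true WT
  and variants mutated in other fragments, tabulated but never scored;
* exactly one amino-acid change -> ``missense``;
* the fragment's stop-control marker codons -> ``stop_control``;
* anything else is discarded with an enumerated reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from Bio.Seq import Seq

from .design import AA_ORDER, STOP_CODON, FragmentSpec, LibraryDesign
from .simulate import COUNT_COLUMNS

__all__ = [
    "CallingParams",
    "ReadCall",
    "classify_read",
    "classify_fastq",
    "tabulate",
    "read_fastq",
]

DISCARD_REASONS = (
    "multi_aa_change",
    "indel_or_length",
    "low_quality",
    "anchor_fail",
    "ambiguous",
)


@dataclass(frozen=True)
class CallingParams:
    """Tolerances for read classification.

    max_err_nt: silent (non-marker) nucleotide mismatches tolerated per read.
    min_mean_quality: mean Phred below this discards the read.
    anchor_max_mismatch: mismatches tolerated when matching primer anchors.
    """

    max_err_nt: int = 1
    min_mean_quality: float = 20.0
    anchor_max_mismatch: int = 0


@dataclass(frozen=True)
class ReadCall:
    fragment: int  # 0 when no fragment could be assigned
    kind: str  # missense / marked_wt / apparent_wt / stop_control / discard
    pos: int = 0
    wt_aa: str = ""
    alt_aa: str = ""
    reason: str = ""
    n_mismatched_codons: int = 0

    @property
    def kept(self) -> bool:
        return self.kind != "discard"


@dataclass(frozen=True)
class _FragmentRefs:
    """Pre-computed per-fragment references for fast classification."""

    frag: FragmentSpec
    wt_insert: str
    wt_codons: tuple[str, ...]
    wt_aas: tuple[str, ...]
    marker_codons: dict[int, str]  # codon index -> expected marker codon
    stop_indices: tuple[int, ...]  # codon indices carrying the stop marker
    read_length: int


def _prepare(design: LibraryDesign) -> list[_FragmentRefs]:
    refs = []
    for frag in design.fragments:
        wt = design.wt_insert(frag)
        codons = tuple(wt[i : i + 3] for i in range(0, len(wt), 3))
        aas = tuple(str(Seq(c).translate()) for c in codons)
        markers = {
            p - frag.first_pos: design.marked_wt.markers[p]
            for p in design.marker_positions_in(frag)
        }
        stops = tuple(p - frag.first_pos for p in design.stop_positions_in(frag))
        refs.append(
            _FragmentRefs(
                frag, wt, codons, aas, markers, stops,
                len(frag.left_anchor) + len(wt) + len(frag.right_anchor),
            )
        )
    return refs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def classify_read(
    seq: str,
    qual: str,
    design: LibraryDesign,
    fragment_refs: list[_FragmentRefs] | None = None,
    params: CallingParams = CallingParams(),
) -> ReadCall:
    """Classify one read.  Deterministic and order-independent."""
    refs = fragment_refs if fragment_refs is not None else _prepare(design)

    candidates = [r for r in refs if r.read_length == len(seq)]
    if not candidates:
        return ReadCall(0, "discard", reason="indel_or_length")

    best, best_mm, ties = None, None, 0
    for r in candidates:
        la, ra = r.frag.left_anchor, r.frag.right_anchor
        mm = _hamming(seq[: len(la)], la) + _hamming(seq[len(seq) - len(ra):], ra)
        if best_mm is None or mm < best_mm:
            best, best_mm, ties = r, mm, 1
        elif mm == best_mm:
            ties += 1
    assert best is not None
    if best_mm > params.anchor_max_mismatch:
        return ReadCall(0, "discard", reason="anchor_fail")
    if ties > 1:
        return ReadCall(0, "discard", reason="ambiguous")
    frag_idx = best.frag.index

    if qual and _mean_quality(qual) < params.min_mean_quality:
        return ReadCall(frag_idx, "discard", reason="low_quality")

    insert = seq[len(best.frag.left_anchor): len(seq) - len(best.frag.right_anchor)]

    aa_changes: list[tuple[int, str]] = []  # (codon index, alt aa)
    marker_hits = 0
    stop_hits = 0
    silent_err_nt = 0
    n_mismatched = 0
    bad = False
    for i, wt_codon in enumerate(best.wt_codons):
        codon = insert[3 * i : 3 * i + 3]
        if codon == wt_codon:
            continue
        n_mismatched += 1
        if i in best.marker_codons and codon == best.marker_codons[i]:
            marker_hits += 1
            continue
        if i in best.stop_indices and codon == STOP_CODON:
            stop_hits += 1
            continue
        alt = str(Seq(codon).translate())
        if alt == best.wt_aas[i]:
            silent_err_nt += _hamming(codon, wt_codon)
        elif alt in AA_ORDER:
            aa_changes.append((i, alt))
        else:  # unexpected stop or ambiguous base
            bad = True

    def discard(reason: str) -> ReadCall:
        return ReadCall(frag_idx, "discard", reason=reason,
                        n_mismatched_codons=n_mismatched)

    if len(aa_changes) >= 2:
        return discard("multi_aa_change")
    if bad or silent_err_nt > params.max_err_nt:
        return discard("ambiguous")
    if len(aa_changes) == 1:
        if marker_hits or stop_hits:
            return discard("ambiguous")
        i, alt = aa_changes[0]
        return ReadCall(
            frag_idx, "missense",
            pos=best.frag.first_pos + i, wt_aa=best.wt_aas[i], alt_aa=alt,
            n_mismatched_codons=n_mismatched,
        )
    # no amino-acid change
    if stop_hits:
        if stop_hits == len(best.stop_indices) and marker_hits == 0:
            return ReadCall(frag_idx, "stop_control",
                            n_mismatched_codons=n_mismatched)
        return discard("ambiguous")
    if marker_hits:
        if marker_hits == len(best.marker_codons):
            return ReadCall(frag_idx, "marked_wt",
                            n_mismatched_codons=n_mismatched)
        return discard("ambiguous")
    return ReadCall(frag_idx, "apparent_wt", n_mismatched_codons=n_mismatched)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a FASTQ file (optionally .gz)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].strip(), seq, qual


def classify_fastq(
    path,
    design: LibraryDesign,
    params: CallingParams = CallingParams(),
) -> Iterator[ReadCall]:
    refs = _prepare(design)
    for _, seq, qual in read_fastq(path):
        yield classify_read(seq, qual, design, refs, params)


def tabulate(
    calls: Iterable[ReadCall],
    bait: str,
    replicate: int,
    condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate one sample's calls into the tidy count schema.

    Returns (counts, discards); kept + discarded counts sum to the number of
    input calls.
    """
    kept: dict[tuple, int] = {}
    dropped: dict[tuple, int] = {}
    for call in calls:
        if call.kept:
            key = (call.fragment, call.kind, call.pos, call.wt_aa, call.alt_aa)
            kept[key] = kept.get(key, 0) + 1
        else:
            key = (call.fragment, call.reason)
            dropped[key] = dropped.get(key, 0) + 1
    counts = pd.DataFrame(
        [
            (bait, replicate, condition, frag, kind, pos, wt, alt, n)
            for (frag, kind, pos, wt, alt), n in sorted(kept.items())
        ],
        columns=COUNT_COLUMNS,
    )
    discards = pd.DataFrame(
        [
            (bait, replicate, condition, frag, reason, n)
            for (frag, reason), n in sorted(dropped.items())
        ],
        columns=["bait", "replicate", "condition", "fragment", "reason", "count"],
    )
    return counts, discards
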