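"""Site-saturation library design.

Represents the mutagenised protein domain, the single-substitution variant
library, the overlapping-amplicon fragmentation scheme imposed by a fixed
sequencing read length, and the two spike-in constructs used by the screen:

* a *marked wild type* — the WT coding sequence carrying a synonymous codon
  change at regular residue intervals, so true-WT reads can be told apart
  from reads of variants whose mutation lies in a different fragment;
* a *stop control* — a guaranteed non-binding construct carrying a premature
  stop codon, identifiable in every fragment.

Coordinates are 1-based inclusive residue numbers in full-protein numbering
throughout the public API; DNA offsets are 0-based half-open internally.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio.Seq import Seq

__all__ = [
    "AA_ORDER",
    "HUMAN_CODONS",
    "DomainSpec",
    "VariantKey",
    "FragmentSpec",
    "MarkedWtSpec",
    "LibraryDesign",
    "enumerate_variants",
    "build_fragments",
    "min_fragments",
    "build_marked_wt",
    "build_stop_control",
    "preferred_codon",
]

#: Fixed alphabetical one-letter amino-acid order used for enumeration and
#: heatmap columns.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

STOP_CODON = "TAA"

#: Codons per amino acid, ordered by human codon-usage frequency
#: (most frequent first).  Any deterministic choice suffices for synthetic
#: constructs; human-preferred codons keep the sequences realistic.
HUMAN_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCC", "GCT", "GCA", "GCG"),
    "C": ("TGC", "TGT"),
    "D": ("GAC", "GAT"),
    "E": ("GAG", "GAA"),
    "F": ("TTC", "TTT"),
    "G": ("GGC", "GGA", "GGG", "GGT"),
    "H": ("CAC", "CAT"),
    "I": ("ATC", "ATT", "ATA"),
    "K": ("AAG", "AAA"),
    "L": ("CTG", "CTC", "TTG", "CTT", "CTA", "TTA"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCC", "CCT", "CCA", "CCG"),
    "Q": ("CAG", "CAA"),
    "R": ("AGA", "AGG", "CGG", "CGC", "CGA", "CGT"),
    "S": ("AGC", "TCC", "TCT", "AGT", "TCA", "TCG"),
    "T": ("ACC", "ACA", "ACT", "ACG"),
    "V": ("GTG", "GTC", "GTT", "GTA"),
    "W": ("TGG",),
    "Y": ("TAC", "TAT"),
}

#: Synthetic stand-in amino-acid sequence for the default demo domain.
#: The demo design uses the coordinates of the BRCA1 tandem BRCT domains
#: (residues 1646-1859 of NP_009225, L = 214) but a synthetic sequence:
#: the actual human sequence is not bundled, and nothing downstream depends
#: on sequence identity — only on coordinates and codon bookkeeping.
DEMO_AA_SEQ = (
    "PDRDYQKAIVKEEGLMFPDFAVLDMAPDLQYNVKEMDEAEDEKAPICNFGYSLGGAGRRLRKPC"
    "LGWGNAPPEYERGDVQAVLAGRVALKSRISRENDSLPSLEKEFKLIGEFIPTELSNTVDDEVLE"
    "LTGKSRLRYCKFIITKKVTTSPGFVGHLYFNPLRQCELYINCAFPRATMLPKDPLQRFVYALLK"
    "RLTRALSWTALLVIEGADKTLN"
)

DEMO_START_POS = 1646

#: Hotspot residues of the phospho-peptide-binding pocket, used as the
#: default "critical" class in synthetic screens.
HOTSPOT_RESIDUES = (1655, 1656, 1699, 1701, 1702, 1704, 1775, 1839)


def preferred_codon(aa: str) -> str:
    """Most-frequent human codon for ``aa``."""
    return HUMAN_CODONS[aa][0]


def backtranslate(aa_seq: str) -> str:
    """Deterministic DNA for a protein: most-frequent human codon per residue."""
    return "".join(preferred_codon(a) for a in aa_seq)


def _translate(dna: str) -> str:
    return str(Seq(dna).translate())


class DesignError(ValueError):
    """Raised for invalid or infeasible library designs."""


# ---------------------------------------------------------------------------
# Domain and variant identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpec:
    """The mutagenised domain: WT protein + coding DNA at absolute coordinates.

    ``start_pos``/``end_pos`` are 1-based inclusive residue numbers in
    full-protein numbering.
    """

    protein_label: str
    start_pos: int
    wt_aa_seq: str
    wt_dna_seq: str

    def __post_init__(self) -> None:
        bad = [i for i, a in enumerate(self.wt_aa_seq) if a not in AA_ORDER]
        if bad:
            raise DesignError(
                f"non-standard residue {self.wt_aa_seq[bad[0]]!r} at domain "
                f"position {bad[0] + 1} (absolute {self.start_pos + bad[0]})"
            )
        if len(self.wt_dna_seq) != 3 * len(self.wt_aa_seq):
            raise DesignError(
                f"DNA length {len(self.wt_dna_seq)} != 3 x protein length "
                f"{len(self.wt_aa_seq)}"
            )
        if _translate(self.wt_dna_seq) != self.wt_aa_seq:
            raise DesignError("wt_dna_seq does not translate to wt_aa_seq")

    @property
    def length(self) -> int:
        return len(self.wt_aa_seq)

    @property
    def end_pos(self) -> int:
        return self.start_pos + self.length - 1

    def aa_at(self, pos: int) -> str:
        """WT residue at absolute position ``pos``."""
        self._check_pos(pos)
        return self.wt_aa_seq[pos - self.start_pos]

    def codon_at(self, pos: int) -> str:
        self._check_pos(pos)
        i = 3 * (pos - self.start_pos)
        return self.wt_dna_seq[i : i + 3]

    def _check_pos(self, pos: int) -> None:
        if not self.start_pos <= pos <= self.end_pos:
            raise DesignError(
                f"position {pos} outside domain [{self.start_pos}, {self.end_pos}]"
            )

    @classmethod
    def demo(cls) -> "DomainSpec":
        """Default demo domain: synthetic 214-residue sequence at the
        coordinates of the BRCA1 BRCT region (1646-1859)."""
        return cls(
            protein_label="BRCT-demo",
            start_pos=DEMO_START_POS,
            wt_aa_seq=DEMO_AA_SEQ,
            wt_dna_seq=backtranslate(DEMO_AA_SEQ),
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a library member or spike-in observation class.

    ``kind`` is one of ``missense``, ``marked_wt``, ``apparent_wt``,
    ``stop_control``.  Only missense keys carry (pos, wt_aa, alt_aa);
    class keys use pos=0 and empty amino acids.
    """

    kind: str
    pos: int = 0
    wt_aa: str = ""
    alt_aa: str = ""

    MISSENSE = "missense"
    MARKED_WT = "marked_wt"
    APPARENT_WT = "apparent_wt"
    STOP_CONTROL = "stop_control"

    def __post_init__(self) -> None:
        if self.kind == self.MISSENSE:
            if self.alt_aa == self.wt_aa:
                raise DesignError(f"missense with alt == wt at {self.pos}")
            if self.alt_aa not in AA_ORDER or self.wt_aa not in AA_ORDER:
                raise DesignError(
                    f"non-standard amino acid in {self.wt_aa}>{self.alt_aa}"
                )
        elif self.kind not in (self.MARKED_WT, self.APPARENT_WT, self.STOP_CONTROL):
            raise DesignError(f"unknown variant kind {self.kind!r}")

    def __str__(self) -> str:  # e.g. "K1702E"
        if self.kind == self.MISSENSE:
            return f"{self.wt_aa}{self.pos}{self.alt_aa}"
        return self.kind


def enumerate_variants(spec: DomainSpec) -> list[VariantKey]:
    """All single-substitution variants, position-major, alternatives in
    fixed alphabetical order.  19 per position; ``19 * L`` in total."""
    out: list[VariantKey] = []
    for i, wt in enumerate(spec.wt_aa_seq):
        pos = spec.start_pos + i
        for alt in AA_ORDER:
            if alt != wt:
                out.append(VariantKey(VariantKey.MISSENSE, pos, wt, alt))
    return out


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSpec:
    """One amplicon window: inclusive residue range plus primer anchors."""

    index: int
    first_pos: int
    last_pos: int
    left_anchor: str
    right_anchor: str

    @property
    def n_residues(self) -> int:
        return self.last_pos - self.first_pos + 1

    @property
    def amplicon_nt(self) -> int:
        """Insert length after primer trimming."""
        return 3 * self.n_residues

    def contains(self, pos: int) -> bool:
        return self.first_pos <= pos <= self.last_pos


def _anchor(index: int, side: str, length: int = 12) -> str:
    """Deterministic primer-anchor sequence for a fragment end."""
    seed = zlib.crc32(f"satbind-anchor/{index}/{side}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def min_fragments(length: int, overlap: int, max_amplicon_nt: int) -> int:
    """Smallest fragment count covering ``length`` residues under the
    amplicon length constraint."""
    max_res = max_amplicon_nt // 3
    if max_res <= overlap:
        raise DesignError(
            f"max_amplicon_nt={max_amplicon_nt} cannot fit overlap={overlap}"
        )
    for f in range(1, length + 1):
        per = -(-(length + (f - 1) * overlap) // f)  # ceil
        if per <= max_res:
            return f
    raise DesignError("no feasible fragmentation")  # pragma: no cover


def build_fragments(
    spec: DomainSpec,
    n_fragments: int = 3,
    overlap: int = 4,
    max_amplicon_nt: int = 250,
) -> list[FragmentSpec]:
    """Tile the domain into ``n_fragments`` overlapping windows of near-equal
    size (remainder residues go to earlier fragments); adjacent windows share
    exactly ``overlap`` residues.  Deterministic.
    """
    if n_fragments < 1:
        raise DesignError("n_fragments must be >= 1")
    if overlap < 0:
        raise DesignError("overlap must be >= 0")
    if n_fragments > 1 and overlap == 0:
        # allowed, but fragments then cannot be cross-normalised
        pass
    L = spec.length
    effective = L + (n_fragments - 1) * overlap
    base, rem = divmod(effective, n_fragments)
    lengths = [base + (1 if k < rem else 0) for k in range(n_fragments)]
    if min(lengths) <= overlap and n_fragments > 1:
        raise DesignError("fragments shorter than overlap; reduce n_fragments")
    if n_fragments > 2 and min(lengths) <= 2 * overlap:
        # a fragment shorter than two overlaps would put positions in 3+
        # windows; overlap positions must belong to exactly 2 fragments
        raise DesignError("overlap too large for fragment size; reduce n_fragments")
    if 3 * max(lengths) > max_amplicon_nt:
        need = min_fragments(L, overlap, max_amplicon_nt)
        raise DesignError(
            f"amplicon {3 * max(lengths)} nt exceeds {max_amplicon_nt} nt; "
            f"need at least {need} fragments"
        )
    frags: list[FragmentSpec] = []
    first = spec.start_pos
    for k, ln in enumerate(lengths, start=1):
        last = first + ln - 1
        frags.append(
            FragmentSpec(k, first, last, _anchor(k, "L"), _anchor(k, "R"))
        )
        first = last - overlap + 1
    assert frags[-1].last_pos == spec.end_pos
    return frags


# ---------------------------------------------------------------------------
# Spike-in constructs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkedWtSpec:
    """Marked-WT spike-in: synonymous marker codons at (near-)regular
    intervals.  ``markers`` maps absolute position -> marker codon;
    ``shifted`` records positions moved off single-codon residues (Met/Trp),
    as (nominal, actual) pairs.
    """

    spacing: int
    markers: dict[int, str]
    shifted: tuple[tuple[int, int], ...] = ()

    def positions(self) -> list[int]:
        return sorted(self.markers)


def _synonymous_alternative(wt_codon: str, aa: str) -> str | None:
    for c in HUMAN_CODONS[aa]:
        if c != wt_codon:
            return c
    return None


def build_marked_wt(
    spec: DomainSpec,
    marker_spacing: int = 15,
    codon_table: dict[str, tuple[str, ...]] | None = None,
) -> tuple[MarkedWtSpec, str]:
    """Place a synonymous marker codon every ``marker_spacing`` residues
    (domain-relative positions spacing, 2*spacing, ...).

    A marker falling on Met/Trp (single-codon residues) is shifted to the
    nearest shiftable position; shifts are recorded in the spec.  Returns the
    spec and the full marked DNA sequence, which translates to the WT protein.
    """
    table = codon_table or HUMAN_CODONS
    markers: dict[int, str] = {}
    shifted: list[tuple[int, int]] = []
    taken: set[int] = set()
    n_markers = spec.length // marker_spacing
    for m in range(1, n_markers + 1):
        rel = m * marker_spacing  # 1-based domain-relative
        actual = None
        for delta in range(spec.length):
            for cand in ({rel} if delta == 0 else {rel - delta, rel + delta}):
                if not 1 <= cand <= spec.length or cand in taken:
                    continue
                aa = spec.wt_aa_seq[cand - 1]
                if len(table[aa]) >= 2:
                    actual = cand
                    break
            if actual is not None:
                break
        if actual is None:
            raise DesignError("no shiftable marker position available")
        if actual != rel:
            shifted.append((rel, actual))
        taken.add(actual)
        pos = spec.start_pos + actual - 1
        wt_codon = spec.codon_at(pos)
        alt = _synonymous_alternative(wt_codon, spec.aa_at(pos))
        if alt is None:  # pragma: no cover - excluded by the >=2 codon check
            raise DesignError(f"no synonymous codon at {pos}")
        markers[pos] = alt
    dna = list(spec.wt_dna_seq)
    for pos, codon in markers.items():
        i = 3 * (pos - spec.start_pos)
        dna[i : i + 3] = codon
    marked_dna = "".join(dna)
    assert _translate(marked_dna) == spec.wt_aa_seq
    return MarkedWtSpec(marker_spacing, markers, tuple(shifted)), marked_dna


def build_stop_control(spec: DomainSpec, fragments: list[FragmentSpec]) -> str:
    """Stop-control (guaranteed non-binder) DNA.

    The construct carries a premature stop codon at the first codon of every
    fragment window, so the negative control is identifiable in each
    separately sequenced amplicon (analogous to the marked-WT's distributed
    markers).  Translation terminates at the very first domain codon.
    """
    dna = list(spec.wt_dna_seq)
    for frag in fragments:
        i = 3 * (frag.first_pos - spec.start_pos)
        dna[i : i + 3] = STOP_CODON
    return "".join(dna)


# ---------------------------------------------------------------------------
# Bundled design + serialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesign:
    """Everything the screen needs to know about the library: domain,
    fragment windows, marked-WT scheme, and derived construct sequences."""

    domain: DomainSpec
    fragments: tuple[FragmentSpec, ...]
    marked_wt: MarkedWtSpec
    marked_dna: str
    stop_dna: str
    variants: tuple[VariantKey, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if not self.variants:
            object.__setattr__(
                self, "variants", tuple(enumerate_variants(self.domain))
            )
        for frag in self.fragments:
            if not any(frag.contains(p) for p in self.marked_wt.markers):
                raise DesignError(f"fragment {frag.index} has no marker position")

    @classmethod
    def build(
        cls,
        domain: DomainSpec,
        n_fragments: int = 3,
        overlap: int = 4,
        max_amplicon_nt: int = 250,
        marker_spacing: int = 15,
    ) -> "LibraryDesign":
        frags = build_fragments(domain, n_fragments, overlap, max_amplicon_nt)
        marked, marked_dna = build_marked_wt(domain, marker_spacing)
        stop_dna = build_stop_control(domain, frags)
        return cls(domain, tuple(frags), marked, marked_dna, stop_dna)

    @classmethod
    def demo(cls) -> "LibraryDesign":
        """The default three-fragment, 214-residue demo design."""
        return cls.build(DomainSpec.demo())

    # -- fragment-level views ------------------------------------------------

    def fragments_for(self, pos: int) -> list[FragmentSpec]:
        return [f for f in self.fragments if f.contains(pos)]

    def wt_insert(self, frag: FragmentSpec) -> str:
        i = 3 * (frag.first_pos - self.domain.start_pos)
        return self.domain.wt_dna_seq[i : i + 3 * frag.n_residues]

    def marked_insert(self, frag: FragmentSpec) -> str:
        i = 3 * (frag.first_pos - self.domain.start_pos)
        return self.marked_dna[i : i + 3 * frag.n_residues]

    def stop_insert(self, frag: FragmentSpec) -> str:
        i = 3 * (frag.first_pos - self.domain.start_pos)
        return self.stop_dna[i : i + 3 * frag.n_residues]

    def marker_positions_in(self, frag: FragmentSpec) -> list[int]:
        return [p for p in self.marked_wt.positions() if frag.contains(p)]

    def stop_positions_in(self, frag: FragmentSpec) -> list[int]:
        return [f.first_pos for f in self.fragments if frag.contains(f.first_pos)]

    def overlap_positions(self, left_index: int) -> list[int]:
        """Residues shared by fragment ``left_index`` and its right neighbour."""
        left = self.fragments[left_index - 1]
        right = self.fragments[left_index]
        return [p for p in range(right.first_pos, left.last_pos + 1)]

    def variant_insert(self, key: VariantKey, frag: FragmentSpec) -> str:
        """Amplicon insert of a construct as read in fragment ``frag``."""
        if key.kind == VariantKey.MARKED_WT:
            return self.marked_insert(frag)
        if key.kind == VariantKey.STOP_CONTROL:
            return self.stop_insert(frag)
        if key.kind == VariantKey.APPARENT_WT:
            return self.wt_insert(frag)
        insert = self.wt_insert(frag)
        if not frag.contains(key.pos):
            return insert  # mutation lies in another fragment: reads as WT
        i = 3 * (key.pos - frag.first_pos)
        return insert[:i] + preferred_codon(key.alt_aa) + insert[i + 3 :]

    # -- serialization -------------------------------------------------------

    def to_files(self, yaml_path, fasta_path) -> None:
        """Write the design as a YAML config plus a companion FASTA holding
        the WT, marked-WT and stop-control coding sequences."""
        doc = {
            "protein_label": self.domain.protein_label,
            "start_pos": self.domain.start_pos,
            "wt_aa_seq": self.domain.wt_aa_seq,
            "fragments": [
                {
                    "index": f.index,
                    "first_pos": f.first_pos,
                    "last_pos": f.last_pos,
                    "left_anchor": f.left_anchor,
                    "right_anchor": f.right_anchor,
                }
                for f in self.fragments
            ],
            "marked_wt": {
                "spacing": self.marked_wt.spacing,
                "markers": {int(p): c for p, c in self.marked_wt.markers.items()},
                "shifted": [list(s) for s in self.marked_wt.shifted],
            },
        }
        with open(yaml_path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        with open(fasta_path, "w") as fh:
            for name, seq in (
                ("wt_dna", self.domain.wt_dna_seq),
                ("marked_wt_dna", self.marked_dna),
                ("stop_control_dna", self.stop_dna),
            ):
                fh.write(f">{name}\n{seq}\n")

    @classmethod
    def from_files(cls, yaml_path, fasta_path) -> "LibraryDesign":
        with open(yaml_path) as fh:
            doc = yaml.safe_load(fh)
        seqs: dict[str, str] = {}
        name = None
        with open(fasta_path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    seqs[name] = ""
                elif name:
                    seqs[name] += line
        domain = DomainSpec(
            doc["protein_label"], doc["start_pos"], doc["wt_aa_seq"], seqs["wt_dna"]
        )
        frags = tuple(
            FragmentSpec(
                f["index"], f["first_pos"], f["last_pos"],
                f["left_anchor"], f["right_anchor"],
            )
            for f in doc["fragments"]
        )
        marked = MarkedWtSpec(
            doc["marked_wt"]["spacing"],
            {int(p): c for p, c in doc["marked_wt"]["markers"].items()},
            tuple(tuple(s) for s in doc["marked_wt"]["shifted"]),
        )
        return cls(domain, frags, marked, seqs["marked_wt_dna"], seqs["stop_control_dna"])
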