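"""Synthetic screen generation with known ground truth.

Produces, per bait, a latent binding fitness b in [0, 1] for every library
member, then simulates the pooled selection: variant abundances in the input
pool are log-normal, the non-selective plate samples the pool as-is, and the
selective plate samples proportionally to abundance x survival (survival is
b, or b**g with an optional generations exponent).  Each amplicon fragment
sample is an independent multinomial over the WHOLE pool, so a variant whose
mutation lies in another fragment surfaces as an apparent-WT read — the
ambiguity the marked-WT spike-in exists to resolve.

All operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import HOTSPOT_RESIDUES, LibraryDesign, VariantKey

__all__ = [
    "EffectConfig",
    "DepthConfig",
    "EffectMap",
    "draw_effects",
    "simulate_counts",
    "emit_reads",
    "COUNT_COLUMNS",
]

#: Tidy count-table schema used throughout the pipeline (TSV interchange).
COUNT_COLUMNS = [
    "bait", "replicate", "condition", "fragment",
    "class", "pos", "wt", "alt", "count",
]

NONSELECTIVE = "nonselective"
SELECTIVE = "selective"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth binding-effect classes.

    Positions in ``critical_positions`` draw fitness from the critical range,
    a ``intermediate_fraction`` of the remaining positions (chosen per seed)
    from the intermediate range, the rest from the neutral range.  Explicit
    ``injections`` — (pos, alt_aa, {bait: b}) — override class draws and are
    how separation-of-function ground truth is planted.
    """

    baits: tuple[str, ...] = ("ABRAXAS1", "CtIP")
    critical_positions: tuple[int, ...] = HOTSPOT_RESIDUES
    intermediate_fraction: float = 0.25
    critical_range: tuple[float, float] = (0.0, 0.05)
    intermediate_range: tuple[float, float] = (0.1, 0.7)
    neutral_range: tuple[float, float] = (0.7, 1.0)
    injections: tuple[tuple[int, str, dict], ...] = ()


@dataclass(frozen=True)
class DepthConfig:
    """Sequencing/plating depth: reads per sample, abundance dispersion, and
    replicate count.  ``generations`` is the survival exponent (survival is
    b**g; g=1 models single-round plate viability)."""

    n_per_sample: int = 200_000
    sigma: float = 0.3
    n_replicates: int = 3
    generations: float = 1.0


@dataclass
class EffectMap:
    """Per-bait map variant -> binding fitness, as a tidy frame with columns
    (bait, pos, wt, alt, b).  Spike-ins are fixed: marked_wt b=1,
    stop_control b=0."""

    frame: pd.DataFrame
    baits: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.baits:
            self.baits = tuple(self.frame["bait"].unique())
        bad = self.frame[(self.frame["b"] < 0) | (self.frame["b"] > 1)]
        if len(bad):
            raise SimulationError("binding fitness outside [0, 1]")

    def for_bait(self, bait: str) -> pd.DataFrame:
        return self.frame[self.frame["bait"] == bait].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "EffectMap":
        return cls(pd.read_csv(path, sep="\t"))


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named child stream: toggling one stage never shifts another's draws."""
    import zlib

    child = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(child,)))


def draw_effects(
    design: LibraryDesign, config: EffectConfig, seed: int
) -> EffectMap:
    """Draw ground-truth binding fitness for every missense variant and bait."""
    domain = design.domain
    for pos, alt, _ in config.injections:
        if not domain.start_pos <= pos <= domain.end_pos:
            raise SimulationError(f"injection position {pos} out of range")
    rng = _stage_rng(seed, "effects")
    positions = np.arange(domain.start_pos, domain.end_pos + 1)
    critical = set(config.critical_positions) & set(positions.tolist())
    rest = np.array(sorted(set(positions.tolist()) - critical))
    n_inter = int(round(config.intermediate_fraction * len(rest)))
    inter = set(rng.choice(rest, size=n_inter, replace=False).tolist()) if n_inter else set()

    rows = []
    for bait in config.baits:
        for key in design.variants:
            if key.pos in critical:
                lo, hi = config.critical_range
            elif key.pos in inter:
                lo, hi = config.intermediate_range
            else:
                lo, hi = config.neutral_range
            b = lo if hi == lo else rng.uniform(lo, hi)
            rows.append((bait, key.pos, key.wt_aa, key.alt_aa, b))
    frame = pd.DataFrame(rows, columns=["bait", "pos", "wt", "alt", "b"])
    for pos, alt, per_bait in config.injections:
        for bait, b in per_bait.items():
            sel = (
                (frame["bait"] == bait)
                & (frame["pos"] == pos)
                & (frame["alt"] == alt)
            )
            if not sel.any():
                raise SimulationError(f"injection {pos}{alt} not in library for {bait}")
            frame.loc[sel, "b"] = b
    return EffectMap(frame, tuple(config.baits))


def _construct_index(design: LibraryDesign) -> pd.DataFrame:
    """All physical constructs in the pool: missense library + spike-ins."""
    rows = [("missense", k.pos, k.wt_aa, k.alt_aa) for k in design.variants]
    rows.append((VariantKey.MARKED_WT, 0, "", ""))
    rows.append((VariantKey.STOP_CONTROL, 0, "", ""))
    return pd.DataFrame(rows, columns=["class", "pos", "wt", "alt"])


def simulate_counts(
    design: LibraryDesign,
    effects: EffectMap,
    depth: DepthConfig,
    seed: int,
) -> pd.DataFrame:
    """Simulate read counts for every (bait, replicate, condition, fragment).

    Input abundance a_v ~ LogNormal(0, sigma) per construct, shared across
    conditions and fragments within a replicate; spike-ins get the median
    library abundance.  Non-selective counts ~ Multinomial(N, a/sum a);
    selective counts ~ Multinomial(N, a*b**g / sum).  In each fragment
    sample, constructs mutated outside the fragment are tabulated as
    ``apparent_wt`` (their reads are indistinguishable from plain WT there).
    """
    rng = _stage_rng(seed, "counts")
    constructs = _construct_index(design)
    n_lib = (constructs["class"] == "missense").sum()

    frames: list[pd.DataFrame] = []
    for bait in effects.baits:
        eff = effects.for_bait(bait)
        merged = constructs.merge(eff, on=["pos", "wt", "alt"], how="left")
        b = merged["b"].to_numpy(float)
        b[(constructs["class"] == VariantKey.MARKED_WT).to_numpy()] = 1.0
        b[(constructs["class"] == VariantKey.STOP_CONTROL).to_numpy()] = 0.0
        if np.isnan(b).any():
            raise SimulationError(f"effects missing for some variants of bait {bait}")
        survival = b ** depth.generations
        if not (survival[:n_lib] > 0).any():
            raise SimulationError(
                f"all library binding fitness zero for bait {bait}: no selective pool"
            )
        for rep in range(1, depth.n_replicates + 1):
            a = (
                np.ones(len(constructs))
                if depth.sigma == 0
                else rng.lognormal(0.0, depth.sigma, size=len(constructs))
            )
            med = np.median(a[: n_lib])
            a[n_lib:] = med  # spike-ins at median library abundance
            p_non = a / a.sum()
            p_sel = a * survival
            p_sel = p_sel / p_sel.sum()
            for frag in design.fragments:
                in_frag = (
                    constructs["pos"].between(frag.first_pos, frag.last_pos)
                    & (constructs["class"] == "missense")
                ).to_numpy() | (constructs["class"] != "missense").to_numpy()
                for condition, p in ((NONSELECTIVE, p_non), (SELECTIVE, p_sel)):
                    counts = rng.multinomial(depth.n_per_sample, p)
                    df = constructs.copy()
                    df["count"] = counts
                    # out-of-fragment library members read as plain WT here
                    out = int(df.loc[~in_frag, "count"].sum())
                    df = df[in_frag].reset_index(drop=True)
                    if out > 0:
                        df = pd.concat(
                            [df, pd.DataFrame(
                                [(VariantKey.APPARENT_WT, 0, "", "", out)],
                                columns=df.columns)],
                            ignore_index=True,
                        )
                    # keep marked_wt row even at count 0: scoring needs it
                    df = df[
                        (df["count"] > 0) | (df["class"] == VariantKey.MARKED_WT)
                    ].reset_index(drop=True)
                    df.insert(0, "fragment", frag.index)
                    df.insert(0, "condition", condition)
                    df.insert(0, "replicate", rep)
                    df.insert(0, "bait", bait)
                    frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["pos"] = out["pos"].astype(int)
    out["count"] = out["count"].astype(int)
    return out[COUNT_COLUMNS]


def emit_reads(
    counts: pd.DataFrame,
    design: LibraryDesign,
    error_rate: float,
    seed: int,
    out_dir,
    quality_char: str = "I",
) -> list[str]:
    """Write one FASTQ per (bait, replicate, condition, fragment) sample.

    One read per count: left anchor + construct insert + right anchor, with
    i.i.d. per-base substitution errors at ``error_rate`` and a fixed Phred
    string.  Returns the written file paths.
    """
    import os

    if not 0 <= error_rate <= 0.05:
        raise SimulationError("error_rate must be in [0, 0.05]")
    rng = _stage_rng(seed, "reads")
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    frag_by_index = {f.index: f for f in design.fragments}
    group_cols = ["bait", "replicate", "condition", "fragment"]
    for (bait, rep, cond, frag_idx), sub in counts.groupby(group_cols, sort=True):
        frag = frag_by_index[frag_idx]
        path = os.path.join(out_dir, f"{bait}_r{rep}_{cond}_f{frag_idx}.fastq")
        with open(path, "w") as fh:
            i = 0
            cols = sub[["class", "pos", "wt", "alt", "count"]]
            for cls, pos, wt, alt, n in cols.itertuples(index=False, name=None):
                if n <= 0:
                    continue
                key = (
                    VariantKey("missense", int(pos), wt, alt)
                    if cls == "missense"
                    else VariantKey(cls)
                )
                template = (
                    frag.left_anchor
                    + design.variant_insert(key, frag)
                    + frag.right_anchor
                )
                qual = quality_char * len(template)
                for _ in range(int(n)):
                    seq = template
                    if error_rate > 0:
                        seq = _mutate(seq, error_rate, rng)
                    fh.write(f"@{bait}_r{rep}_{cond}_f{frag_idx}_{i}\n{seq}\n+\n{qual}\n")
                    i += 1
        paths.append(path)
    return paths


_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if not len(hits):
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars)
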