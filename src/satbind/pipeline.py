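"""Pipeline orchestration: config, stage wiring, validation, manifests.

Runs simulate (optional) -> call (optional) -> score -> analyze with a single
root seed feeding named per-stage random streams, TSV interchange between
every stage, and a JSON manifest recording versions, parameters and outputs.
Identical config + seed yields byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .calling import CallingParams, classify_fastq, tabulate
from .design import LibraryDesign, VariantKey
from .scoring import ScoringParams, ScoreTable, score_bait
from .simulate import (
    COUNT_COLUMNS,
    NONSELECTIVE,
    SELECTIVE,
    DepthConfig,
    EffectConfig,
    draw_effects,
    emit_reads,
    simulate_counts,
)
from . import analysis

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every stage parameter with its default; serialisable to/from YAML."""

    design_yaml: str | None = None  # None -> built-in demo design
    design_fasta: str | None = None
    baits: tuple[str, ...] = ("ABRAXAS1", "CtIP")
    seed: int = 0
    out_dir: str = "satbind_out"
    counts_in: str | None = None  # skip simulate/call, score these counts
    reads_in: str | None = None  # directory of FASTQs to call
    simulate_reads: bool = False  # route simulated counts through FASTQ+caller
    error_rate: float = 0.0
    effects: EffectConfig = field(default_factory=EffectConfig)
    depth: DepthConfig = field(default_factory=DepthConfig)
    calling: CallingParams = field(default_factory=CallingParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    annotations_in: str | None = None
    group_pos: tuple[str, ...] = ()
    group_neg: tuple[str, ...] = ()
    tau_residue: float = 0.0
    tau_loss: float = -2.0
    tau_ret: float = -1.0
    render_heatmaps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        if "effects" in kwargs:
            eff = dict(kwargs["effects"])
            if "injections" in eff:
                eff["injections"] = tuple(
                    (int(p), a, dict(m)) for p, a, m in eff["injections"]
                )
            for k in ("baits", "critical_positions", "critical_range",
                      "intermediate_range", "neutral_range"):
                if k in eff:
                    eff[k] = tuple(eff[k])
            kwargs["effects"] = EffectConfig(**eff)
        if "depth" in kwargs:
            kwargs["depth"] = DepthConfig(**kwargs["depth"])
        if "calling" in kwargs:
            kwargs["calling"] = CallingParams(**kwargs["calling"])
        if "scoring" in kwargs:
            kwargs["scoring"] = ScoringParams(**kwargs["scoring"])
        for k in ("baits", "group_pos", "group_neg"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, tuple):
                return [conv(v) for v in x]
            return x

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def load_design(self) -> LibraryDesign:
        if self.design_yaml is None:
            return LibraryDesign.demo()
        if not os.path.exists(self.design_yaml):
            raise PipelineError(f"design file not found: {self.design_yaml}")
        if self.design_fasta is None or not os.path.exists(self.design_fasta):
            raise PipelineError(f"design FASTA not found: {self.design_fasta}")
        return LibraryDesign.from_files(self.design_yaml, self.design_fasta)


def demo_config(out_dir: str = "satbind_out", seed: int = 0) -> PipelineConfig:
    """Default demo: the 214-residue three-fragment design, two baits, and
    two planted separation-of-function variants."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        effects=EffectConfig(
            injections=(
                (1741, "K", {"ABRAXAS1": 1.0, "CtIP": 0.0}),
                (1668, "R", {"ABRAXAS1": 0.0, "CtIP": 1.0}),
            )
        ),
    )


# ---------------------------------------------------------------------------
# Count-table validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    problems: list[str]

    def __str__(self) -> str:
        head = "PASS" if self.ok else "FAIL"
        return "\n".join([head] + self.problems)


def validate_counts(
    counts: pd.DataFrame, design: LibraryDesign | None = None
) -> ValidationReport:
    """Schema and sanity checks on a count table, with line-level diagnostics.

    Checks: required columns, non-negative integer counts, known classes,
    variant keys within the design, and a marked_wt row in every sample.
    """
    problems: list[str] = []
    missing_cols = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing_cols:
        return ValidationReport(False, [f"missing columns: {missing_cols}"])

    valid_classes = {
        "missense", VariantKey.MARKED_WT, VariantKey.APPARENT_WT,
        VariantKey.STOP_CONTROL,
    }
    lib = (
        {(k.pos, k.alt_aa) for k in design.variants} if design is not None else None
    )
    ordered = counts[COUNT_COLUMNS]
    for i, (bait, rep, condition, fragment, cls, pos, wt, alt, n) in enumerate(
        ordered.itertuples(index=False, name=None), start=2  # 1 = header
    ):
        try:
            ni = int(n)
            if ni < 0 or ni != float(n):
                problems.append(f"line {i}: negative or non-integer count {n}")
        except (TypeError, ValueError):
            problems.append(f"line {i}: malformed count {n!r}")
        if condition not in (NONSELECTIVE, SELECTIVE):
            problems.append(f"line {i}: unknown condition {condition!r}")
        if cls not in valid_classes:
            problems.append(f"line {i}: unknown class {cls!r}")
        elif cls == "missense" and lib is not None and (pos, alt) not in lib:
            problems.append(f"line {i}: variant {wt}{pos}{alt} not in design")

    samples = counts[["bait", "replicate", "condition", "fragment"]].drop_duplicates()
    with_wt = counts[counts["class"] == VariantKey.MARKED_WT][
        ["bait", "replicate", "condition", "fragment"]
    ].drop_duplicates()
    missing_wt = samples.merge(with_wt, how="left", indicator=True)
    for row in missing_wt[missing_wt["_merge"] == "left_only"].itertuples(index=False):
        problems.append(
            f"sample (bait={row.bait}, replicate={row.replicate}, "
            f"condition={row.condition}, fragment={row.fragment}) has no marked_wt row"
        )
    return ValidationReport(not problems, problems)


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_counts(path) -> pd.DataFrame:
    """Read a count TSV preserving empty wt/alt fields of spike-in rows."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"wt": str, "alt": str})
    for col in ("replicate", "fragment", "pos", "count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def run_simulate(config: PipelineConfig, design: LibraryDesign, out: str) -> pd.DataFrame:
    effects = draw_effects(design, config.effects, config.seed)
    effects.to_tsv(os.path.join(out, "truth_effects.tsv"))
    counts = simulate_counts(design, effects, config.depth, config.seed)
    if config.simulate_reads:
        reads_dir = os.path.join(out, "reads")
        emit_reads(counts, design, config.error_rate, config.seed, reads_dir)
        counts = run_call(config, design, reads_dir, out)
    _write(counts, os.path.join(out, "counts.tsv"))
    return counts


def run_call(config: PipelineConfig, design: LibraryDesign, reads_dir: str, out: str) -> pd.DataFrame:
    """Classify every FASTQ named <bait>_r<rep>_<condition>_f<frag>.fastq."""
    import re

    frames, discards = [], []
    pattern = re.compile(r"(?P<bait>.+)_r(?P<rep>\d+)_(?P<cond>[a-z]+)_f(?P<frag>\d+)\.fastq(\.gz)?$")
    files = sorted(os.listdir(reads_dir))
    for name in files:
        m = pattern.match(name)
        if not m:
            continue
        calls = classify_fastq(os.path.join(reads_dir, name), design, config.calling)
        c, d = tabulate(calls, m["bait"], int(m["rep"]), m["cond"])
        frames.append(c)
        discards.append(d)
    if not frames:
        raise PipelineError(f"no FASTQ files found under {reads_dir}")
    counts = pd.concat(frames, ignore_index=True)
    disc = pd.concat(discards, ignore_index=True)
    _write(disc, os.path.join(out, "discards.tsv"))
    return counts


def run_score(
    config: PipelineConfig, design: LibraryDesign, counts: pd.DataFrame, out: str
) -> dict[str, ScoreTable]:
    tables: dict[str, ScoreTable] = {}
    offsets_rows = []
    for bait in sorted(counts["bait"].unique()):
        table = score_bait(counts, design, config.scoring, bait=bait)
        table.to_tsv(os.path.join(out, f"scores_{bait}.tsv"))
        for frag, off in table.offsets.items():
            offsets_rows.append((bait, frag, off))
        tables[bait] = table
    _write(
        pd.DataFrame(offsets_rows, columns=["bait", "fragment", "offset"]),
        os.path.join(out, "offsets.tsv"),
    )
    return tables


def run_analyze(
    config: PipelineConfig,
    design: LibraryDesign,
    tables: dict[str, ScoreTable],
    out: str,
) -> None:
    for bait, table in tables.items():
        mat, mask = analysis.heatmap_matrix(table, design)
        mat.to_csv(os.path.join(out, f"heatmap_{bait}.tsv"), sep="\t",
                   float_format=FLOAT_FMT)
        mask.to_csv(os.path.join(out, f"heatmap_mask_{bait}.tsv"), sep="\t")
        res = analysis.residue_aggregate(table, design, config.tau_residue)
        _write(res, os.path.join(out, f"residues_{bait}.tsv"))
        analysis.write_residue_attributes(
            res, f"binding_loss_{bait}", os.path.join(out, f"residues_{bait}.defattr")
        )
        if config.render_heatmaps:
            analysis.plot_heatmap(
                mat, mask, os.path.join(out, f"heatmap_{bait}.png"), title=bait
            )
    if len(tables) == 2:
        t_a, t_b = (tables[b] for b in sorted(tables))
        sof = analysis.classify_sof(t_a, t_b, config.tau_loss, config.tau_ret)
        _write(sof, os.path.join(out, "sof_calls.tsv"))
        if config.annotations_in:
            ann = pd.read_csv(config.annotations_in, sep="\t")
            report = analysis.external_concordance(
                t_a, t_b, ann,
                list(config.group_pos) or None, list(config.group_neg) or None,
                tau_loss=config.tau_loss,
            )
            report.to_json(os.path.join(out, "concordance.json"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    design = config.load_design()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "status": "running",
    }
    manifest_path = os.path.join(out, "manifest.json")
    try:
        with open(os.path.join(out, "config.yaml"), "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        if config.counts_in:
            if not os.path.exists(config.counts_in):
                raise PipelineError(f"counts file not found: {config.counts_in}")
            counts = read_counts(config.counts_in)
            report = validate_counts(counts, design)
            if not report.ok:
                raise PipelineError(f"invalid counts: {report}")
            manifest["stages"].append("load_counts")
        elif config.reads_in:
            counts = run_call(config, design, config.reads_in, out)
            _write(counts, os.path.join(out, "counts.tsv"))
            manifest["stages"].append("call")
        else:
            counts = run_simulate(config, design, out)
            manifest["stages"].append("simulate")
        tables = run_score(config, design, counts, out)
        manifest["stages"].append("score")
        run_analyze(config, design, tables, out)
        manifest["stages"].append("analyze")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
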