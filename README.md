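# satbind

Scoring and analysis of **site-saturation yeast two-hybrid (Y2H)
interaction screens** — deep mutational scans in which every residue of a
protein domain is mutated to all 19 alternative amino acids and each
variant's ability to bind a partner protein is read out by pooled growth
selection and amplicon sequencing.

The package was built around screens of the BRCA1 tandem BRCT domains
(residues 1646–1859, 214 aa, 19 × 214 = 4,066 variants) against the
phospho-peptide partners ABRAXAS1 and CtIP, but the design, scoring and
analysis machinery is generic over any domain, fragmentation and bait set.

It is intended for groups running (or re-analysing) pooled binding screens:
it covers library design and bookkeeping, a synthetic-screen generator with
known ground truth, codon-level variant calling from amplicon FASTQ,
depletion scoring, and the downstream interaction analyses.

## The method

For variant *v* in replicate *r*, with counts *c* on the selective and
non-selective plates and *w* the counts of a **marked wild type** spike-in
(WT carrying a synonymous codon change every 15 residues, so true WT reads
are distinguishable from fragment-local WT reads of variants mutated
elsewhere), the binding score is a WT-referenced log-ratio with pseudocount
p = 0.5:

```
s_vr = ln((c_sel + p)/(w_sel + p)) − ln((c_non + p)/(w_non + p))
se_vr = sqrt(1/(c_sel+p) + 1/(c_non+p) + 1/(w_sel+p) + 1/(w_non+p))
```

Negative scores mean depletion under selection, i.e. loss of binding; the
marked WT scores exactly 0. Replicates are combined by random-effects
meta-analysis (method-of-moments between-replicate variance). Because a
250-nt read limit forces the domain to be sequenced as three overlapping
amplicon fragments, the per-fragment score tables are stitched onto one
scale using the variants at residues shared by adjacent fragments (median
pairwise difference, accumulated left to right). Finally the curation rule:
a variant well represented in the input pool but undetected in **every**
selective sample is assigned the floor score **−5** (complete loss of
binding); a variant absent from the input pool is reported as *missing*,
not floored.

Downstream, the package produces the position × 20 heatmap matrix, sums the
negative substitution scores per residue for structure mapping (defattr
export), classifies paired-bait scores into separation-of-function (SoF)
classes, and quantifies concordance with external annotations (Spearman for
numeric functionality scores, rank-sum AUC for clinical classes).

## Worked example

The built-in demo simulates a full screen on the default 214-residue design
(two baits, three replicates, 200,000 reads per sample, two planted SoF
variants), then scores and analyses it:

```
satbind run --seed 42 --out demo_out
# or: python -m satbind.cli run --seed 42 --out demo_out
```

Key outputs under `demo_out/` (numbers from this exact command):

* `scores_ABRAXAS1.tsv` — 4,045 variants scored, 23 floored at −5.
  The planted SoF variant E1741K scores −0.13 ± 0.15 (binding retained).
* `scores_CtIP.tsv` — the same variant is absent from every CtIP selective
  sample and is floored: score −5, status `floored`.
* `sof_calls.tsv` — E1741K is called `B_specific_loss` (loses CtIP, keeps
  ABRAXAS1), matching its planted ground truth; class totals here were
  3,184 `both_retained`, 653 `indeterminate`, 155 `both_lost`,
  47 `A_specific_loss`, 27 `B_specific_loss`.
* `offsets.tsv` — cross-fragment normalization offsets, e.g. −0.053 for
  fragment 2 of ABRAXAS1 (the fragment-level shift introduced by marked-WT
  sampling noise, which the overlap residues correct).
* `residues_<bait>.tsv` / `.defattr` — per-residue aggregate scores; the
  most negative residues in this run (−73.6, −73.2, −72.1, −71.3 at
  positions 1656, 1702, 1655, 1839) are exactly the simulated binding-pocket
  hotspots.

`truth_effects.tsv` holds the simulated ground-truth binding fitness, so
every downstream claim can be checked against it. Real data enter the same
pipeline either as per-sample FASTQ (`satbind call`) or as a count TSV in
the documented schema (`satbind score --counts ...`), validated with
`satbind validate`.

## Layout

| module | role |
| --- | --- |
| `satbind.design` | domain/variant/fragment/spike-in bookkeeping |
| `satbind.simulate` | ground-truth effects, pool counts, FASTQ emission |
| `satbind.calling` | codon-level read classification and tabulation |
| `satbind.scoring` | log-ratio scores, replicate combination, normalization, curation |
| `satbind.analysis` | heatmaps, residue aggregation, SoF, concordance |
| `satbind.pipeline` / `satbind.cli` | orchestration, validation, CLI |

See `docs/methods.md` for the model, parameter defaults and limitations.
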