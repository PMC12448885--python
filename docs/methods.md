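# Methods

## The screen being modelled

A site-saturation library of a protein domain (every position mutated to
all 19 alternative amino acids) is expressed as Y2H bait and grown as a
pool under two conditions: non-selective (every transformant grows) and
selective (growth requires bait–prey interaction). Deep sequencing of the
domain amplicon before and after selection yields per-variant counts; the
relative frequency change measures each substitution's effect on binding.

Two engineering details of such screens shape the whole pipeline:

1. **Fragmentation.** Reads are shorter than the domain (250 nt vs 642 nt
   for the default 214-residue domain), so the amplicon is sequenced as
   three overlapping windows. A read covering fragment *f* of a variant
   whose mutation lies in another fragment is sequence-identical to wild
   type within *f*. Such "apparent WT" reads are an unresolvable mixture of
   true WT and other-fragment mutants and are therefore tabulated but never
   scored.
2. **Spike-ins.** A *marked WT* — the WT coding sequence with a synonymous
   codon substitution every 15 residues (positions falling on Met/Trp are
   shifted to the nearest substitutable residue and recorded) — is the sole
   WT reference: its markers make true-WT reads identifiable in every
   fragment. A *stop control* carrying a premature stop codon is a
   guaranteed non-binder anchoring the bottom of the scale. In this
   implementation the stop construct carries a stop codon at the first
   codon of every fragment window rather than a single stop at the domain
   start; a single premature stop would make the construct unidentifiable
   (apparent WT) in downstream fragments, so the distributed form — exactly
   analogous to the marked-WT's distributed markers — keeps the negative
   control countable per fragment.

## Scoring model

Per replicate, the score is the WT-referenced natural-log ratio with
pseudocount p = 0.5 (see README for the formula), with a Poisson-
propagation standard error. Referencing to the marked WT cancels
library-size normalization and pins the WT score at exactly zero. The
pseudocount bounds scores when selective counts reach zero and makes the
score depth-quasi-invariant (scaling all counts by k shifts a score by at
most the pseudocount perturbation, which vanishes as counts grow).

**Replicate combination** uses random-effects meta-analysis: fixed-effect
weights 1/se², a method-of-moments between-replicate variance τ² clamped at
zero, re-weighting by 1/(se² + τ²). With homogeneous replicates this is the
inverse-variance mean; with equal standard errors, the arithmetic mean. An
arithmetic-mean mode is available for ablation.

**Cross-fragment normalization.** Fragment samples are amplified and
sequenced independently, so each fragment's scores carry a fragment-level
shift (dominated by sampling noise of the marked-WT reference counts, which
is shared by all variants of a sample). Adjacent fragments share 3–4
residues (57–76 variants); the junction offset is the median (optionally
mean) of left-minus-right score differences over variants scored on both
sides, accumulated left to right with fragment 1 as anchor. Offsets apply
to library variants only — the marked WT defines zero on every fragment and
must remain exactly zero after unification. Variants in an overlap get the
mean of their two aligned scores. Junctions with fewer than 5 scored
overlap variants fall back to offset 0 with a warning.

**Curation.** Applied after normalization, so the floor is on the reported
scale: a variant with selective count 0 in every sample whose non-selective
count reaches `min_input_count` (default 10) in at least one replicate is
*floored* at −5 (complete loss of binding, matching the reported-score
convention for selection dropouts); a variant never reaching
`min_input_count` in the input pool is *missing* (library dropout — no
binding claim). Every library variant carries exactly one status
(scored/floored/missing).

## Synthetic screens

The generator is first-class, tested code: it defines the conditions under
which every downstream guarantee is demonstrated.

* **Ground truth.** Each variant gets a binding fitness b ∈ [0, 1] per
  bait. Positions are classed critical / intermediate / neutral; defaults:
  the eight phospho-binding-pocket hotspot residues (1655, 1656, 1699,
  1701, 1702, 1704, 1775, 1839) are critical with b ~ U(0, 0.05), a
  seed-chosen 25% of remaining positions intermediate with b ~ U(0.1, 0.7),
  the rest neutral with b ~ U(0.7, 1.0) — a mixed landscape spanning full
  loss to neutrality. Explicit injections (pos, alt, per-bait b) override
  class draws and plant separation-of-function ground truth. Marked WT has
  b = 1, stop control b = 0, always.
* **Counts.** Per replicate, input abundance a_v ~ LogNormal(0, σ = 0.3)
  models a near-uniform library with realistic dispersion; spike-ins sit at
  the median library abundance (override via config). Non-selective counts
  are Multinomial(N, a/Σa); selective counts Multinomial(N, a·b^g/Σ) with
  g = 1 by default — plate selection is modelled as single-round survival
  proportional to b, keeping the ground-truth score ln(b) directly
  recoverable; a `generations` exponent is available for growth-style
  selection. Each fragment sample is an independent multinomial over the
  whole pool, so out-of-fragment variants surface as apparent-WT counts,
  reproducing the ambiguity the marked WT resolves.
* **Reads.** Optionally, one FASTQ record per count: anchor + insert +
  anchor with i.i.d. substitution errors (indels excluded — the caller
  rejects length changes anyway) and a fixed Phred string.
* **Depth.** Default N = 200,000 reads per sample (≈ 49× per-variant
  coverage), chosen so a full two-bait, three-replicate screen simulates
  and scores in under a second; the parameter-recovery demonstration uses
  N = 10⁶ (≈ 246×).

What the generator does **not** emulate: PCR jackpotting, index hopping,
chimeras, position-dependent error rates, replicate-correlated abundance,
or bait expression effects. Passing tests therefore demonstrate the
pipeline's statistical behaviour under clean pooled-selection sampling, not
robustness to every artefact of real libraries.

All randomness flows from one root seed through named per-stage child
streams (effects / counts / reads), so toggling one stage never shifts
another's draws, and identical config + seed gives byte-identical TSVs.

## Variant calling

Fixed-length amplicons permit alignment-free, frame-anchored codon
comparison after primer-anchor matching (exact by default, configurable up
to 2 mismatches; ties between fragments are discarded as ambiguous). Rules:
all expected marker codons and no amino-acid change → marked WT (partial
marker sets are discarded as ambiguous, minimizing error-driven
misclassification); no change at all → apparent WT; exactly one amino-acid
change, no markers, and at most `max_err_nt` (default 1) additional silent
mismatches → missense; the fragment's stop-marker codons → stop control.
Everything else is discarded with an enumerated reason (multi_aa_change,
indel_or_length, low_quality, anchor_fail, ambiguous); kept + discarded
always equals input reads. With error-free reads the caller reproduces
simulated count tables exactly.

## Downstream analyses

* **Heatmap matrix**: positions × fixed alphabetical amino-acid order;
  WT cells masked, floored cells carry −5 plus a mask bit, missing cells NA.
* **Residue aggregation**: per position, the sum of substitution scores
  below τ (default 0 — any negative score counts; the cutoff is
  config-exposed since "negatively affected" admits interpretation).
  Exported in the defattr convention for structure painting.
* **Separation of function**: loss = score ≤ τ_loss (−2), retained =
  score ≥ τ_ret (−1); the band between the thresholds is indeterminate on
  that axis. The defaults separate the floored/near-floored cloud from
  retained binders on this score scale. Classes: both_lost,
  A_specific_loss, B_specific_loss, both_retained, indeterminate.
* **Concordance**: the combined binding statistic is min(s_A, s_B) — loss
  of either interaction counts as loss. Numeric annotations get Spearman
  rank correlations; categorical ones a rank-sum AUC oriented so that the
  designated loss-like group scoring lower gives AUC → 1, plus per-label
  summaries and the list of VUS-labelled variants at or below τ_loss. The
  report flags variants; it does not classify them clinically. Annotations
  are user-supplied TSVs keyed by (pos, alt) in absolute residue numbering.

## Numerical and design choices

* Natural log and p = 0.5 throughout; the −5 floor is a configuration
  constant on the reported scale, not derived from the score range.
* Amino-acid order is fixed alphabetical (one-letter); variant enumeration
  is position-major, so all orderings are deterministic.
* Fragment windows are near-equal with remainder residues assigned to
  earlier fragments; boundaries are deterministic. Overlap of 3–4 residues
  and a fragment count of 3 are the defaults under the 250-nt constraint;
  both are config-exposed. Configurations whose windows would cover a
  position more than twice are rejected.
* Missense construct codons use the most-frequent human codon of the target
  amino acid; marker codons the most-frequent synonymous alternative to the
  WT codon. Any deterministic choice would do; these keep sequences
  realistic.
* The default demo domain uses the BRCT coordinates (1646–1859) with a
  synthetic stand-in sequence; no result depends on sequence identity, only
  on coordinates and codon bookkeeping.
* Degenerate inputs: single replicate passes through combination unchanged;
  single fragment skips normalization; empty replicate lists, negative
  counts, all-zero library fitness, inverted SoF thresholds and empty
  annotation joins raise typed errors.

## Known limitations

* The two-condition ratio score deliberately omits time-series
  weighted-regression scoring; the screen has exactly two conditions.
* Apparent-WT reads are discarded from scoring rather than deconvolved;
  with very high per-fragment mutation loads the discarded fraction grows.
* Anchor matching is exact-prefix/suffix, not an aligner; heavily degraded
  read ends inflate anchor_fail rather than being rescued.
* The stop-control geometry (per-fragment stop markers) is an
  identifiability device; it does not model readthrough or truncated
  peptide effects.
* AUC/Spearman concordance quantifies agreement on a synthetic or
  user-provided annotation set; it makes no clinical claim.
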