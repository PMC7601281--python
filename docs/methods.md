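# Methods

## The analysis model

`melpanel` treats germline panel testing as three coupled problems:
deterministic variant triage, binomial carrier counting, and 2×2
contingency inference.

### Variant triage

Every subject×variant observation carries a fixed annotation vector
(consequence class, caller quality, maximum external-database MAF,
control allele count, ClinVar class, repeat-region / last-exon flags,
and a functional-assay verdict). The cascade is a short-circuiting
sequence of nine predicates evaluated in a fixed order; the first true
predicate eliminates the variant and is recorded, so the per-step audit
table is a partition of the input. Key semantic choices:

- **Rescue.** ClinVar P/LP classification or a deleterious functional
  result exempts a variant from steps 2–9 but *not* from the quality
  filter: a pathogenic allele supported by a low-quality call is still a
  low-quality call. This makes step 1 the only step that can eliminate a
  rescued variant.
- **Control-frequency filter (step 5).** The two published forms of the
  threshold — "MAF > 0.001" and "allele count > 2" — coincide at 2×1479
  control alleles (3/2958 ≈ 0.00101), and the allele-count form is
  taken as authoritative because it is exact under the cohort size.
- **Strict thresholds.** quality exactly 150 is retained (`< 150`
  eliminates); MAF exactly 0.003 and allele count exactly 2 are
  retained.
- **Last-exon rule (step 9)** applies to both frameshift and stop-gain
  variants: a truncating allele whose premature stop lands in the final
  exon escapes nonsense-mediated decay and is *not* assumed damaging.
- **CNVs.** Frameshifting CNVs are P/LP-eligible like other truncating
  classes; non-frameshifting CNVs are VUS unless rescued. CNV records
  are keyed `chrom:start-end:CNV:type` since ref/alt literals are
  meaningless for them.
- **P/LP calling.** Survivors are P/LP iff truncating-class
  (frameshift, stop-gain, frameshifting CNV, canonical splice) or
  rescued; all other survivors are VUS and are excluded from every
  downstream statistic.

Variant identity is the literal `chrom:pos:ref:alt` string; inputs are
assumed pre-normalized (left-alignment and multi-allelic splitting are
the upstream caller's job, though the VCF reader does split multi-ALT
records). Canonical-splice status (±1–2 intronic nt) is consumed as an
annotation, not recomputed — the package deliberately carries no
transcript database.

### Carrier counting

A carrier has ≥1 P/LP variant in the stratum (gene or risk class) and
counts once regardless of variant multiplicity. Multi-class carriers are
attributed to the highest-risk class: high-to-moderate melanoma (rank 1)
> cancer syndrome (2) > low-risk melanoma (3) > unknown risk (4). Burden
tables come in two modes: multi-variant carriers **included** (each
counted once, in the assigned class) or **excluded**, which removes them
from the case arm's numerator *and* denominator. Exclusion is applied to
the case arm only: the reference analysis this mirrors kept the full
control denominator in both modes (its control columns are identical
across modes even though the control set demonstrably contains
multi-variant carriers), and "filtered identically" refers to the
cascade, not to carrier exclusion.

### Inference on 2×2 tables

- Odds ratio: cross-product `ad/bc`; undefined (NaN) when `bc = 0`.
  An optional Haldane–Anscombe correction (+0.5 to every cell) is off by
  default, matching the reporting convention of showing no OR when a
  control cell is empty.
- 95% CI: Woolf's log-normal interval,
  `exp(ln OR ± 1.959964·√(1/a+1/b+1/c+1/d))`. This method reproduces the
  reference intervals at one printed decimal for all tables with
  moderate counts; for the extreme 9/264-vs-1/1479 table the upper bound
  computes to 413.5 where 413.1 was printed, and for the 12-vs-35 table
  the count-based OR is 1.96 where 1.9 was printed (the printed CI
  1.0–3.8 *does* match the counts; the printed OR is consistent with
  odds recomputed from percentages rounded to one decimal). The package
  always reports its own computed values.
- p-values: two-sided Fisher exact (hypergeometric tail mass ≤ observed,
  scipy-backed, cross-checked in the tests against an independent
  exhaustive enumeration) and Pearson χ² with 1 df and no Yates
  correction, always computed side by side; no multiple-testing
  correction is applied to the primary output (an optional
  Benjamini–Hochberg helper exists but never alters it).

### Clinical stratification

Personal history partitions into five mutually exclusive categories by
rule order: multiple melanoma + other cancer → multiple melanoma →
melanoma + other cancer → single melanoma split at age < 25 strictly
(25 exactly is the older group). The tumor-multiplicity OR compares
carriers of clinically relevant mutations (high-to-moderate ∪ syndrome
tiers) between probands with ≥2 primary tumors and single-melanoma
probands, with multi-variant carriers excluded; it reuses the burden
machinery unchanged. Family-history comparisons drop records with
unknown family history and use negative history as the reference. For
the per-category comparisons both a pairwise Fisher test against the
reference category and (via the burden module) full-table χ² are
available, since either convention is defensible for ordered category
panels.

## The synthetic-data generator

The generator emulates what the analysis *assumes* about real cohorts,
with defaults fixed at the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_cases` / `n_controls` | 264 / 1479 | cohort sizes |
| case carrier probs | 0.034 / 0.083 / 0.045 / 0.106 | per class (high/syndrome/low/unknown) |
| control carrier probs | 0.0007 / 0.039 / 0.024 / 0.089 | per class |
| `background_intensity` | 12 | Poisson mean decoys per subject |
| `multiplicity_theta` | 3.0 | odds tilt of multi-tumor categories for relevant carriers |
| `extra_double_class_fraction` | 0.02 | promotes single-class carriers to a second class |
| `seed` | 0 | single RNG; every draw flows from it |

Carrier status is drawn per subject per class (independent Bernoulli);
each carrier receives one planted P/LP variant from a five-allele
recurrent pool per gene (allele identity fixes annotation, so shared
variants never conflict; consequence mix 40% frameshift, 25% stop-gain,
20% canonical splice, 10% ClinVar-P missense, 5% functionally
deleterious missense — the last two exercising both rescue routes).
Independent class draws alone give ~2.4% multi-class carriers at the
default frequencies; the 2% promotion fraction brings the multi-variant
carrier share to ~4%, the observed regime. Decoy variants draw an
intended fate from a fixed mix over the nine elimination steps plus a
surviving-VUS slot (5/25/17/20/8/10/2/2/1/10%), with annotations
constructed so the intended step is provably the *first* matching
predicate; the 10% VUS slot makes VUS ≈ 87% of cascade survivors,
matching the share reported for real panel data. Clinical categories
are drawn from the reference cohort's marginals (6/17/71/36/134 personal,
60/136/47/21 family), with the multi-tumor categories' odds multiplied
by θ for clinically relevant carriers.

The generator does **not** model annotation error, so 100% truth-ledger
identity shows the engine implements the rules exactly — not that the
rules are robust to noisy annotation. It also has no LD/haplotype
structure, no realistic site-frequency spectrum, and synthetic dummy
gene intervals instead of transcripts.

A carrier-level fast path (`simulate_carrier_table`) draws a class's
2×2 table directly from the same binomial model. Replicate studies
(OR recovery, test calibration) use it because the variant layer is
lossless for planted carriers — a property the end-to-end identity
check proves separately on full variant-level simulations — so the fast
path adds replicates, not approximation. Recovery studies plant odds
ratios of 2/10/50 on control baselines 0.039/0.01/0.004, chosen so
expected control carrier counts stay ≳6 and zero-cell tables are rare
(rare zero-control tables are ranked +∞ when taking the median OR, the
natural ordering for an unbounded-above estimate). The null-calibration
check uses the largest class frequency (0.089): Fisher's exact test is
intentionally conservative at tiny expected counts (at the
high-to-moderate tier's 0.0007 it rejects far below nominal), which is
a property of the test, not of the pipeline, and the calibration check
is meant to exercise the latter.

## Problem sizes and determinism

The shipped test suite runs ~110 tests in well under a minute: the
conformance fixture has 60 variants covering all nine steps, both rescue
routes and every boundary; end-to-end identity uses ten full cohorts at
default size (~21k variants each); recovery and calibration use 500
replicates per condition. Property-based tests (hypothesis) are
derandomized; all simulation tests use fixed seeds. `simulate_cohort` is
byte-reproducible for a given config and seed; pipeline outputs carry a
JSON manifest with the parameter snapshot, input checksums, seed and
version.

## Known limitations

- No annotation computation (no VEP/SnpEff equivalent), no liftover, no
  transcript models, no re-alignment/normalization of input alleles.
- No ACMG re-classification beyond the operational P/LP rule; in-frame
  indels are reachable as P/LP only via ClinVar/functional rescue.
- No covariate adjustment, logistic regression or population
  stratification control in the burden statistics.
- Per-gene control carrier counts in real applications come from the
  input data; the packaged tests back-derive illustrative per-gene
  tables (e.g. a 7-vs-4 carrier split reproducing a ten-fold *NBN*
  enrichment) from published summary ratios and label them as such.
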