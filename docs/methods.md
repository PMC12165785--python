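# Methods

## Functional score

For one variant, condition and replicate, the assay readout is a vector of
classified read counts (variant-edited, WT′-edited, frameshift indel,
other). The score of a day-12 arm is the variant/WT′ count ratio divided by
the same replicate's day-2 ratio, expressed as a percent; day 2 is 100% by
construction. Normalization happens per replicate **before** averaging —
pooling counts across replicates would weight replicates by depth and bias
the ratio when depth and effect covary. Replicates are summarized as the
arithmetic mean and the sample SD (n−1 denominator; whether the original
analysis used sample or population SD is not stated — sample SD is the
conventional choice for 3 biological replicates). A single surviving
replicate reports SD 0 with a warning rather than NaN.

Zero WT′ reads make the ratio undefined: the sample errors out and must be
handled explicitly (an optional +0.5 pseudocount was considered and
rejected — no smoothing is part of the measurand's definition, and a WT′
dropout indicates a failed edit or sample swap that should be seen, not
papered over).

## Read classification

Allele tables (aligned sequence, read count, inserted/deleted bases — the
CRISPResso2 output dialect) are classified by exact sequence identity
against the expected variant and WT′ amplicons. Rows matching neither are
frameshift when the net indel length is not divisible by three, otherwise
"other" (this includes unedited reference reads and substitution-only
mismatches). Fuzzy matching is deliberately absent: the upstream aligner
already produced aligned allele strings, and exactness keeps the partition
reproducible bit for bit. Consequence: partial-HDR alleles (variant edit
without accompanying silent PAM mutations) fall into "other" rather than
the variant class; with fully specified edit templates this undercounts
both edited classes symmetrically and cancels in the ratio to first order.

Samples under 7,500 total reads fail QC and are excluded; a failed day-2
baseline invalidates its entire replicate, since every day-12 arm of that
replicate loses its denominator.

## Thresholds and calibration

Arms are categorized from the replicate mean (the quantity plotted against
the threshold lines): deleterious ≤ 25% < intermediate ≤ 50% < neutral.
The two-threshold scheme is configuration with these defaults, not an
inference — ROC analysis on the controls is reported (AUC, curve, and the
Youden-J single cutoff) for transparency, but a two-threshold operating
procedure is not uniquely determined by a ROC curve, so the constants are
the source of truth.

The calibration score of a control is its **minimum** replicate-mean ratio
across the four day-12 arms: functional evidence for pathogenicity is
triggered by deleteriousness in any single arm, so the worst-case arm is
the decision-relevant summary. Sensitivity and specificity use the binary
readout abnormal = (score ≤ 25%) with Wilson 95% score intervals
(statsmodels); at k = n the Wilson lower bound reduces algebraically to
n/(n + z²), which the tests check to 1e-12. The Brown hybrid variant
coincides with plain Wilson at the k = n cases that arise here.

OddsPath follows the ClinGen SVI functional-evidence calibration: prior
P1 = pathogenic fraction among controls, posterior P2 = pathogenic
fraction within a readout class, OddsPath = [P2(1−P1)]/[(1−P2)P1]. A pure
readout class (only one truth present) gets exactly one hypothetical
opposite-truth control added before computing P2; this correction applies
only to the pure class. Counts being integers, the computation uses exact
rational arithmetic. Strength cutpoints: pathogenic ≥ 350 very strong,
≥ 18.7 strong, ≥ 4.3 moderate, ≥ 2.1 supporting; benign ≤ 0.00285,
≤ 0.053, ≤ 0.23, ≤ 0.48 on the reciprocal scale.

## Evidence codes and combination

One PS3/BS3 code per variant: PS3 at the calibrated strength if any arm is
deleterious; PS3 at indeterminate strength (0 points) if the worst arm is
intermediate — hypomorphic behaviour must not be converted into benign
evidence; BS3 at the calibrated strength only when every assessable arm is
neutral. A variant with no QC-passing arm is "not assessable".

Population codes band the maximum nonfounder filter allele frequency:
BA1 > 0.001 (stand-alone benign), BS1 > 0.0001, BS1-supporting > 0.00002;
below that, an observed minor allele frequency gives PM2 at indeterminate
strength (0 points) and absence from controls gives PM2-supporting.
Computational codes: PP3 when SpliceAI Δmax ≥ 0.2 or BayesDel_noAF ≥ 0.30;
BP4 when SpliceAI ≤ 0.1 and BayesDel ≤ 0.18; the gap between the bands
yields no code. Asserted splicing codes pass through with exclusions: a
PVS1(RNA) assertion suppresses both PS1(Splicing) and PP3 for the same
variant, so the splicing impact is never counted twice.

Codes are combined twice. The point system sums supporting/moderate/
strong/very-strong as ±1/±2/±4/±8 (indeterminate 0) onto the scale
benign ≤ −7, likely benign −6..−2, uncertain −1..5, likely pathogenic
6..9, pathogenic ≥ 10, with BA1 short-circuiting to benign. The
qualitative 2015 rules are implemented as published; two gaps required
decisions: (a) moderate-strength benign codes have no 2015 slot and count
as two benign-supporting (standard VCEP practice; it is also what lets
BS3-moderate + BP4 reach likely benign); (b) "conflicting evidence"
defaults to uncertain only when both a pathogenic and a benign rule are
simultaneously satisfied. The final class requires the two systems to
agree; otherwise the variant is uncertain and flagged discordant. An
exhaustive scan over all implementable code bundles shows the systems
never reach opposite extreme classes (pathogenic vs benign); they can land
on opposite sides at the "likely" level for extreme discordant bundles
(e.g. a very-strong RNA code plus two benign-supporting codes, +6 points
but qualitatively likely benign because a lone very-strong code satisfies
no 2015 pathogenic rule) — exactly the situation the concordance
requirement resolves to uncertain.

## Synthetic data

The generator's defaults are the study conditions: 9 benign controls, 14
pathogenic controls, 54 queries; 3 replicates; ≥ 7,500 (default 10,000)
reads/sample; frameshift day-12 retention 0.2 (strong negative selection);
replicate CV 0.1. Day-2 HDR incorporation fractions are not reported
anywhere, so they are free parameters with defaults (variant 0.12,
WT′ 0.12, frameshift 0.25, other 0.51) — both knockin alleles around 12%
and a large CRISPR-byproduct class, typical of ssODN-templated editing with
an efficient guide.

Selection is parameterized directly by the target normalized ratio per arm
(the generations elapsed between day 2 and day 12 are unknown, and any
fitness-per-generation parameterization would only re-derive this number),
so simulated truth and measurand coincide. Per sample, a mean-one
log-normal factor multiplies the variant fraction, "other" absorbs the
remainder (an error if the simplex is left), and one multinomial draw
produces the four class counts. Because the noise also perturbs the day-2
denominator, the normalized-ratio estimator carries a small positive bias
of order CV² (~1% at CV 0.1) — visible in the Monte-Carlo recovery test's
tolerance and irrelevant at the 25/50 decision boundaries.

Query strata (neutral 0.80, intermediate 0.06, deleterious 0.14,
half of the deleterious stratum splice-like) approximate the study panel's
outcome mix (45 of 54 neutral; T10K/G25R-style hypomorphs; 7 variants
deleterious in at least one arm, 4 of them splice-region with MMC-specific
depletion). Deleterious missense variants deliberately carry benign-band
BayesDel scores: in this domain the metapredictor disagrees with the
functional readout, and the pipeline must reproduce the resulting
uncertain calls, not wish them away. Panel annotations (FAF/MAF bands,
scores, asserted splicing codes) are synthetic stand-ins for curated
values; passing end-to-end tests therefore demonstrates the machinery and
its decision logic, not concordance with any real cohort.

Everything is seeded (numpy Generator; per-variant streams derived from
the seed and a CRC of the variant id), and identical inputs give
byte-identical outputs, including the written allele tables.

## Problem sizes

The test suite and the acceptance script run the study-sized panel
(77 variants × 15 samples × 10,000 reads), a 1,000,000-read consistency
check of the generator against its own truth (1% tolerance), a 300-dataset
Monte-Carlo recovery of a 20% true ratio, and an 80-variant parameter
recovery experiment; these sizes make every check deterministic-in-
practice while keeping a full run in the low minutes on one CPU.

## Known limitations

- No modeling of sequencing error, PCR duplicates or alignment ambiguity;
  ingest trusts the upstream aligner's allele strings.
- Calibration assumes binary control truth; variants with conflicting
  prior classifications (risk alleles) must be excluded upstream, as the
  pipeline does by role.
- The evidence-code set covers the codes usable for rare variants in this
  assay context (PS3/BS3, PM2/BA1/BS1, PP3/BP4, PS1-splicing, PVS1-RNA);
  segregation, case-control and co-occurrence codes (PP1/BS4, PS4,
  PM3/BS2, PP4/BP5) are out of scope by design.
- Domain-specific recalibration (e.g. separate control sets per protein
  domain) is not provided; the OddsPath machinery accepts any control set,
  so callers can calibrate per domain by filtering controls.
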