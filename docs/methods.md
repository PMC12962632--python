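# Methods

## Data model

A cohort is a table of trial participants, each joining clinical staging
and treatment attributes (trial, age, M-stage, R-status, histology, CSI
arm, carboplatin flag, boost field, PFS/OS follow-up) with molecular
annotations (molecular group WNT/SHH/G3/G4, methylation subgroup, binary
mutation/amplification flags, chromosome-level calls). Survival times are
months; the 5-year horizon used throughout is t = 60.

Missingness is pervasive in trial data (histology in particular, and
sequencing-derived flags were only available for a subset of patients), so
missing values are first-class: the literal `NA` on disk, a distinct
unknown state in memory (`None` for tri-state flags, an `unknown`/`none`
enum member otherwise). No operation coerces unknown to a concrete
category; operations either carry unknowns through, flag them, or refuse.

Record-level invariants are enforced at validation: PFS ≤ OS when both are
present, carboplatin only on ACNS0332, LDCSI only on ACNS0331.

## Copy-number calling

Input is a SEG-dialect table (`sample_id, chrom, loc.start, loc.end,
num.mark, seg.mean`), 1-based inclusive on disk and converted to 0-based
half-open in memory (asserted by round-trip tests).

* **Baseline and scale.** The reference baseline is the
  probe-count-weighted median of autosomal segment log2 ratios; the MAD is
  the weighted median absolute deviation around it. Probe-count weighting
  is used because segment sizes span orders of magnitude and unweighted
  medians over-weight tiny segments. The 1.4826 normal-consistency
  constant is deliberately omitted: the calibrated quantity is the
  multiplier (4×), not the scale convention. Sex chromosomes are excluded
  from baseline/MAD estimation to avoid ploidy-by-sex artifacts.
* **Focal events.** A segment qualifies when |log2 − baseline| >
  4 × max(MAD, floor); adjacent qualifying segments on the same side are
  merged before the < 10 Mb length test, because segmentation can split
  one amplicon and it is the event, not the segment, that must be focal.
  The MAD floor (default 0.01) guards against near-noiseless profiles
  where 4×MAD would approach zero. A caveat of merge-then-measure: raising
  the multiplier can in principle split a ≥ 10 Mb run into two sub-runs
  that each pass the length test, so monotonicity of the call set in the
  multiplier holds for isolated (single-segment) events but not for every
  pathological multi-segment configuration.
* **Chromosome and arm calls.** A chromosome is called gain (loss) when
  the length-weighted mean deviation exceeds +0.1 (falls below −0.1) *and*
  at least 80 % of covered length lies on that side of the baseline. These
  three thresholds are package configuration with stated defaults, not
  literature constants. The 17p call clips chr17 segments at the packaged
  hg19 arm boundary (24.0 Mb, the p-arm side of the centromere gap);
  arm-level rather than whole-chromosome 17 was chosen because isochromosome
  17q — 17p loss with 17q gain — is the common configuration and would
  cancel in a whole-chromosome average. Absent chromosomes are called
  unknown with a logged warning.
* **WCA-FR phenotype.** True iff ≥ 2 of {chr7 gain, chr8 loss, chr11
  loss}; unknown calls propagate to an unknown phenotype only when the
  known calls neither reach two hits nor rule them out.
* Whether the MAD should be per-sample or per-reference-set is not
  determined by the source material; per-sample is implemented, and the
  multiplier, length cap, and floor are exposed parameters.

## Harmonization

The six analysis categories and their merge into four treatment categories
are fixed rules applied in order; every patient receives exactly one
category (partition property), and each assignment carries its matched
rule label. Unknown histology is treated as non-LC/A for eligibility —
the trials stratified on reported histology — but such assignments are
flagged. Combinations that were protocol-ineligible (metastatic, residual
or LC/A disease on ACNS0331; HDCSI on ACNS0331) raise a validation error
rather than being silently excluded, because they indicate corrupted
input, not an excludable patient. Unknown M-stage, R-status, CSI arm, or
carboplatin values lead to exclusion with the field named, since the
category cannot be determined without guessing.

## rCM risk classification

The nine groups and their precedence are encoded as an ordered rule table
over fully observed feature vectors (VHR rules first in SHH and G3/G4:
subgroup-3 or MYC-amplified disease is very-high-risk regardless of
otherwise favorable features). Unknown features are resolved by
enumeration: the classifier evaluates the rules under every resolution of
the unknowns and returns a tier only when all resolutions agree; otherwise
the patient is unclassifiable and the decisive (blocking) features are
named. This maximizes usable assignments while never guessing. The rule
table is data, so comparator schemes can be plugged in, but only the rCM
rules ship.

Two documented assumptions: the WNT high-risk criterion (M+) and its HDCSI
allocation are modelling choices carried as notes on every WNT assignment;
and isolated LC/A histology does not modify G3/G4 tiers (it was not
evaluable as a G3/G4 risk factor in the source cohorts). The observed
worse outcome of carboplatin in G3/G4 subgroup 5 is surfaced as a report
note but deliberately does not alter the allocation.

The population model is a set of (label, fraction, survival) strata whose
fractions must sum to 1; expected population survival is the weighted sum.
The packaged reference deployment is LDCSI 40 %/0.90, SDCSI 25 %/0.80,
HDCSI 20 %/0.60, HDCSI+carboplatin 10 %/0.60, novel therapy 5 %/0.40,
which evaluates to 0.76.

## Survival statistics

All estimators are implemented from first principles; lifelines and scipy
appear only as independent cross-check oracles in the tests.

* **Kaplan–Meier**: product-limit estimate with Greenwood variance
  S(t)² Σ dᵢ/(nᵢ(nᵢ−dᵢ)); censored subjects at an event time remain at
  risk for that event time (events precede censorings at ties). Curves
  are right-continuous step functions.
* **Log-rank**: O−E over pooled event times with hypergeometric variance;
  k-sample via the (k−1)-dimensional quadratic form with a pseudo-inverse
  for degenerate variance matrices; χ² on k−1 df.
* **Cox PH**: Efron tie correction — month-resolution trial data are
  heavily tied and Efron is less biased than Breslow — maximized by
  Newton–Raphson with step-halving; covariates are centered for
  stability; convergence when the relative log-partial-likelihood change
  falls below 1e−9, cap 50 iterations. Monotone likelihood (separation)
  is detected from diverging coefficients (‖β‖∞ > 10) and flagged rather
  than silently returned. The score test at β = 0 is reported; on
  tie-free two-group data it equals the log-rank χ² exactly, which the
  tests assert.
* **Concordance**: Harrell's c over usable pairs (the member with the
  shorter observed time had an event; equal times are usable only for an
  event/censored pair; two tied events are not orderable); tied scores
  count ½; higher score must predict shorter survival.
* **Bootstrap comparison**: B ≥ 100 subject-level resamples with
  replacement, seeded; degenerate resamples (no events or no usable
  pairs) are skipped and counted; reports mean Δc and the 2.5/97.5
  percentile interval.
* **Fisher exact (2×2)**: two-sided by the probability-mass rule, summed
  in exact rational arithmetic so borderline ties in table probabilities
  are handled without floating-point heuristics.
* Tests are two-sided at α = 0.05 with no multiplicity adjustment,
  matching the reporting style of the analyses this package supports.

## Dose accounting

Regimens live in a packaged YAML config as phases × administrations
(drug, per-administration dose in mg/m², count per cycle, cycle count).
Accounting is per body surface area as prescribed: absolute mg caps (e.g.
vincristine 2.0 mg) and age adjustments depend on patient size and are out
of scope. The ACNS0332 carboplatin radiosensitizer phase is included by
default (it defines the HDCSI+carboplatin arm); the isotretinoin add-on,
which showed no survival benefit, is excluded by default — both are
load-time flags. CSI dose ranges and boost CTV margins are metadata only.
The transcribed regimens yield SJMB03 cisplatin 300 mg/m² vs 450 on the
COG trials (ratio 1.5), cyclophosphamide 16 vs 6 vs 12 g/m², and
vincristine 8 vs 45 vs 27 mg/m².

## Synthetic data

`generate_cohort` draws, per patient: molecular group at the published
cohort mix (WNT 131/898, SHH 151/898, G3 220/898, G4 396/898); subgroup
and feature flags at configurable per-group prevalences (defaults are
round values consistent with published oncoprints — they are
configuration, not claims); a trial/arm combination consistent with each
trial's eligibility; an rCM risk group assigned by the packaged
classifier; an exponential PFS time (Weibull shape exposed as config,
default 1) with rate set so that S(60) equals the risk group's target
5-year PFS; and independent uniform administrative censoring on 36–120
months. Default targets: WNT-LR 0.95, WNT-HR 0.85, SHH-LR 0.90, SHH-AR
0.80, SHH-VHR 0.25, G3/G4-LR 0.90, -AR 0.80, -HR 0.60, and -VHR 0.65 with
carboplatin vs 0.35 without — anchoring the generator to the qualitative
survival orderings the risk scheme encodes. OS is PFS plus an exponential
post-progression survival (mean 18 months), censored at the same
administrative time, so PFS ≤ OS by construction. Times are rounded to
0.1 months, which introduces realistic ties.

`generate_reference_roster` is deterministic: one record per patient with
the attribute combination qualifying it for each of the six cross-trial
categories at sizes 86/276/177/97/80/87, plus 95 excluded records split
24/24/24/23 over the four exclusion strata (M0 LC/A and M0R+ on each of
SJMB03/ACNS0332 — only the total of 95 is externally meaningful; the
split is arbitrary). Group labels fill the published totals exactly.

`generate_segment_profile` backgrounds each autosome with ~25 Mb segments
(noise N(0, sd), default sd 0.01) and inserts planted events as their own
segments carrying the exact log2 shift. Because every background segment
exceeds the 10 Mb focal cap, background noise cannot produce focal false
positives through the length rule, which makes planted-event
sensitivity/specificity checks deterministic.

What the generator does **not** emulate: correlations between molecular
features (flags are independent given the group), per-trial differences in
group composition (uniform by default, configurable), age–outcome
structure, non-proportional hazards, competing risks, and real
segmentation noise (probe-level wiggle, waviness, subclonality). Passing
tests therefore demonstrate that the estimators and rules behave correctly
under the stated statistical model, not that the package reproduces any
patient-level trial result — patient-level data are not redistributable,
which is precisely why the synthetic layer exists.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 898–4,000 patients, 2,000 patients
per risk group for hazard-recovery checks (tolerance 3 Greenwood standard
errors), 500 replicates for log-rank null calibration (tolerance 3
binomial standard errors around 0.05), and 150–300 bootstrap resamples —
sizes chosen so each check has clear statistical resolution while the full
suite runs in seconds. Ties in Kaplan–Meier risk sets follow the
events-before-censorings convention; the log-rank variance uses the
finite-population correction (nⱼ−dⱼ)/(nⱼ−1); Cox fits center covariates
and clip linear predictors at ±500 before exponentiation.

## Known limitations

* Group/subgroup labels are inputs; methylation classification and raw
  array preprocessing are out of scope, as are variant calling and any
  re-derivation of trial eligibility from source data.
* Comparator risk models are supported only through the pluggable rule
  interface; none ship.
* Time-dependent ROC/AUC analysis is not implemented; model performance
  comparison is covered by concordance plus bootstrap.
* The Cox implementation supports neither stratification nor frailty
  terms, and interval censoring is not modelled.
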