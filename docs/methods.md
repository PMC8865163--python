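# Methods

## The rating model

`tractnorm` rates one subject's tract-averaged diffusion metrics against
a normative control sample, tract by tract. The inputs are per-bundle
mean FA (dimensionless, in [0, 1]) and mean RD (mm²/s, > 0) over a
fixed 50-bundle inventory; producing those means from metric volumes
and bundle masks is supported (`extraction`) but upstream of the
statistics. The core inference is deliberately nonparametric: the
empirical p-value of a patient value is the fraction of controls lying
strictly beyond it in the pathological direction (below for FA, above
for RD). Its only assumption is exchangeability of the patient with the
controls under the null — not normality — so the p-values remain exact
for skewed control distributions; the accompanying z-score
(value − μ)/σ, with the n−1 sample SD, is descriptive only.

Consequences the implementation embraces rather than hides:

- p takes only values {0, 1/n, …, 1}. With n = 50 the smallest
  resolvable p is 1/50 = .02; p = 0 is printed as "< 0.0200" because
  the count/n estimator cannot certify smaller values (no smoothing is
  applied, matching the plain count definition).
- Significance is invariant under any strictly monotone transform
  applied to patient and controls alike (tested by property test).
- Calibration is exact and enumerable: rating each of n controls
  against the remaining n−1 flags exactly #{k : k/(n−1) < α} = 2 of 50
  per tract and metric at α = .025; a fresh null subject flags at
  2/(n+1) = 2/51 per metric (rank uniform over n+1 slots).

Two one-sided tests run per tract (FA reduction, RD elevation), hence
the per-metric threshold α = .05/2 = .025. A tract is *affected* when
**either** metric is significant. The per-metric significance flags are
retained on every finding, because group-level tables report FA-driven
and RD-driven involvement separately and the two sets need not
coincide; scoring "affected" as a strict AND would make separate
FA-only and RD-only tract lists unrepresentable.

## Group-level inference

For each (tract, metric), m is the number of patients in whom the tract
was evaluable and k the number individually significant. Under the null
that subject-level calls are chance at rate p₀ = .025, k is a draw from
X ~ Binomial(m, p₀); the group p-value is the upper tail P(X ≥ k),
thresholded at α_group = .01. Using "≥" makes the discrete test
conservative (type-I error never exceeds α_group); strict ">" is
available behind the `exceedance` flag. Both an exact closed-form tail
(default, via the standard survival-function implementation) and a
Monte-Carlo null (100,000 Binomial draws, seed mandatory, p floored at
1/iterations so it is never exactly 0) are provided; tests verify their
agreement at the 3σ Monte-Carlo bound.

One genuine ambiguity is the number of binomial trials. The observed
statistic is a count over *patients*, so the default null uses
trials = m ("patients") and null and statistic share a support. An
alternative reading sets trials to the number of evaluable *tracts*;
it is implemented as `null_trials="tracts"` for comparability but not
recommended, and the two can differ materially when group size and
tract count diverge.

A limitation worth naming: all patients of a group are rated against
the *same* finite control sample, so their flags are positively
correlated given that sample (conditionally, each flags at rate
q_t ~ Beta(2, 49) rather than exactly .025). The binomial null ignores
this overdispersion, which inflates the group false-flag rate above the
nominal per-tract tail probability (≈0.0013 at m = 20) to roughly 1%
in our synthetic experiments — still inside the ≤ 2% band we test, but
not negligible. A hierarchical null would remove this at the cost of
the method's simplicity.

## The 50-bundle registry

The bundle inventory follows the nomenclature of neural-network bundle
segmentation: 21 bilateral left/right families (arcuate, cingulum,
corticospinal, the three superior-longitudinal subdivisions, the
thalamo- and striato-cortical projection bundles, the cerebellar
peduncles, …), the seven corpus-callosum segments (rostrum, genu,
rostral body, anterior midbody, posterior midbody, isthmus, splenium)
and, completing the cerebellar-peduncle family, the commissural middle
cerebellar peduncle — 50 bundles total. The choice of the middle
cerebellar peduncle as the 50th entry is a documented convention of
this package (the inferior and superior peduncles are both in the
bilateral set, and their family is otherwise incomplete). Name lookup
normalises case, whitespace, typographic hyphens and the abbreviated
"post. midbody" segment, so typeset table spellings resolve. Custom
registries load from JSON.

Built-in phenotype signatures (bvFTD, nfvPPA, svPPA, ALSFTD-C9+,
ALSFTD-C9NEG) carry per-metric FA/RD tract lists and their union. The
ALSFTD-C9NEG list is a synthetic reconstruction from qualitative
descriptions (symmetric corticospinal, callosal, cerebellar-peduncle,
long-association, arcuate, uncinate and cingulum involvement) rather
than a printed table, and is flagged as such in its docstring.

## Age-matching verification

Each phenotype-by-sex patient group is compared to its same-sex control
group with a pooled-variance Student t-test on age (df = n₁ + n₂ − 2,
sign convention control − patient). The pooled test is chosen over
Welch deliberately: it reproduces the conventional df and handles the
n = 1 patient group (the pooled variance then reduces to the control
variance). Summary-statistics mode and raw-age mode agree exactly when
the raw data reproduce the summaries. Note that recomputing t from
summaries already rounded to two decimals can perturb the last printed
digit (the worked-example table reproduces to within one unit in the
last place).

## The synthetic generator

`simulate` emulates the statistical structure the analysis assumes, at
the study's scale: 50 controls per sex; per-tract control populations
FA ~ N(μ_t, σ_t) truncated to [0, 1] and RD ~ N(ν_t, τ_t) truncated to
(0, ∞), with (μ_t, σ_t) ~ U[0.30, 0.65] × U[0.02, 0.05] and
(ν_t, τ_t) ~ U[5·10⁻⁴, 9·10⁻⁴] × U[2·10⁻⁵, 6·10⁻⁵] mm²/s drawn once
per tract from the top-level seed (literature-plausible tract-averaged
ranges; the source study prints no per-tract values, so these are the
package's own convention); ages ~ N(59, 9.8) years truncated to
[35, 85]. Patients draw a control-like profile, then subtract δ·σ_t
from FA and add δ·τ_t to RD in their signature tracts (per-metric
lists; per-tract multipliers supported), with δ = 3 control-SDs as the
default pathological effect. The default study layout is 60 patients
(7/9/3/21/20 across the five phenotypes, published sex splits) plus
100 controls. Truncation uses rejection sampling; all draws descend
from `SeedSequence` spawns of the single seed, so cohorts are bitwise
reproducible.

Deliberate simplifications, and what they imply: tract values are
independent across tracts by default (an equicorrelation stress
parameter exists, documented as exploratory), there are no age or site
effects, and missingness is uniform at a configurable rate. Passing
tests therefore demonstrate the *procedure's* calibration, sensitivity
and laterality behaviour under its own assumptions — they do not
certify performance on real scanner data, where inter-tract
correlation, age trends and segmentation quality all intrude. Because
the inference is rank-based, the Gaussian family is immaterial to
calibration; the log-normal RD option exists to demonstrate exactly
that.

The laterality experiments use a strongly left-lateralised signature:
the left-hemisphere members of the nfvPPA union signature. The full
printed nfvPPA set contains nearly as many right- as left-hemisphere
tracts and is only weakly asymmetric, so it is unsuitable as a
laterality probe; restricting to its left members gives a signature
whose expected left-right asymmetry is unambiguous while keeping the
language-network anatomy.

## Numerical and formatting choices

- Sample SDs use the n−1 denominator throughout (normative samples
  estimate populations).
- Ties count as not exceeding (strict inequalities) in rank counts.
- Report lines sort by ascending p, then lexicographic tract name, for
  reproducible diffs; z prints at 2 decimals, p at 4.
- Metric tables are CSV/TSV (delimiter by extension), UTF-8, decimal
  point, exact header
  `subject_id,sex,age,role,phenotype,tract,fa_mean,rd_mean`; floats are
  written at full precision and re-read with round-trip parsing, so
  write → read is exact.
- RD is stored in mm²/s (SI-consistent with b-value units); display
  scaling is left to the caller.
- Probabilistic masks in binary averaging mode threshold at > 0.5; NaN
  voxels are excluded from means and counted in the provenance log;
  volumes and masks must share grid and affine (1e-4 tolerance) — no
  resampling is performed.
- A degenerate control sample (σ = 0 or fewer than 2 values) marks the
  (tract, metric) unusable — a "not evaluable" signal, never a silent
  z of ±∞.

## Problem sizes

The test suite and the acceptance script run everything at the study's
own scale — 50 controls per sex, 20-patient groups, 100,000 Monte-Carlo
draws — since the full pipeline takes seconds: signature recovery uses
20 independent replicates, subject-level calibration ≥ 3,000 simulated
tract-evaluations per metric spread over 8 independently generated
control worlds (decorrelating the shared-reference effect described
above), and laterality 100 replicates.

## Known limitations

- No age-bracketed or regression-based normative modelling: matching is
  sex-stratification with post-hoc age-matching verification only.
- The binomial group null ignores shared-reference overdispersion (see
  above) and applies no family-wise correction across the 50 tracts
  beyond the stringent α_group = .01.
- The smallest single-subject p is 1/50; severity ranking below that
  resolution relies on z-scores.
- The imaging front-end consumes segmentation outputs; it performs no
  registration, tensor fitting or bundle segmentation.
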