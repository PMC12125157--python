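# Methods

This note records the modelling conventions, parameter choices and
numerical decisions behind fishmet, and what the test suite does and
does not demonstrate.

## Harmonization model

A literature record is one reported mean concentration of one
metal(loid) in one species, carrying its basis (dry/wet), censoring
status (measured, or an LOD/LOQ/BDL bound), an optional moisture
percentage, and the number of fish pooled into the mean (`sample_n`).
Harmonization applies, in order:

1. **Censoring substitution** — a left-censored bound is replaced by
   half its value. This is the conventional substitution estimator for
   censored concentration data; it is biased (upward when the true
   value is far below the bound, downward when near it), and the
   synthetic-data recovery report quantifies that bias rather than
   hiding it.
2. **Basis conversion** — dry-weight values are multiplied by
   (100 − %moisture)/100. The 80% default moisture applies only when a
   dry-basis record lacks its own value.
3. **Weighted aggregation** — per species and metal, the weighted mean
   Σ(CᵢNᵢ)/ΣNᵢ. An empty pool yields an *absent* entry, never zero.

Species resolve against an explicit catalog (canonical name + aliases,
case-folded, whitespace-collapsed). Records naming an uncatalogued
species go to a rejects report and the run continues. A species
catalogued in two habitats yields one profile per (species, habitat)
stratum; since literature records do not carry the habitat of the
sampled population, such a species' records contribute to both its
profiles. Category descriptive statistics treat each species-level
weighted mean as one data point (unweighted across species): the
published per-category counts match species counts, not record counts,
which rules out record-level pooling. The standard deviation uses the
n−1 denominator and the median of an even count is the central
midpoint; both conventions are stated because data of this kind is
reported without them.

MPL screening is strict: a concentration exactly at the limit is
compliant (flag 0).

## Exposure and risk model

Default exposure parameters describe an adult Bangladeshi consumer:
EF = 365 d yr⁻¹, ED = 70 yr, FIR = 62.6 g d⁻¹, BW = 60 kg,
AT = 365 × ED = 25 550 d. With these defaults EF·ED/AT = 1 and the
chronic daily intake reduces to FIR·C/BW·10⁻³ (tested as an algebraic
identity). No age- or subpopulation-specific parameter sets are
provided; none are available for this population.

Oral reference doses (mg kg⁻¹ d⁻¹ scale): As 0.0003, Cd 0.001, Cr 1.5,
Cu 0.04, Hg 0.0003, Mn 0.14, Ni 0.02, Pb 0.0035, Zn 0.3. Reference
tables sometimes label these values with concentration-like units; the
numbers are the standard USEPA oral reference doses on the same numeric
scale as the CDI, and the hazard quotient is their plain ratio. We
follow the arithmetic, not the unit label, and flag the ambiguity here
rather than "converting".

**Carcinogenic risk has two published forms.** The standard USEPA form
is CR = CDI × SF; some assessments print an equation that additionally
divides by RfDo (equivalently THQ × SF). For nickel at the omnivorous
category mean the two differ fifty-fold (1.95 × 10⁻³ vs 9.8 × 10⁻²),
and only the standard form reproduces published maxima. The engine
therefore defaults to `cr_standard` and keeps `cr_as_printed` behind an
explicit call/flag for auditing published tables. Metals without a
slope factor (Cu, Hg, Mn, Zn) have an *undefined* risk — cumulative CR
sums skip them; they are never coerced to zero.

The safe consumption limit inverts THQ = 1:
FIR = BW·RfDo·AT/(EF·ED·C)·10³ g d⁻¹ per metal; the species limit is
the minimum and the limiting metal the argmin, with ties broken by the
fixed alphabetical metal ordering so output is reproducible. A zero
concentration returns +inf (never binding). Category-level safe limits
are unweighted means of species limits, consistent with the
species-as-data-point convention above.

Known inconsistencies in the published record we deliberately do not
reproduce: the saltwater mercury hazard quotient (and hence the
saltwater cumulative hazard index) printed in the source literature is
incompatible with its own mean concentration table, and published
cumulative carcinogenic-risk magnitudes match neither CR variant. These
quantities are excluded from the reproduction surface; everything else
reproduces to within the rounding of the printed inputs (~1%).

## Ordination

Rows are species profiles (the natural unit after harmonization);
columns the nine metals. Profiles missing any metal are listwise
deleted with a logged count. The transform is natural-log log(x+1)
followed by per-column centering and unit-variance scaling (ddof = 1);
the log base is immaterial because standardization absorbs it. PCA is
an eigendecomposition of the covariance of the transformed matrix
(which is the correlation matrix of the logged data). Components are
ordered by decreasing eigenvalue; each eigenvector's sign is pinned so
its largest-magnitude entry is positive, since eigen-signs are
otherwise arbitrary and would break regression tests. Constant columns
are zeroed with a warning. Metals with |loading| strictly greater than
0.7 are labelled the component's defining cluster.

## Predictive model and attribution

Features per species: habitat and feeding codes (small integers, the
bijective dictionary serialized beside the dataset), nine
concentrations (absent metal → 0, i.e. no measured burden) and nine MPL
exceedance flags. Target: the species' overall safe limit (g d⁻¹). The
90/10 train/test split is a seeded permutation.

The linear model is ordinary least squares on the intercept-augmented
design; a rank-deficient design (typically a flag column that is
constant across the data) falls back to a logged, tiny ridge penalty.
The network is a minimal fully-connected regressor — default one hidden
layer of 16 tanh units, squared-error loss — trained by full-batch
gradient descent with the update
ω ← ω − η(α·∂R/∂ω + ∂Loss/∂ω), R = ½‖ω‖², biases unpenalized. The
architecture is a configurable default, not a claim about any published
network (whose architecture is unstated). Training is deterministic
given the config seed; divergence to non-finite loss raises an error
naming the learning rate. Inside the pipeline the network trains on
z-scored features and target (one learning rate cannot serve raw
columns spanning five orders of magnitude) and predicts in raw units.

Shapley attribution is exact: all 2ᵖ coalitions are enumerated (gated
at 15 features), with absent features filled from the baseline row —
the feature-wise training mean by default, a documented choice since no
canonical background distribution exists. The implementation satisfies
the efficiency, dummy and symmetry axioms to 10⁻⁸ and is cross-checked
against the permutation-average formulation in the tests. In the
pipeline, attributions are computed per held-out row over the nine
metal concentrations (other features clamped to the row's values), and
drivers are ranked by mean |φ| with ties broken by metal order. The
model's target variable is the continuous safe limit; exceedance flags
can serve as a secondary binary target through the same evaluate
interface (fraction correct at a 0.5 threshold).

## Synthetic data generator

The generator emulates a literature extraction sheet. Per habitat
stratum, species latent mean concentrations are drawn from a lognormal
moment-matched (μ = ln(m²/√(v+m²)), σ² = ln(1+v/m²)) to the published
category mean and standard deviation — lognormal because tissue
concentrations are strictly positive and right-skewed, consistent with
the published mean ≫ median pattern. Records scatter around the latent
mean with a within-species CV of 0.3 (default; a moderate analytical +
temporal variability for repeated studies of one species). Defaults:
3 records per species, per-record sample sizes uniform on 3–30, 20% of
records reported dry-basis at 80% moisture (recorded, so conversion is
exact), censoring off unless configured; censored records report the
per-metal LOD (default one fifth of the stratum mean) as an LOD/LOQ/BDL
bound. Feeding classes are assigned round-robin within each habitat
stratum so both classification axes are populated.

It does **not** emulate inter-study methodological bias, between-metal
correlation within a species, or reporting heterogeneity beyond the
basis/censoring axes — so passing recovery tests demonstrate that the
pipeline arithmetic is unbiased under the stated sampling model, not
that real literature compilations are free of systematic error.

The recovery report compares, per stratum and metal, the recovered mean
of species weighted means with the mean of the generating latent means,
using the paired standard error of the per-species differences; |z| > 3
raises a `biased` flag. The same report carries per-species safe-limit
recovery. Under 50% censoring at LOD = mean/5 the substitution
estimator collapses half the records to mean/10, and the report flags
the strong downward bias — by design, visibly.

## Problem sizes and tolerances

Property tests run the safe-limit round trip at 10⁴ random
(metal, concentration) pairs (tolerance 10⁻¹²); oracle equivalence
checks (weighted mean vs integer expansion, PCA vs an independent
eigendecomposition, exact Shapley vs the 6!-permutation average, OLS vs
normal equations) hold to 10⁻⁸. Parameter recovery uses one stratum of
200 species × 50 records (10⁴ records) at the saltwater-arsenic
calibration (mean 0.50, sd 0.87 µg g⁻¹), asserting recovery within
three Monte-Carlo standard errors. These sizes make the full suite run
in seconds while keeping the Monte-Carlo bands tight enough to detect
percent-level arithmetic errors.

## Known limitations

- Half-bound substitution is a crude censoring estimator; maximum
  likelihood or Kaplan–Meier estimators for left-censored data would be
  principled extensions.
- The dual-habitat convention duplicates records across a species'
  profiles; with habitat-resolved records a finer assignment would be
  possible.
- Exposure is deterministic; no Monte-Carlo percentiles on parameters.
- Exact Shapley is exponential in features; above 15 features a
  sampling approximation would be needed (out of scope).
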