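# Methods

## Duplex relative quantification

Each well co-amplifies one RCCX target (C4A, C4B, CYP21A1P, CYP21A2,
HERV-K(C4) deletion or insertion allele, or the segment breakpoint) with
the single-copy *RPPH1* reference gene.  Under equal amplification
efficiencies the quantification cycles satisfy
`ΔCq = Cq_target − Cq_reference = 1 − log2(GCN)`: the reference dosage
of 2 gives ΔCq = 0 and each halving of target copies costs one cycle.
The gap between consecutive integers, `log2((n+1)/n)`, shrinks from
1 cycle (1→2 copies) to 0.322 cycles (4→5), which is the fundamental
resolution limit this package quantifies.

Per-well measured copy numbers are computed from the well's own
target/reference Cq pair (never from channel-averaged Cqs); the sample
value is the mean of per-well values, with SD (n−1), CV% and a
normal-theory 95% CI.  Dropout wells (no target amplification) are
measured as 0 copies and excluded from the dispersion statistics; an
all-dropout sample is reported as 0 with dispersion flagged undefined.

## Offset calibration

Quantification-threshold differences between an assay's two channels
shift ΔCq by a constant.  Rather than normalizing to designated
reference samples (the ΔΔCq convention), the shift is absorbed into a
per-assay offset tuned so the cohort mean relative error is exactly
zero: since applying offset `o` multiplies every measured value by
`2^o`, the closed form is `o = −log2(mean_i(mGCN_i / n_i))`, samples
with `n_i = 0` excluded.  When integer labels are unavailable, an
iterative round → tune → re-round scheme (at most 10 rounds, stopped on
a stable assignment) bootstraps the labels; it converges in one or two
rounds at the noise levels where calling is feasible at all.

## Ambiguity, misclassification and the normal error model

The calling rule treats a measured value within ±0.3 of an integer as
unambiguous; the complementary boundary 0.7 = 1 − 0.3 marks the
catchment of the neighbouring integer.  The boundary is inclusive
(|m − n| = 0.3 counts as unambiguous), implemented with a 1e-12
tolerance against binary-representation artefacts, and the halfwidth is
configurable per assay.

Modeling the per-sample average relative error as `X ~ N(μ, σ²)` and
the measured value at true count `n` as `n(1 + X)` maps the windows
onto the relative-error axis divided by `n`:
`ambiguity(n) = P(0.3/n < |X| < 0.7/n)` and
`misclassification(n) = P(|X| ≥ 0.7/n)`, both closed forms in the
normal CDF.  Unambiguous + ambiguous + misclassified = 100% exactly,
misclassification is non-decreasing in `n`, and all rates depend on
|μ| only (the windows are symmetric).  Mass beyond `(n ± 1.3)/n` (the
far side of the *next* integer's window) is counted as misclassified
rather than re-entering an ambiguity band; at the σ ≤ 0.2 relevant
here that mass is below 1e-4 and the simplification is immaterial, as
the Monte-Carlo agreement tests confirm.

The inverse fit recovers `(|μ|, σ)` from two ambiguity rates at
distinct copy numbers by a deterministic coarse grid of starts refined
with bounded trust-region least squares (|μ| ∈ [0, 0.5],
σ ∈ (1e-6, 0.5]); the solution must reproduce the inputs to 1e-10 in
probability units or the fit fails loudly.  Scanning the bounded domain
shows the 2×2 system has a single solution, so the fit is not
initialization-sensitive.  Fitted to a published column's ambiguity at
2 and 3 copies, the model reproduces that column's other cells closely
but not perfectly — in our computation the C4A column's ambiguity at 4
copies comes out near 32.6% against a printed 35.00%, while the other
cells agree to ≤ 0.07 percentage points; the published table appears
not to be exactly self-consistent under this (or any examined) normal
geometry, and the package reports the computed value rather than the
printed one.  Tables render cells below 0.005% with a sub-threshold
symbol (`<0.01%` by default, switchable to the inverted `>0.01%` glyph
some published tables use for the same cells).

## Standard-curve QC

Calibration curves are ordinary least squares of Cq on log10 template
copies (≥ 3 distinct concentrations).  Template copies come from mass
via `copies = m / (2 · 3.1e9 bp · 650 g mol⁻¹ bp⁻¹ / N_A) ·
copies_per_diploid_genome` (≈ 374 diploid genomes in 2.5 ng);
efficiency is `10^(−1/slope) − 1`, so the perfect-doubling slope
−3.3219 gives 1.0.  Non-negative slopes are returned flagged degenerate
rather than raised, so QC reports can still tabulate a failed assay.

The Hubaux–Vos detection limit assumes a response linear in
concentration, so Cq is linearized as `y = 2^(−Cq)` and the curve
re-fit as y on copies.  The decision limit is the upper (1 − α)
prediction bound at zero concentration; the LOD is the concentration
whose lower (1 − β) prediction bound first exceeds it (Brent root
search; α = β = 0.05 by default).  A Monte-Carlo false-positive /
false-negative search over refitted calibrations serves as the test
oracle.  Because the residual scale is estimated on the linearized
response across the whole mass range, LODs from calibrations measured
far above the limit are overestimates — a known property of the
construction, visible in the examples.

Precision is the degrees-of-freedom-weighted pooled CV,
`sqrt(Σ (n_g − 1) CV_g² / Σ (n_g − 1)) · 100`, for repeatability
(within run) and reproducibility (across runs) scopes; groups with
non-positive means are excluded with a warning.  Normalization
efficiency is the NRMSE of observed target Cqs against
`Cq_ref + offset + 1 − log2(n)`, normalized by the mean observed target
Cq (the normalizer is a documented choice; the numerator is invariant
to shifts common to both channels).

## Integer calling

The caller is a two-stage Gaussian LDA written from scratch (class
means, pooled within-class covariance with N−K denominator, linear
discriminants, softmax posteriors, leave-one-out loop) — the estimation
procedure is the package's core, so no library classifier stands behind
it; scikit-learn's LDA appears only as an independent cross-check in
the test suite.  The pooled covariance is ridge-stabilized by
`regularization · trace/d` on the diagonal (default 1e-6) because
reference sets of a few dozen samples give near-singular covariances.
Priors default to empirical class frequencies (configurable to
uniform).

Stage 1 classifies the 4-vector of total estimates (C4A+C4B,
CYP21A1P+CYP21A2, HERV_del+HERV_ins, BP+2) into an integer total `T`.
Stage 2 resolves each paralogous pair on (pair A, pair B, breakpoint)
features over reference classes summing to `T`; a pair with one side
unambiguously zero is assigned `(T, 0)` without a discriminant, a total
with a single admissible reference split inherits that split, and a
total with no reference sample falls back to constrained rounding with
the call flagged ambiguous.  Every call therefore satisfies the
four-way constraint by construction, and the `IntegerGcnCall`
constructor re-asserts it.  A call is flagged ambiguous when any stage
posterior falls below 0.95 (configurable; published practice flags via
"probabilities and cross-validation" without a stated cutoff) or when
stage-1 leave-one-out cross-validation disagrees; singleton classes are
not cross-validatable and are reported as such rather than failed.
The cohort is its own reference set by default, matching how a
validation cohort is used in practice; an external labeled reference
table is accepted and recommended when rare high copy numbers are
under-represented.  Replicates are combined to per-sample means before
LDA.

The consistency screen computes an expected total as the equal-weight
mean of the four totals and splits it across each pair in proportion to
the measured values; a locus deviating from its expectation by more
than 0.4 copies is flagged.  An equal-weight mean is used instead of a
fitted multiple regression: the regression variant is under-specified
(weights and granularity unstated in the source material), while equal
weighting is reproducible and respects the same constraints.

## Synthetic data

The generator emulates the data-generating process the analysis
assumes.  Genotypes are two haplotypes drawn from a configurable pool;
the default pool is monomodular/bimodular/trimodular at 0.55/0.40/0.05
with CYP21A2 on exactly one segment per haplotype — a realistic
European-style skew producing diploid totals 2–6 (population haplotype
tables are not part of the source material, so the defaults are a
documented choice, configurable but not calibrated).  Cq wells follow
the ΔCq relationship with: a per-sample matrix shift (default SD 0.5
cycles, mirroring the large between-sample reference-Cq spread of real
genomic DNA) applied to both channels so it cancels in ΔCq; a small
channel-asymmetric per-sample, per-assay component (SD 0.02 cycles)
that does not cancel and drives sample-level accuracy differences;
between-run shifts (SD 0.05); independent well noise per channel (SD
0.05, so within-sample ΔCq has SD √2·0.05); and, for "bad quality"
samples, a +0.05-cycle target-channel bias plus 0.1 cycles of extra
well noise emulating degradation-sensitive assays.  Zero-copy target
loci emit dropout records; the reference gene never drops out.  The
default cohort is 46 samples (good/population/bad ≈ 17/19/10) measured
as 3 wells × 3 runs, and dilution series span 2.5–80 ng.  All
randomness flows from one seeded generator in documented draw order.

What the generator does *not* emulate: PCR-efficiency differences
between channels (ΔCq is generated directly from the model, so
calibration slopes are perfect up to noise), inhibitor-driven
non-linearity at concentration extremes, probe cross-reactivity, and
plate-position effects.  Passing tests therefore demonstrate
correctness of the computational pipeline under its stated model, not
robustness of any wet-lab assay.

## Problem sizes and numerical choices

Property tests use 10⁴ genotype draws, 10⁶-draw Monte-Carlo rate
checks over 50 random error models, 1000 random LDA instances against
a log-density oracle, and a 200-sample end-to-end cohort at the default
noise levels — sizes chosen so the full suite runs in about a minute
while keeping binomial standard errors far below the asserted margins.
Ties in `classify` resolve to the first class in sorted label order
(posteriors are compared by argmax); `classify_ambiguity` rounds
half-integers to the nearest even integer before the window test,
consistent with its shift-invariance property.

## Known limitations

* The supplementary raw-data replication (pooled reproducibility CV and
  the 150/153 cross-validation pass rate on the original 46-sample
  cohort) requires the study's raw workbook, which is not
  redistributable here; the loader and pipeline support it, and the
  corresponding test states what is missing.
* The breakpoint assay has no counterpart paralog; its integer is
  derived as `T − 2` rather than via a stage-2 discriminant.
* Rates in the error model are per-sample (average-RE) rates; per-well
  rates would need the within-sample replicate correlation structure.
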