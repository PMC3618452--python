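# Methods

## Scope and data model

The package analyses two-group 1D ¹H-NMR profiles. A `Spectrum` is one
sample's (ppm, intensity) pair; a `BucketTable` is the samples × buckets
matrix after spectral reduction, carrying bin-centre ppm labels
(descending, NMR plotting convention) and a normalization flag. All
tabular inputs and outputs are plain delimited text.

## Bucketing and normalization

Buckets of width 0.01 ppm tile the analysed range `[lo, hi)` as
half-open intervals `[b, b + w)` anchored at the lower bound. The bucket
value is the plain sum of point intensities falling in the interval — a
rectangular integral up to the constant grid-spacing factor, which the
subsequent constant-sum normalization cancels. A bucket that intersects
any exclusion window is dropped whole; partial-coverage proration is
deliberately avoided because it would make bucket values depend on an
arbitrary area convention. Default exclusions: 0–0.6 ppm (no signal),
1.1–1.23 and 3.62–3.7 ppm (ethanol contamination), 4.54–5.0 ppm
(residual water), 8.3–20 ppm (no signal). Interval comparisons use a
1e-9 ppm guard so that a bucket sharing only a boundary with an
exclusion is not dropped by floating-point accident.

Constant-sum normalization divides each row by its own total (row sums
become exactly 1; the constant is 1 because only relative abundances are
meaningful afterwards). A non-positive row total is an error naming the
sample. Normalization is idempotent and scale-invariant. The retained
bucket count is a function of the configured range and exclusions —
with the defaults, 703 buckets — and is never assumed constant.

## Univariate statistics

Each bucket is tested with the two-sided pooled-variance (Student's)
two-sample t-test, df = n₁ + n₂ − 2, on normalized, unscaled values
(unit-variance scaling is a multivariate-model device and would distort
fold changes). Degenerate buckets with zero pooled variance are defined
explicitly: equal means give t = 0, p = 1; unequal means give p = 0 and
a `degenerate` flag. Fold change is treated mean over control mean.

q-values follow the Storey–Tibshirani construction. The null proportion
estimate π̂₀(λ) = #{pᵢ > λ} / (m(1 − λ)) is either taken at a fixed λ
(exact, used by oracle tests) or smoothed: a cubic smoothing spline is
fitted to π̂₀ over λ ∈ {0.05, 0.10, …, 0.95} and evaluated at the
largest λ, then clamped to (0, 1] (lower clamp 1e-8 so that q-values
remain defined when every p-value is tiny). With fewer p-values than
grid points the smoother falls back to the fixed estimate at λ = 0.5.
The step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ π̂₀ m p₍ⱼ₎ / j (capped at 1) makes
q-values monotone in p; with π̂₀ = 1 they coincide with
Benjamini–Hochberg adjusted p-values, which the tests assert to 1e-12
against an independent implementation.

## OPLS-DA

Unit-variance scaling subtracts each column mean and divides by the
(n − 1)-denominator standard deviation; zero-variance columns cannot be
scaled and are dropped with their indices recorded, and prediction is
invariant to the values such columns take in new data.

The discriminant model is single-response O-PLS. The class response is
coded 1 = treated, 2 = control and centered. Per orthogonal component:
w ∝ Xᵀy normalized, t = Xw, p = Xᵀt/(tᵀt), w_o ∝ p − (wᵀp)w normalized,
t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o), and X is deflated by t_o p_oᵀ. The
predictive component is then fitted on the filtered X. Orthogonal scores
have exactly zero sample covariance with the centered response by
construction (asserted numerically at 1e-8). Requesting more orthogonal
components than the data's rank supports raises an error.

Quality summaries: R²X is the fraction of the scaled X sum of squares
captured by the predictive plus orthogonal components; R²Y the fraction
of centered-response sum of squares explained; Q² = 1 − PRESS/SSY under
k-fold cross-validation (default 7 folds, the chemometrics convention)
with fold membership assigned by seeded shuffle then round-robin, and a
full refit per fold — scaling learned on the training folds only, so no
information leaks from held-out samples. Q² ≤ R²Y always; on null
cohorts at the study geometry (23 samples × 703 buckets) the observed
maximum over 20 seeds is ≈ 0.03–0.09, comfortably below the 0.1 bound
asserted in tests. The null Q² distribution widens at smaller p/n
ratios, which is why the bound is evaluated at the pipeline's own
geometry.

A classical identity anchors correctness: for a single response, O-PLS
with 1 predictive + k orthogonal components predicts identically to
plain NIPALS PLS1 with k + 1 components. The tests verify this to 1e-8
(observed ~1e-15) against an independent NIPALS implementation.

VIP uses the standard PLS formula with per-component explained response
sums of squares as weights; orthogonal components explain none, so it
collapses to √p·|w| for the unit-norm predictive weight, giving the
exact identity ∑VIP² = p (asserted at 1e-9). The precise VIP variant of
the commercial software the workflow originated in is undocumented; the
standard formula is the defensible choice and is flagged as such.

Back-scaled coefficients multiply the predictive regression vector
(orthogonal filtering folded in) by each retained column's original
standard deviation, restoring spectral appearance. The colour value is
min-max-normalized VIP in [0, 1]; if all VIPs are equal the colour is
defined as 0.5 everywhere. Because the coding puts treated at 1 and
control at 2, a bucket elevated in the treated group has a negative
back-scaled coefficient.

## Hold-out validation

Per repeat, `test_per_class` (default 3) samples per class are drawn
seeded and without replacement within the repeat; the model — scaling
included — is refitted on the remainder and held-out samples are
classified as treated when the continuous prediction falls strictly
below the cutoff (default 1.5), control otherwise; a tie at exactly the
cutoff therefore goes to control. Four repeats are drawn independently
by default: with 11 controls, four disjoint test triples are impossible,
so disjoint partitioning (provided as an option) cannot have been the
original scheme for both groups. The report carries per-repeat correct
counts and the overall average percentage (e.g. 20/24 → 83.3%).

## Annotation and fold-change aggregation

Selection is strict: q < 0.2 OR VIP > 1.5. The shift library maps a
bucket to every metabolite whose half-open ppm window contains its
centre; multi-window hits are flagged ambiguous and contribute to every
matching metabolite — mirroring how overlapping resonances (acetate/GABA
near 1.9 ppm, choline/phosphorylcholine near 3.2 ppm) are reported in
practice rather than silently arbitrated. Unassigned buckets are listed
separately. Per metabolite, selected buckets are summed within each
sample and the fold change is the treated-group mean of sums over the
control-group mean; by linearity this equals the ratio of summed group
means, and both routes agree to 1e-12 in tests. Direction is up exactly
when FC > 1. An option aggregates over all library buckets instead of
selected ones for sensitivity analysis (pass the full bin-stat list to
`assign_bins`).

A property worth knowing: the VIP arm of the selection rule is not
FDR-controlled. Mean VIP² = 1 by construction, so a fixed cutoff always
admits a quantile of buckets — on a completely null cohort roughly 13%
of 703 buckets exceed 1.5. Only the q-value arm controls false
discoveries; on null data the metabolite table is accordingly populated
by weak, near-unit-fold-change VIP selections. This is a property of
the published rule, reproduced faithfully and demonstrated in the test
suite.

## Enrichment

Right-tailed hypergeometric tail P(X ≥ hits) with population = universe,
successes = pathway ∩ universe, draws = query ∩ universe. The universe
is an explicit required input: the original analysis ran against a
proprietary knowledge base whose background is unknowable, so every p
here is auditable instead. Query IDs outside the universe are dropped.
No adjustment is applied to the reported p (matching the original
reporting); a Benjamini–Hochberg column is emitted as an extra. IDs are
opaque strings, so mixed metabolite + protein queries need no namespace
translation. The bundled `example_pathways.gmt` / `example_universe.txt`
are synthetic illustrative stand-ins, not curated pathway content.

## Synthetic cohort generator

The generator emulates the study design: 12 treated vs 11 control
samples, ~18 brain metabolites with Lorentzian peaks between 0.6 and
8.3 ppm, multiplicative treatment effects applied to the treated group's
amplitudes, additive i.i.d. Gaussian noise per grid point, and an
optional (default off) smooth polynomial baseline. Peak positions come
from standard aqueous-solution reference shifts shipped as an editable
TSV, with the lactate CH₃ doublet centre at 1.325 ppm as the reference;
relative intensities are proportional to proton counts. The default
half-width is 0.005 ppm (typical tissue MAS linewidth on a 0.01-ppm
bucket scale); the grid is 0.0–10.0 ppm at 0.0005 ppm (20 points per
bucket). Default planted fold changes are the cortex metabolite-level
values of the emulated study (0.84–1.15, thirteen affected metabolites);
base amplitudes are free parameters set to plausible relative brain
abundances.

The default noise level (noise_sd = 15 per grid point) was chosen so
that a bucket holding the main peak of a unit-amplitude metabolite with
a 10% fold change shows a between-group difference of about three
bucket-level noise standard deviations: a unit-area Lorentzian
concentrates ≈ 50% of its area within ± one half-width, so the central
bucket sums to ≈ 0.5/0.0005 = 1000 amplitude units, a 10% effect moves
it by ≈ 100·(relative intensity), and the bucket noise sd is
15·√20 ≈ 67.

`snr_calibrated_config` constructs the cohort used for recovery
benchmarking: it solves each affected metabolite's amplitude so that its
strongest bucket's group difference equals a prescribed multiple
(default 3) of the bucket noise sd, computed deterministically from the
noise-free lineshapes. Under the default amplitudes instead, strong
metabolites reach bucket SNR ≈ 18 and their Lorentzian tails become
statistically detectable inside neighbouring metabolites' windows
(e.g. the N-acetylaspartate 2.01 ppm tail inside the glutamate
2.025–2.055 ppm window) — realistic resonance-overlap crosstalk that
inflates the apparent false-metabolite rate beyond what the selection
rule itself produces.

What the generator does **not** emulate: FID-domain effects (phase and
baseline error, water suppression, spinning sidebands), peak-position
jitter between samples (no alignment step is therefore needed or
provided), multiplets, J-coupling fine structure, and inter-metabolite
concentration correlations. Passing tests therefore demonstrate the
statistical machinery under the stated noise model, not robustness to
misalignment or baseline artefacts in real spectra. Noise can drive
near-empty buckets slightly negative; values are deliberately not
clipped, since truncation would bias the null t-test calibration.

## Determinism and problem sizes

A single seed governs simulation, cross-validation fold assignment and
hold-out draws; per-stage seeds are derived from it deterministically
and identical configurations produce byte-identical outputs. The
benchmark sizes used by the test suite and acceptance script — 200 null
cohorts for type-I calibration (≈ 140,600 pooled tests), hold-out
classification on 25 of them (600 predictions), 20 null cohorts for the
Q² bound, 50 SNR-calibrated cohorts for recovery, 20 random problems for
the PLS equivalence, 100 random spectra for bucketing conservation —
were chosen to give stable estimates (binomial SE ≈ 0.0006 on the
calibration fraction, ≈ 2% on null accuracy) at interactive runtimes.

## Known limitations

- Bucket boundaries are fixed, not peak-adaptive; a resonance straddling
  a boundary splits its intensity across two buckets.
- The shift library windows are a best-effort reference, explicitly
  user-editable; window placement materially affects metabolite-level
  aggregation in crowded regions.
- The smoother π̂₀ uses scipy's cubic smoothing spline, which is not
  numerically identical to the R `qvalue` package's `smooth.spline`
  (df = 3); agreement is behavioural (π̂₀ within 0.05 of truth on
  uniform p-values), not bit-exact.
- Only two-group designs and a single predictive component are
  supported; multi-class OPLS-DA, S-plots and permutation tests of Q²
  are out of scope.
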