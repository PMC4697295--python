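# Methods

## Problem and model

Serum fatty-acid panels are commonly reported on two scales: absolute
concentration (mmol/l, the "mass" scale) and percentage of total fatty
acids (the closed, compositional scale). Closure divides each subject's
fatty-acid vector by its own total, so percent-scale values carry
information about the *rest of the pool* as much as about the focal fatty
acid. `lipidcomp` quantifies how this changes Pearson correlations with
blood-lipid biomarkers, and predicts the percent-scale correlation from
concentration-scale moments alone.

The k-fatty-acid problem is always reduced to two components: the focal
concentration X₁ and the per-subject **sum** of all other fatty acids
X₂ (not their mean; the two printed pool means, 3.83 + 8.27 = 12.10 mmol/l,
are consistent with a total serum fatty-acid pool only under the sum
convention). With S = X₁+X₂, P = X₁/S, biomarker Y, moments
μᵢ, σᵢ, ρ = corr(X₁,X₂), ρᵢ = corr(Xᵢ,Y), σ_Y, and M = μ₁+μ₂, the
first-order Taylor expansion of P about (μ₁, μ₂),

    P ≈ μ₁/M + [μ₂(X₁−μ₁) − μ₁(X₂−μ₂)] / M²,

yields

    cov(Y,P) ≈ σ_Y (μ₂ρ₁σ₁ − μ₁ρ₂σ₂)/M²,
    var(P)   ≈ (μ₂²σ₁² + μ₁²σ₂² − 2μ₁μ₂ρσ₁σ₂)/M⁴,
    cov(S,P) ≈ (μ₂σ₁(σ₁+ρσ₂) − μ₁σ₂(σ₂+ρσ₁))/M²,   var(S) exact.

The predicted correlations are the ratios of these quantities; σ_Y cancels,
and every prediction is invariant under a common rescaling of
(μ₁, σ₁, μ₂, σ₂), i.e. unit-free. Two sign conditions follow because the
denominators are positive:

* corr(Y, P) < 0  ⇔  ρ₁σ₁μ₂ − ρ₂σ₂μ₁ < 0  ⇔  ρ₁·CV₁ < ρ₂·CV₂;
* corr(S, P) < 0  ⇔  σ₁μ₂(σ₁+ρσ₂) − σ₂μ₁(σ₂+ρσ₁) < 0
  ⇔  CV₁(σ₁+ρσ₂) < CV₂(σ₂+ρσ₁).

### Boundary geometry

Each condition is a line through the origin of the (x = CV₂, y = CV₁)
plane. For the biomarker condition the boundary is y = (ρ₂/ρ₁)x, with the
region below it negative when ρ₁ > 0. For the total-pool condition,
holding the sample sds fixed while the means sweep the CVs, the boundary
is y = x·(σ₂+ρσ₁)/(σ₁+ρσ₂) (at ρ = 0 this is y = (σ₂/σ₁)x). Classification
is implemented through the linear form coef_y·y − coef_x·x — algebraically
identical to the sign terms — so the boundary and the sign condition can
never disagree. Degenerate cases are explicit errors: ρ₁ = 0 (no boundary;
sign is that of −ρ₂ everywhere) and σ₁+ρσ₂ = 0 (vertical boundary).

## Statistics

* Pearson sample correlations throughout (scipy); zero-variance input is a
  hard error, never a silent 0/NaN. No regression modelling.
* Significance of non-zero correlations via the Fisher z-transformation:
  z = atanh(r), statistic z·√(n−3) referred to N(0,1), two-sided; requires
  n ≥ 4. p-values are kept strictly inside (0, 1] (floored at 1e-300 when
  the normal tail underflows; |r| = 1 is reported at the 1e-15 text floor
  with an explicit underflow flag). Text reports print p < 1e-15 as
  "<1e-15"; JSON keeps full precision. No multiple-testing correction is
  applied — the grid reports raw p-values and the reversal classifier
  filters at a user-chosen α (default 0.05).
* Sample sds use the n−1 denominator (standard clinical-cohort reporting;
  whether the motivating summaries used n or n−1 is not stated, and
  Pearson r is denominator-free so only μ/σ magnitudes could differ, by
  O(1/n) at n = 93).
* Missing data: complete-case deletion per (fatty acid, biomarker) cell; a
  missing value in *any* fatty-acid column removes the subject from that
  cell because the sum-of-others and the closure denominator are undefined.
  Effective n per cell is logged and used in the Fisher z-test.
* Comparisons against 2-decimal printed values round half away from zero.

## Units and closure conventions

The canonical internal concentration unit is mmol/l; µmol/l inputs are
divided by 1000 at load. Closure basis is 0–100 by default (configurable to
0–1); correlations are invariant to it. Closure is computed over exactly
the columns supplied — callers providing a partial panel are closing over
that panel, and written composition files record the basis in a comment
line.

## Synthetic cohorts

Raw subject-level data for the motivating cohorts are not available, so the
generator reproduces their *printed* moment structure. Default law:
joint multivariate normal over fatty acids and biomarkers with specified
means, sds and a correlation matrix validated symmetric, unit-diagonal and
PSD (eigenvalue tolerance 1e-8). Justification: the Taylor machinery
consumes only first and second moments, and at the printed CVs (≤ ~0.35)
the normal's negative tail is negligible. Negative draws are handled by
`negativity_policy`: `resample_row` (default; redraws offending rows,
preserving means and correlations to <1 % relative error when all CVs
≤ 0.35), `truncate_at_zero`, or `allow` (raw draws). A moment-matched
multivariate lognormal mode is provided for skewness-robustness checks.

What the generator deliberately does **not** emulate: the right-skew and
heteroscedasticity of real TAG distributions, measurement error of the
chromatography, correlated missingness, and any within-panel correlation
structure beyond second moments. Passing tests therefore demonstrate the
mathematics of closure and the delta method under a moment-matched law,
not distributional realism of any particular cohort.

Scenario specs (`demo_like_spec`):

* LA scenario — focal (3.83, 0.77), others-sum (8.27, 2.17), TAG
  correlations (0.60, 0.87): the reversal case.
* OA scenario — focal (2.39, 0.76), others-sum (9.70, 2.04), TAG
  correlations (0.90, 0.82): the concordant case.
* n = 93 subjects by default, matching the cohort the moments describe.
* The focal↔others correlation ρ is **not** a printed quantity. Default:
  the largest value keeping the joint 3×3 correlation matrix PSD minus a
  0.05 margin (LA: 0.866, OA: 0.938) — total serum fatty-acid pools co-vary
  strongly, so a high coupling is realistic — and it is an explicit
  parameter for sensitivity work. Because ρ is unknown, only the *sign* of
  observed percent-scale correlations is reproducible, not their printed
  magnitudes.
* TAG moments are likewise unprinted and irrelevant to every correlation;
  the specs use 1.5 (sd 0.5) mmol/l, plausible for an overweight
  postmenopausal cohort and keeping the CV at 0.33 so resampling stays in
  its documented <0.002 negative-mass regime.
* The 19-fatty-acid filler panel (`filler_panel_spec`) uses invented,
  physiologically plausible moments (synthetic — not any study's Table) and
  a seeded two-factor loading model for the joint correlation matrix, which
  guarantees PSD and gives every fatty acid a shared "pool" factor — the
  structural ingredient that produces reversals after closure.

Determinism: identical spec + seed give bit-identical cohorts (single
`numpy` Generator, eigendecomposition factorisation).

## Accuracy of the first-order approximation

The delta-method prediction is exact for the *linearised* fraction, so its
error against the true corr(Y, P) grows with the CVs. Monte-Carlo
characterisation at n = 10⁵ over random valid moment sets (means 1–10
mmol/l, |ρ·| ≤ 0.9):

* max(CV₁, CV₂) < 0.20 — |error| ≤ ~0.02 (median ~0.005);
* CV 0.20–0.25 — 95th percentile ~0.04;
* CV 0.25–0.40 — median ~0.02, but a heavy tail: ~10–20 % of moment sets
  exceed 0.05 and the worst observed error is ~0.15.

The printed worked examples (CVs 0.20–0.32) sit comfortably in the
well-behaved region, but users should treat predictions with any CV above
~0.3 as directional rather than quantitative. Predicted values are clamped
to [−1, 1] with a `clamped` flag when the approximation leaves the valid
range; a first-order var(P) ≤ 0 (possible only at |ρ| = 1) is a
degenerate-composition error. No second-order correction and no confidence
intervals are provided — predictions are point values.

A related numerical caution drove one design choice: when simulating at
large CVs with `allow`, the total S can cross zero and P = X₁/S has no
finite moments, making empirical Pearson correlations outlier-dominated.
Monte-Carlo validation therefore uses `resample_row`, which keeps
concentrations physical and the denominator bounded away from zero.

## Pipeline conventions

* TC:HDL is computed per subject (requires HDL > 0) and treated as an
  ordinary biomarker column.
* Each fatty acid's prediction uses its own two-component reduction
  independently; no joint covariance propagation across fatty acids.
* Constant columns yield NA cells with a logged warning, not a crash.
* Reversal and prediction-agreement flags are recomputed from the stored r
  values on every access, so they cannot drift out of sync.
* `classify_reversals` returns sign-flipped cells with both p ≤ α, sorted
  by |r_mass| descending, ties broken lexicographically.
* Grid TSV renders floats at 6 significant figures (round-trippable via
  `read_grid`); JSON keeps full precision. Exit codes: 0 success, 2
  validation error.

## Problem sizes used in validation

Monte-Carlo oracles use n = 10⁵ subjects; reversal-reproduction sweeps use
500 replicates at the cohort-realistic n = 93; sign-identity sweeps use
1000 random moment sets; the end-to-end panel grid uses 19 fatty acids ×
5 biomarkers at n = 2000. The full suite and the acceptance script each
run in a few minutes on a single core.

## Known limitations

* Two-component reduction only; no full-k compositional covariance model
  and no log-ratio (Aitchison) machinery — raw percentages are the object
  of study.
* The moment generator cannot reproduce observed percent-scale correlation
  magnitudes of the motivating cohorts (the required within-panel
  correlations are unpublished); sign patterns are the reproducible target.
* Percent-scale p-values use the same Fisher-z machinery as mass-scale
  ones; closure-induced dependence between components is not corrected for.
* No per-fatty-acid molar-mass conversion between mg/dl and mmol/l is
  implemented; Pearson correlations are unit-invariant so the grid is
  agnostic to the input unit.
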