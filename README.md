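# lipidcomp

Fatty-acid association studies almost universally report each serum fatty
acid as a *percentage of total fatty acids*. That convenient normalisation is
a compositional closure: it divides every concentration by the per-subject
total, and in doing so it can change — and even **reverse the direction
of** — Pearson correlations between fatty acids and blood-lipid biomarkers
(TAG, total cholesterol, LDL, HDL, TC:HDL). A fatty acid whose serum
concentration rises with TAG can simultaneously *fall* with TAG as a share
of the pool, because the rest of the pool rises faster.

`lipidcomp` is a small Python library + CLI for epidemiologists and
lipidomics analysts who want to quantify, predict and report this effect:

* compute mass-scale and percent-scale correlation grids with Fisher-z
  p-values from plain per-subject CSVs;
* **predict** the percent-scale correlation from concentration-scale
  summary moments alone, via a first-order Taylor (delta-method)
  approximation of the ratio X₁/(X₁+X₂);
* evaluate the two closed-form **sign conditions** that decide the
  direction of percent-scale correlations, and export the corresponding
  CV-plane boundary curves;
* simulate moment-matched synthetic cohorts (multivariate normal or
  moment-matched lognormal) for validation and power-style experiments.

## The model

Let X₁ be the concentration of a focal fatty acid, X₂ the summed
concentration of all other fatty acids, S = X₁+X₂ the total pool,
P = X₁/S the focal fraction, and Y a biomarker. With
μᵢ = E Xᵢ, σᵢ = sd Xᵢ, ρ = corr(X₁,X₂), ρᵢ = corr(Xᵢ,Y) and M = μ₁+μ₂,
linearising P about the mean vector gives

    cov(Y, P) ≈ σ_Y (μ₂ρ₁σ₁ − μ₁ρ₂σ₂) / M²
    var(P)    ≈ (μ₂²σ₁² + μ₁²σ₂² − 2μ₁μ₂ρσ₁σ₂) / M⁴

so corr(Y, P) is **negative iff ρ₁σ₁μ₂ − ρ₂σ₂μ₁ < 0**, i.e. iff
ρ₁·CV₁ < ρ₂·CV₂ with CVᵢ = σᵢ/μᵢ. Analogously, corr(S, P) is negative iff
σ₁μ₂(σ₁+ρσ₂) − σ₂μ₁(σ₂+ρσ₁) < 0. Both criteria are unit-free straight-line
boundaries through the origin of the (CV₂, CV₁) plane.

## Worked example

The classic reversal case is linoleic acid (LA, C18:2n-6) against TAG in a
93-subject cohort: μ₁ = 3.83, σ₁ = 0.77 mmol/l for LA; μ₂ = 8.27, σ₂ = 2.17
mmol/l for the sum of the other fatty acids; ρ₁ = 0.60, ρ₂ = 0.87.

```python
from lipidcomp import SummaryMoments, sign_condition_biomarker

la = SummaryMoments(mu1=3.83, sigma1=0.77, mu2=8.27, sigma2=2.17,
                    rho1=0.60, rho2=0.87)
cond = sign_condition_biomarker(la)
print(f"CV1={la.cv1:.2f} CV2={la.cv2:.2f}")
print(f"rho1*CV1={cond.left_term:.2f} < rho2*CV2={cond.right_term:.2f}"
      f" -> {cond.predicted_sign}")
```

prints

```
CV1=0.20 CV2=0.26
rho1*CV1=0.12 < rho2*CV2=0.23 -> negative
```

so although LA concentration correlates **positively** with TAG
(ρ₁ = 0.60), its percentage of total is predicted to correlate
**negatively** — 0.12 < 0.23 flips the sign. For oleic acid
(μ₁ = 2.39, σ₁ = 0.76, μ₂ = 9.70, σ₂ = 2.04, ρ₁ = 0.90, ρ₂ = 0.82) the same
arithmetic gives 0.29 > 0.17 and no reversal.

The same check end-to-end from the shell, on a simulated cohort:

```sh
cat > spec.yaml <<EOF
scenario: LA
n_subjects: 93
seed: 7
EOF
lipidcomp simulate --spec spec.yaml --out cohort/
lipidcomp analyze --concentrations cohort/concentrations.csv \
                  --lipids cohort/biomarkers.csv --out report/
```

`report/association_grid.tsv` then contains one row per (fatty acid,
biomarker) cell with `r_mass_observed`, `r_percent_observed`,
`r_percent_predicted`, Fisher-z p-values, the predicted sign and a
reversal flag; `report/reversals.tsv` lists the significant sign flips.
`lipidcomp predict` evaluates the moments-only prediction directly and
`lipidcomp boundaries` exports CV-plane boundary curves for plotting.

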