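# Methods

## Pharmacokinetic model and closed-form solutions

Both implemented models are one-compartment with zero-order infusion
input and first-order elimination. For an infusion of rate
`R0 = amount/duration` starting at `s` with elimination rate `k = CL/V`,
the concentration is `R0/CL·(1 − e^(−k·(t−s)))` during the infusion and
decays exponentially from the end-of-infusion value afterwards; multiple
doses superpose linearly. AUC over any window is the exact integral of
this piecewise curve (no quadrature), and the cumulative AUC of a course
reduces to total dose / CL. Internally everything is mg, L, h and mg/L;
ng/mL is accepted and emitted at the I/O boundary (÷/× 1000) because
busulfan assays report ng/mL. This single canonical unit system is a
deliberate guard against silent factor-1000 errors: the parametric
model's additive error is quoted in ng/mL while the nonparametric
residual rule is quoted in mg/L.

AUC over the first six hours of therapy is computed as the true integral
of the fitted curve over [0, 6] h, not as the per-interval dose/CL
shortcut; with q6h dosing the two differ only by the tail that
accumulates into later intervals, but the integral is what "AUC after the
first dose" denotes. The dose/CL quantity is available separately as the
cumulative AUC divided by the number of doses.

Infusions shorter than 1e-6 h are rejected rather than approximated by a
bolus; the clinical setting is 2-h infusions and a bolus limit would
silently change the model.

## Covariate models

*Parametric:* `CL = 2.18·(BW/9)^θ` with θ = 1.25 below 9 kg and 0.76 at
or above, continuous at the breakpoint; `V = BW^0.86`. Between-subject
variability is log-normal with `ω² = ln(1 + CV²)` (CV 23% for CL, 22% for
V) — the standard convention for CV-quoted variability; it keeps
parameters positive and reproduces the quoted CV exactly.

*Nonparametric:* `Ke = KeS·size^−0.25`, `V = VS·size` with
`size = min(BW, IBW)`. The Traub–Johnson ideal body weight is
`height²·1.65/1000`; published implementations differ in the exact
variant, so the coefficient is configurable and the variant in force is
recorded in every run's provenance file. Heights outside 40–200 cm warn
but still compute — silent truncation would hide data errors.

All published constants live in `data/model_library.yaml`, not in code.

## The synthetic discrete prior

The original nonparametric support set is unpublished; only the median,
range and CV of each slope parameter are public. The package therefore
builds a *synthetic* prior: a log-spaced grid (default 25×25) spanning
the published (min–max) box, weighted by the product of independent
truncated log-normal densities with medians 0.71/0.72 and CVs 18%/21%.
On a log-uniform grid the cell measure is constant in log space, so the
weight of a point is simply the normal density of its log. The weighted
marginal medians of the constructed prior reproduce the published medians
to well within 2%. This prior is an approximation and is labelled as such
wherever it appears; posterior summaries (means, medians, effective
support size) always retain the full weight vector for inspection.

## Individual estimation

*MAP (parametric).* The objective is the extended least-squares form

    Σ_i [ (C_obs,i − C_pred,i)² / σ_i² + ln σ_i² ] + Σ_k η_k²/ω_k²

with `σ_i = sqrt((0.11·C_pred,i)² + 0.057²)` evaluated at the model
prediction. The `ln σ²` term is kept because σ depends on the prediction;
dropping it makes overprediction artificially cheap (larger σ discounts
the residual). The nonparametric residual rule is written in terms of the
observation (`SD = 0.02 + 0.1·C_obs`), so there σ is evaluated at the
observed concentration; both choices follow the printed formulas
literally. Optimization is Nelder–Mead (derivative-free; the surface is
smooth and 2-D, so robustness is worth more than speed) from η = 0 with a
restart from the best point of a 5×5 coarse grid on [−1, 1]²; objective
tolerance 1e-8. Because η = 0 is always a starting point, the solution
can never be worse than the prior mode. The optimizer has been verified
against an exhaustive 0.005-resolution grid over [−1.5, 1.5]².

*Discrete posterior (nonparametric).* `w_j ∝ prior_j · Π_i
N(C_obs,i; C_pred,ij, σ_i²)`, computed in log space and renormalized.
Support points never move — only their probabilities change, which is
exactly why gross outliers can defeat this estimator (no candidate curve
fits). If even the best support point's likelihood underflows double
precision, the posterior falls back to uniform and is flagged
`degenerate` with a warning, rather than returning an arbitrary
renormalization.

Point summaries for the nonparametric model (predictions, AUC, dosing
clearance) are posterior-weighted means, not the single best support
point: the mean is a convex combination inside the support hull, is
stable under small data perturbations, and uses the whole posterior.

## Dosing

`dose = target_AUC_cum · CL / n_doses`, from the identity
`AUC_cum = total dose / CL`. The recommendation is therefore invariant to
interval and infusion duration, and re-simulating the recommended regimen
through the PK engine reproduces the target exactly up to floating point
(this closure is asserted in the tests). Doses are not rounded by
default — model comparison needs the raw values; rounding to practical
increments is an option.

## Agreement analysis

Predictive performance: mean percent error (bias) and root-mean-squared
percent error (imprecision) of predictions vs. observations, on the
percent scale. The MPE confidence interval is Student-t on the per-point
percent errors (the method behind published CIs of this kind is rarely
stated; t on the percent errors is the simplest defensible choice).

Bland–Altman percent differences use the pairwise mean as denominator,
`100·(A−B)/((A+B)/2)` — the symmetric convention, chosen because neither
arm is ground truth when two models are compared; the
reference-denominated variant is available. Limits of agreement are
mean ± 1.96 SD; pairs beyond them are flagged with their patient
identifiers. Regression is ordinary least squares of the test model on
the reference model.

`cross_validate` fits both models per patient on first-dose observations
only, scores each against the observations, and compares three
quantities: predicted concentrations at the sampling times, the
first-dose AUC, and the per-administration dose for the 80 mg·h/L
cumulative target. Patients failing either fit are excluded with a
logged reason and counted in the report.

## Virtual cohort generator

The generator emulates a pediatric busulfan TDM service: body weight
log-normal around a 16.7-kg median (log-SD 0.67, so the published
3.2–90.9 kg range sits at roughly ±2.5 SD; draws outside are redrawn),
q6h 2-h infusions × 16, and two samples at 0.5 and 2 h after the end of
the first infusion (absolute times 2.5 and 4.0 h). True parameters are
typical values × exp(η) with the parametric model's ω's; observations add
one combined-error draw per sample, with non-positive draws redrawn (up
to 100 times) rather than floored, to avoid a point mass at zero that no
assay produces.

Height is `35.3·BW^0.38` with 5% log-normal noise, clipped to the
published 46–190 cm range. The exponent and coefficient anchor the
published medians (16.7 kg ↔ 103 cm) and end-ranges (≈55 cm at 3.2 kg,
≈196 cm before clipping at 90.9 kg); height only feeds the ideal-body-
weight computation. Age is a labelled covariate only (neither model uses
it) and sex is carried but unused. Starting doses follow the conventional
intravenous busulfan weight-band nomogram (1.0 / 1.2 / 1.1 / 0.95 /
0.8 mg/kg by band) — the studied service's actual initial doses are not
public, and dose level scales concentrations linearly, so this choice
cannot affect relative errors.

What the generator does *not* emulate: the real age–weight–height joint
distribution (only marginals are matched), repeat TDM occasions and
inter-occasion variability (excluded from both implemented models), assay
LLOQ censoring, and model misspecification beyond the two implemented
structures. Passing tests on this cohort therefore demonstrate internal
consistency of the estimation/dosing machinery under the stated
stochastic model, not predictive performance on real patients.

## Problem sizes and numerical choices

The default experiment sizes are 200 simulated patients for parameter
recovery, 61 for the cross-validation cohort (two concentrations each,
119–122 values, matching the scale of a realistic probe subset), and 20
for the dose-attainment closure check. The brute-force MAP verification
uses a 0.005-step η grid; the discrete-posterior verification uses exact
enumeration on 5-point priors (agreement to 1e-12). Ties in the weighted
median of gridded priors are collapsed to the marginal before
interpolation — the flattened 2-D weighted median is quantized by grid
ties and drifts by grid step.

Recovery under the sparse two-sample design has an intrinsic error floor:
with 23% between-subject CV, an 11% + 57 ng/mL residual model and two
samples, the MAP clearance error is about 14–17% relative RMSE depending
on the realization (an exact-enumeration posterior mean does no better
than ≈15.5%). The dominant contributor is the additive 57 ng/mL error
term at typical busulfan concentrations of 0.6–1.2 mg/L. In the
identifiable limit — exact data, dense sampling, and the *assumed*
residual SD scaled toward zero (`fit_residual_scale`) — the MAP estimate
collapses onto the curve-through-points solution and recovers clearance
to better than 0.01%. With exact data but the full-size residual SD, the
prior and the `ln σ²` term still shrink estimates by a few percent; that
is a property of MAP estimation, not an implementation defect (the
optimizer provably reaches the objective's global optimum on a grid).

## Known limitations

- The nonparametric prior is a reconstruction; real support points would
  change individual posteriors (though the between-model agreement
  pipeline is indifferent to the prior's provenance).
- First-dose parameters are assumed to persist across the course
  (no inter-occasion variability), matching how the dose projections are
  defined.
- Multi-compartment kinetics, oral absorption and nonlinear elimination
  are out of scope.
- The event-CSV reader takes covariates from a patient's first row;
  time-varying covariates are not supported.
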