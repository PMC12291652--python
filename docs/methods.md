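# Methods

## Decision model

The model is a one-shot (non-Markov) comparison of two strategies for
hospitalized penicillin-allergic patients: beta-lactam desensitization (DES)
and management without desensitization (NDES). Three uncertain quantities
drive it — the per-patient incremental hospital cost ΔC, the cure-rate
difference Δp_cure, and the 30-day survival-rate difference Δp_surv — each
modelled as a single distribution fitted to the *difference* between arms
rather than as two per-arm distributions. The published parameter table
tabulates one distribution per difference, and its beta parameters match the
difference's moments exactly, so sampling the difference directly is the
faithful reading. No correlation structure between the three quantities is
published; draws are mutually independent. A correlation hook is deliberately
out of scope.

Per draw: LYG = Δp_surv × L; ICER_LYG = ΔC / LYG; ICER_cure = ΔC / Δp_cure;
NMB(λ) = λ·LYG − ΔC. No discounting is applied to future life-years, and no
quality-of-life (QALY) weighting: the source data contain survival but not
utilities, so the model is a cost-effectiveness, not cost–utility, analysis.

## Calibration

Distributions are calibrated by **method of moments** from summary mean/SD:

- Gamma (shape–scale): shape = (mean/SD)², scale = SD²/mean. The scale
  carries EUR units; shape is dimensionless. The tabulated gamma row
  (1.3, 29,685) is reproduced from (39,563, 34,270) at printed rounding,
  which confirms the shape–scale (not shape–rate) convention:
  1.3 × 29,685 ≈ 38,590 ≈ the deterministic difference.
- Beta: with κ = mean(1−mean)/SD² − 1, α = mean·κ, β = (1−mean)·κ. Moments
  with SD² ≥ mean(1−mean) admit no beta distribution and always raise.

The observed min/max columns are stored and validated
(min ≤ mean ≤ max) but play no role in fitting: only the mean/SD fit
reproduces the tabulated α/β. Both fits are exact inverses of the
closed-form moments, and round-trip to 1e−9 relative error (property-tested).

**Printed-parameter cross-check.** When a config block supplies α/β alongside
the moments, validation accepts it if *either* (a) the moment fit rounds to
the supplied parameters at printed precision (half-up rounding), or (b) the
supplied distribution's analytic moments round back to the configured
mean/SD. Direction (b) is needed because published parameters are typically
fitted from unrounded moments: refitting from the rounded table values lands
near, but not exactly on, them (e.g. refitting Beta from (0.166, 0.017)
gives (79.35, 398.7), not the tabulated (79.9, 401.6), although that
distribution's moments round exactly to (0.166, 0.017)). A config failing
both directions is rejected with a structured error listing every offending
key, unless `--allow-param-mismatch` (or `validation.allow_param_mismatch`)
downgrades it to a logged warning.

When α/β are supplied and pass the cross-check, the simulation uses them
directly — they are the calibration the published analysis actually ran —
falling back to the moment fit otherwise. With the bundled config the cost
draw is therefore Gamma(1.3, 29,685), whose mean (38,590.5 EUR) sits about
0.7 standard errors from the published probabilistic mean of 37,805 EUR.

## Life-years gained

Remaining life expectancy L = (1−w)(LE_m − age) + w(LE_f − age), with
mean age 73.3 y, LE 80.3 y (men) / 85.8 y (women). The cohort's sex mix is
not published; the default w = 0.5 (unweighted sex average) gives
L = 9.75 y. The published mean LYG of 1.42 back-implies L ≈ 9.9
(w ≈ 0.57); `female_weight` is a config key so either convention is one
line away. LYG = Δp_surv × L is exactly bilinear; the mapping is not spelled
out in the publication but 0.143 × 9.75–9.9 ≈ 1.39–1.42 reproduces it to
within a few hundredths of a year.

## Simulation and summaries

- n = 1000 draws (the published simulation size) and a fixed documented
  default seed (20250625); both overridable. All three parameter streams
  come from one `numpy.random.Generator` in a fixed order, so a seed pins
  the entire run bit-for-bit, including output files.
- 95% CIs are empirical 2.5/97.5 percentiles (numpy linear interpolation),
  preserving the right-skew the published asymmetric intervals show. Exact
  CI endpoints are seed-dependent order statistics and are only checked for
  containing the mean and for upper-tail-longer asymmetry.
- P(additional cost) is the fraction of draws with ΔC > 0 — identically 1
  for any gamma, matching the published 100%.
- CEAC(λ) is the fraction of draws with NMB(λ) > 0. Since all LYG draws are
  positive this equals P(ICER < λ), but NMB is the convention robust to sign
  issues. CEAC is non-decreasing in λ with limits 0 (λ = 0) and 1 (λ → ∞).
- **Two ICER conventions** are always reported: the mean of per-draw ratios
  (the only one with a per-draw SD, hence the headline statistic — the
  published value is printed with an SD) and the ratio of means. For these
  skewed draws the mean of ratios has closed-form expectation
  E[ΔC]·E[1/Δp_surv]/L with E[1/Beta(α,β)] = (α+β−1)/(α−1) ≈ 27,960 EUR at
  L = 9.75 — about 12% above the published 24,618 EUR. Whether the original
  analysis used correlated draws, a different L, or a different averaging is
  not stated; the gap is treated with a wide (±25%) tolerance and both
  conventions are exposed so users can see it.
- The published 100% acceptability at λ = 30,000 EUR/LYG is arithmetically
  inconsistent with the ICER CI upper bound of 73,488 EUR printed alongside
  it (a CEAC of 1 would require essentially no draws above 30,000); the
  model reproduces ≈65% there and the figure is documented as
  non-reproducible rather than targeted.
- Reporting precision follows the published tables: whole EUR, proportions
  to 3 decimals, LYG to 2 decimals, half-up rounding.

## Synthetic cohorts

`generate_cohort` emulates the source study's structure: 14 DES vs 42 NDES
(1:3), per-arm per-patient costs from gamma distributions moment-matched to
the configured arm mean/SD, cure and 30-day survival as independent
Bernoulli draws at the arm rates, sex ~ Bernoulli(female_weight), age fixed
at the cohort mean (no age variance is published, so none is simulated).

Two published quantities cannot be derived from the cohort and are handled
as explicit conventions:

- **Per-arm cost SDs** are not published. Defaults allocate variability in
  proportion to the arm means so that the patient-level difference spread
  √(SD_DES² + SD_NDES²) equals the tabulated 34,270 EUR (giving
  SD_DES ≈ 33,146, SD_NDES ≈ 8,710). The per-patient-difference convention
  is used because it is the only one of the right magnitude: the
  standard-error-of-the-mean form √(SD₁²/n₁ + SD₂²/n₂) is an order of
  magnitude too small at n = 14/42.
- **Rate-difference SDs.** The two-proportion standard error at n = 14/42
  (≈0.136 for cure) is far larger than the tabulated 0.017/0.015, so those
  values evidently are not simple two-proportion SEs. `cohort_to_moments`
  computes the two-proportion SE as the honest sample statistic, while the
  calibration SDs default to the tabulated 0.017/0.015 as externally
  supplied inputs (`cure_diff_sd`/`surv_diff_sd` in the config).

What passing tests on synthetic data show — and don't. Parameter recovery
and the end-to-end loop (cohort → moments → calibration → PSA) demonstrate
the pipeline's statistical correctness under the generator's assumptions:
independent gamma costs, independent Bernoulli outcomes, no confounding.
Real case–control data violate several of these (comorbidity-driven cost
confounding is discussed but not modelled in the source; matching induces
dependence), so green tests validate the machinery, not the clinical
conclusion.

## Numerical choices and degenerate inputs

- Validation is fail-fast with named fields; infeasible beta moments raise
  rather than clamp.
- A single-patient arm gets sample SD 0 (ddof=1 undefined); downstream gamma
  fitting then rejects the zero SD explicitly.
- The pooled cohort min/max annotate the cost difference only when they
  bracket it (similar arm means can push the difference below every
  observed cost; the range is then omitted rather than stored in violation
  of min ≤ mean ≤ max).
- Ties in half-up rounding go away from zero, matching printed-table
  conventions rather than banker's rounding.
- Tolerances in tests are standard-error based (3–4 SE) at the simulation
  sizes actually run: 1000 draws for table-level checks, 1e5 draws for
  convergence/oracle checks, 100× cohorts for parameter recovery — sizes
  chosen so Monte Carlo noise is well below the published rounding.

## Known limitations

- One-shot model: no time structure, discounting, EVPI, or multi-arm
  comparison.
- Independence between cost and effectiveness draws is an assumption, not a
  published fact; it is the likeliest cause of the ≈12% ICER-convention gap
  noted above.
- The LYG mapping and the provenance of the tabulated difference SDs are
  reconstructed conventions (documented above), not published formulas.
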