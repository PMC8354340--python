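# Methods

## Score rules and boundary conventions

The three scores are deterministic counts of dichotomized admission
findings (see the README table). All inequality directions are taken
literally as commonly printed — sbp ≤ 100, gcs ≤ 14, rr ≥ 22 (qSOFA),
temp > 38.3 or < 36, hr > 90, rr > 20 (SIRS), wbc > 12,000 or < 4,000,
rr ≥ 20 (qSIRS) — and no rounding is applied to raw vitals before
comparison, so e.g. rr = 20.0 counts for qSIRS but not SIRS, and
rr = 21 counts for SIRS and qSIRS but not qSOFA. Because the three scores
read the respiratory rate at three different cutoffs, the criterion panel
stores three distinct RR flags derived from the single underlying rate;
this makes the qSIRS de-duplication rule (RR counted once, at ≥ 20)
explicit and testable. The qSIRS maximum is 6: five non-RR items plus the
single RR item.

Missing data policy: strict rejection. A record missing any of the six
required vitals is refused with an error naming the field, and a batch
containing any invalid record fails listing all offenders. An explicit
complete-case mode (`drop_invalid=True` in `read_cohort`,
`--drop-invalid` on the CLI) drops and logs bad rows instead. Silent
imputation would fabricate scores, so there is none.

## 2×2 statistics

- **Metrics.** Sensitivity, specificity, PPV, NPV by their defining
  ratios. A zero denominator yields an explicitly *undefined* metric with
  a reason, never a silent 0. CIs are Clopper–Pearson exact
  (`statsmodels.proportion_confint(method="beta")`), chosen because cell
  counts in the replicated tables are as small as 1; asymptotic intervals
  would be anti-conservative there.
- **Percent rendering.** One-decimal **truncation** (36.36 → "36.3",
  97.18 → "97.1"). Truncation, not rounding, reproduces all twelve
  published metric entries; rounding fails on e.g. 98/107 = 91.58 → 91.6
  vs the printed 91.5. Truncation is presentation-only; internal values
  keep full precision. A 1e-9 guard in the truncator absorbs binary
  representation error of ratios of small integers without ever crossing
  a genuine decile boundary.
- **Odds ratio.** (TP·TN)/(FP·FN) with the Woolf log-normal CI. This
  method reproduces the published qSOFA CI (1.5–25.3) and qSIRS CI
  (1.4–95.7) to within printing precision; the published SIRS CI
  (1.8–56.9) matches no method we can attribute (Woolf gives ≈ 1.7–39.8)
  and is therefore reported but never asserted. No continuity correction
  is applied by default anywhere; with a zero cell the OR errors and the
  Haldane–Anscombe 0.5 correction is an explicit opt-in, recorded in the
  result's `method` field.
- **Tests.** Pearson χ² (1 df, no Yates correction, expected counts from
  margins) and the standard two-sided Fisher exact test (sum of
  hypergeometric probabilities of tables no more probable than the
  observed one, at fixed margins). The selection rule — Fisher when any
  expected cell < 5 (Cochran's rule) — is the conventional reading of
  "chi-square or Fisher" and is configurable. Both tests go through
  scipy; the test suite holds them to independent oracles (hand-computed
  expected-count arithmetic; exhaustive enumeration over every 2×2 table
  with total ≤ 30).

## ROC, AUC and DeLong

The ROC convention is *score ≥ threshold → positive*; operating points
are emitted at every distinct score value plus the all-negative anchor,
so curves run from (0,0) to (1,1) (points via
`sklearn.metrics.roc_curve(drop_intermediate=False)`).

The AUC is the Mann–Whitney estimator with tie correction,
Â = [#(s_dead > s_alive) + ½·#ties]/(m·n), computed from midrank
placement values in O(N log N) (the Sun–Xu formulation of DeLong's
components): for case i, V₁₀ᵢ is the fraction of controls it outranks
(ties half); for control j, V₀₁ⱼ symmetric. Then
Var(Â) = S₁₀/m + S₀₁/n with sample variances of the placements, and for
two scores on the same patients the paired z-test uses the placement
covariance matrices, z = (Â_a − Â_b)/√(cᵀΣc), two-sided normal p. Â from
placements is algebraically identical to the trapezoid over the full
operating-point set; the suite asserts this equivalence, agreement with
brute-force pairwise counting, and sign/magnitude agreement of z with a
stratified bootstrap.

Degenerate cases: a single-class outcome is an error; self-comparison of
a score with itself returns z = 0, p = 1; two constant scores are an
error (no paired AUC variability exists). With perfect separation the
DeLong variance is 0 and the CI collapses to the point.

A binary positivity flag used as a "score" gives AUC = (sens + spec)/2
exactly — which is why published multi-point-score AUCs (0.845 / 0.783 /
0.737 in the replicated study) cannot be recovered from the printed 2×2
tables alone: they require the patient-level distribution of score
points, which is not printed. The AUC machinery is therefore validated by
the oracle properties above rather than against those three numbers.

## Synthetic cohort generator

One-factor latent-severity (Gaussian copula / probit) model — the
simplest mechanism that delivers (a) exact marginal prevalences and
(b) tunable positive association between every criterion and death:

- z ~ N(0,1) per patient; criterion k fires when
  λₖ·z + √(1−λₖ²)·ε > Φ⁻¹(1−pₖ), so the marginal is exactly pₖ for any
  loading λₖ ∈ [0,1).
- Death ~ Bernoulli(logistic(β₀ + s·z)). β₀ is solved from
  E_z[logistic(β₀ + s·z)] = target mortality by Brent root-finding over
  an 80-node Gauss–Hermite quadrature (residual ≤ 1e-6; cross-checked
  against a 10⁶-draw Monte-Carlo in the tests).
- Defaults: n = 118 and the modelled study's marginals — prevalences
  (temp 0.364, sbp 0.186, hr 0.655, rr≥20 0.559, gcs 0.847, wbc 0.568),
  mortality 0.093 — with loading 0.4 on every criterion and death slope
  1.5, values chosen once to make the score–death association visible at
  n = 118 while keeping ORs in a clinically plausible single-digit range.
  All are configuration, not constants.
- Raw vitals are drawn uniformly from documented normal/abnormal ranges
  consistent with each flag (e.g. sbp_low → U[70,100], else U[101,150]);
  abnormal temperature is fever with probability 0.7, abnormal WBC is
  leukocytosis with probability 0.8 (clinically typical splits in
  abdominal sepsis; the dichotomized flag is all that matters
  downstream). The respiratory rate is one underlying value
  (U[20,35] vs U[10,19.9]), keeping its three cutoff flags consistent.
- Determinism: one `numpy` Generator seeded from the config; a fixed seed
  yields a byte-identical serialized cohort.

What the generator does *not* emulate: real joint dependence beyond a
single factor (no criterion-specific pairwise correlations), realistic
continuous vital distributions (only the flags are calibrated),
time-varying vitals, or outcome-linked covariates such as ASA class or
diagnosis. Passing tests on synthetic cohorts therefore demonstrate
pipeline correctness and calibration of the model's own margins — not
clinical validity on real patients. Two baseline-table defaults are
internally questionable in the source (gcs_low 84.7% alongside 11.1%
qSOFA positivity; SIRS positivity 62.7% vs the 47/118 implied by the
outcome table); they are kept as overridable defaults with a logged
warning, and the replication of the outcome tables never depends on the
generator.

## Replication harness

The published 2×2 counts are shipped as package data and pushed through
the same statistics as any user cohort. Asserted: the twelve metric
percents (exact after truncation), the three OR point estimates (|Δ| ≤
0.1, or ≤ 0.2 for the zero-decimal SIRS value), the qSOFA/qSIRS Woolf CI
bounds (|Δ| ≤ 0.2), and headline mortality (11/118 → "9.3"). Reported
but never asserted: per-table p-values (the source does not say which
test produced each; both χ² and Fisher are shown side by side) and the
SIRS CI (method unattributable). An internal-consistency invariant checks
that all three tables share the same death margin (11/107/118). Where an
abstract and a table disagree on a digit (SIRS sensitivity 81.9 vs 81.8),
the table wins.

## Problem sizes

The default suite exercises the generator at n = 20,000 (unit) and
n = 50,000 (end-to-end calibration: prevalence within ±0.01, mortality
within ±0.005), enumerates all ~46,000 2×2 tables with total ≤ 30 for the
Fisher oracle, and uses a 2,000-replicate bootstrap for the DeLong
cross-check; the whole suite runs in well under a minute of CPU plus
~20 s for the Fisher enumeration. `scripts/acceptance.py` uses the same
sizes.
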