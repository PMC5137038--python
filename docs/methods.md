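# Methods

## The model

A genome-wide NIPT pipeline summarises the evidence for a trisomy of
chromosome 13, 18 or 21 as a Z-score: the number of control-group standard
deviations by which the sample's target-chromosome read fraction exceeds
the mean of diploid controls. `niptbayes` models that Z-score under two
hypotheses:

- **Euploid**: Z ~ N(0, 1). By construction of the Z-score against a
  diploid control group, 2Φ(3) − 1 ≈ 99.7% of euploid samples fall in
  [−3, +3].
- **Trisomic**: the extra fetal chromosome copy raises the target-chromosome
  fraction of the cell-free DNA pool by half the fetal fraction *f* (the
  fetal genome contributes 3 copies instead of 2, diluted by *f*). On the
  Z scale that excess is

      z_exp = (f / 2) / CV,

  with *f* and the control-group coefficient of variation CV both in
  percent, and Z ~ N(z_exp, 1).

The fetal fraction is often unknown or known only as a range, so it is a
nuisance parameter. It carries a prior that is a fixed value, a uniform
range, or a weighted mixture of uniform ranges; the trisomic likelihood is
the prior-weighted average of the shifted Gaussian. The posterior
("personalised a posteriori risk", PPR) is the Bayes odds update of the
pre-test risk *p* with the likelihood ratio LR = trisomic density /
euploid density at the observed Z:

    PPR = p · LR / (p · LR + 1 − p).

Only chromosomal *excess* is modelled (one-sided): a Z-score below the
neutral point z_exp/2 yields LR < 1 and a posterior below the prior, which
is reported as-is — that behaviour is what quantifies false-negative risk
at low fetal fractions. Monosomies, sex-chromosome aneuploidies,
microdeletions and mosaicism are out of scope; confined placental mosaicism
in particular violates the fixed-shift assumption and is the main reason a
high PPR still requires invasive confirmation.

## Parameters and defaults

| parameter | units | default | why |
|---|---|---|---|
| CV (chr21) | % of mean fraction | 0.5 | close to empirically measured assay values |
| CV (chr13/18) | % | 0.4 | higher read counts on these chromosomes give lower variation |
| fetal-fraction prior | % | 0.4·U(1, 23) + 0.6·U(6, 18) | mimics the observed ff distribution (mean 12%) while over-weighting the extremes, so unknown-ff posteriors stay conservative at low ff |
| call threshold | Z | 3.0 | the conventional 3-SD cutoff (99.87% euploid specificity one-sided) |
| prior | probability | — | required input: FCT result, odds string, or age-table lookup |

All of these can be overridden per sample, per CLI flag, or in a YAML/JSON
config; flags > config > built-ins. Units policy: *f* and CV are always
percentages; values with *f* > 50 or CV ≥ 5 are rejected as
fraction-vs-percent mistakes rather than silently producing garbage.

## Numerical choices

- **Closed-form marginalisation.** For a uniform component on [lo, hi] the
  average of N(z; f/(2CV), 1) over *f* reduces, after substituting
  u = f/(2CV), to (Φ(z − lo/(2CV)) − Φ(z − hi/(2CV))) / ((hi − lo)/(2CV)).
  The engine evaluates this directly instead of numerical quadrature: it is
  exact, deterministic, vectorised, and has no tuning knobs. Tests
  cross-check it against an independent 10⁵-node trapezoid integration of
  the defining integral (agreement to 1e-6) and, for fixed *f*, against the
  closed-form likelihood ratio exp(z_exp·z − z_exp²/2) (1e-10).
- **Tail stability.** Far above the component's range both CDFs approach 1
  and the difference cancels in floating point; per element the code
  switches to the equivalent survival-function difference based on the sign
  of the interval midpoint. Posteriors are computed in log-odds space
  (logit p + log LR through a logistic), so extreme Z-scores saturate
  cleanly at 0 or 1 instead of overflowing.
- **Degenerate inputs.** A zero-width uniform component is treated as a
  point mass and reproduces the fixed-*f* result to 1e-9. Priors of exactly
  0 or 1 are rejected (nothing to update in a screening population).
  |Z| > 50 is rejected as outside any plausible assay range.
- **Display rounding.** The raw posterior is kept at full precision; the
  clinical display string rounds to integer percent in 1–99, degrades to
  "<1" and "<0.1" below, and caps at "99.9" above — a screen is never
  reported as certainty. Ten of the 14 built-in validation samples (all
  with Z > 6) hit the cap.
- **Interpolation.** Age-table priors use bilinear interpolation on the raw
  probability grid (no log-odds transform), exact at nodes and linear along
  axes, with no extrapolation outside the table hull — an extrapolated
  clinical prior would be unsafe, so out-of-hull queries raise.
- **Odds notation.** "1:n" and "1/n" are both read as a risk of 1 in n,
  probability 1/n, matching their interchangeable clinical use
  ("1:1000 (0.001)"); the strict-odds reading 1/(n+1) is deliberately not
  used.

## The simulator and what passing tests show

`simulate_cohort` is the sampling dual of the scorer: each pregnancy is
trisomic with the given prevalence, draws *f* from the fetal-fraction
prior, and draws Z from the status-appropriate Gaussian, using one seeded
numpy generator with a fixed draw order (status, component, fraction,
noise) for stream-level reproducibility. Because generator and scorer share
the model exactly, two facts must hold and are exercised as stochastic
validation at n = 10⁵ with fixed seeds (the suite runs in seconds):

- the empirical detection rate at threshold t matches Φ(z_exp − t) within
  3 binomial SE, and euploid |Z| ≤ 3 coverage matches 99.73%;
- the posterior computed with prior = prevalence is calibrated: in every
  populated posterior bin the observed trisomy frequency matches the mean
  posterior within 3 binomial SE, while scoring with a deliberately wrong
  prior breaks calibration detectably (negative control).

The simulator models only the Z-score abstraction — no read counts, GC
bias, sequencing error, or the heavier-tailed Z distributions seen in
mosaic samples. Passing tests therefore demonstrate internal consistency
of the Bayesian machinery, not the adequacy of the two-Gaussian model for
any particular laboratory's data; the CV and fetal-fraction inputs remain
the user's responsibility.

## Known limitations

- The unknown-fetal-fraction posteriors of the original web tool cannot be
  matched exactly: its published example values under unknown ff imply a
  marginalisation scheme that density averaging does not reproduce, and the
  scheme itself is not specified. This package documents its own
  marginalisation (the closed-form density average above) and validates it
  by the oracle and calibration properties instead. Our unknown-ff
  posterior at Z = 3 with a 1:1000 prior is 0.40%, consistent with the
  published "<1%" bound.
- CV is never marginalised; if unknown, a default is used and reported.
- The trisomic SD is fixed at 1.0; mosaicism-driven overdispersion is not
  modelled.
- No clinical maternal-age risk table is bundled (the published tables are
  licensed works); `synthetic_risk_table()` provides an invented grid with
  the correct schema for tests and demonstrations, and users load their own
  tables from CSV.
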