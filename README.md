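# niptbayes

Personalised posterior trisomy risk from non-invasive prenatal testing
(NIPT) results.

NIPT screens for fetal trisomy 13, 18 and 21 by sequencing cell-free DNA in
maternal plasma; genome-wide pipelines report the evidence as a **Z-score**
against a diploid control group. A positive call (Z > 3) from a test with
">99% sensitivity and specificity" does *not* mean a >99% chance the foetus
is trisomic — that chance depends on the woman's pre-test (a priori) risk.
`niptbayes` is for screening laboratories and clinical geneticists who need
to turn a Z-score into the number that actually matters for counselling:
the **personalised a posteriori risk (PPR)**, the posterior probability of
trisomy given the woman's own prior.

## The model

Under the euploid hypothesis Z ~ N(0, 1). Under trisomy, the extra fetal
chromosome copy shifts the mean to

    z_exp = (f / 2) / CV

where *f* is the fetal DNA fraction and CV the control-group coefficient of
variation (both in percent), with SD 1. When *f* is unknown or ranged it is
integrated out over a prior (default: the mixture 0.4·U(1, 23) +
0.6·U(6, 18) %). The posterior is the Bayes odds update

    PPR = p · LR / (p · LR + 1 − p),    LR = P(z | trisomy) / P(z | euploid).

Sensitivity analytics come from the same model: detection power at call
threshold t is Φ(z_exp − t). See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

A woman with a 1:100 prior (e.g. from the first-trimester combined test)
receives a chromosome-21 Z-score of 3.0; the lab measured 4% fetal DNA and
runs at CV 0.5%:

```text
$ niptbayes ppr --prior 1:100 --z 3 --cv 0.5 --ff 4
chromosome        21
prior             0.01
cv_percent        0.5
fetal_fraction    fixed 4%
likelihood_ratio  54.5982
ppr               0.355461
ppr_display       36%
```

Despite the "positive" screen, her chance of carrying a foetus with Down
syndrome is 36% — a 64% chance of a false positive. The same Z-score gives
5% at a 1:1000 prior and 86% at 1:10; only above Z ≈ 6 does the posterior
become effectively prior-independent (display capped at "99.9").

Assay planning uses the same engine:

```text
$ niptbayes sensitivity --ff 6 --cv 0.5
sensitivity          0.99865
sensitivity_percent  99.87
euploid_coverage     0.9973
```

i.e. at 6% fetal DNA and CV 0.5% the screen detects 99.87% of trisomies at
the Z > 3 cutoff (dropping to 84.13% at 4% fetal DNA;
`--target-sensitivity` inverts the formula to the CV required).

Other subcommands: `batch` scores a TSV/CSV of samples (per-row errors are
reported, never dropped; exit code 3 flags partial failure), `grid` sweeps
priors × Z-scores, `simulate` writes a synthetic cohort that flows back
through `batch`. Priors may be given as decimals ("0.001"), odds ("1:1000",
"1/4") or via a maternal-age × gestational-week risk-table CSV with
bilinear interpolation. Everything is also available as a library:

```python
from niptbayes import FetalFractionPrior, posterior_risk
res = posterior_risk(0.01, 3.0, FetalFractionPrior.default(), 0.5)
print(res.ppr, res.display_percent)   # 0.0399… "4"
```

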