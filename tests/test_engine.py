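"""Unit and property tests for the Bayesian scoring core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from niptbayes import (
    FetalFractionPrior,
    TrisomyTarget,
    euploid_central_coverage,
    euploid_density,
    expected_z,
    format_ppr_percent,
    likelihood_ratio,
    posterior_ppr,
    posterior_risk,
    required_cv,
    sensitivity,
    trisomy_density,
)
from niptbayes.errors import (
    DegeneratePriorError,
    InvalidParameterError,
    UnitsError,
)

from conftest import trapezoid_density_oracle


class TestExpectedZ:
    @pytest.mark.parametrize(
        "f, cv, expect",
        [(6.0, 0.5, 6.0), (4.0, 0.5, 4.0), (4.0, 0.4, 5.0), (1e-9, 0.5, 1e-9)],
    )
    def test_values(self, f, cv, expect):
        assert expected_z(f, cv) == pytest.approx(expect)

    def test_monotone_in_f_and_cv(self):
        assert expected_z(8, 0.5) > expected_z(6, 0.5)
        assert expected_z(6, 0.4) > expected_z(6, 0.5)

    @pytest.mark.parametrize("f, cv", [(0, 0.5), (-1, 0.5), (6, 0), (6, -0.2)])
    def test_nonpositive_rejected(self, f, cv):
        with pytest.raises(InvalidParameterError):
            expected_z(f, cv)

    def test_units_guard(self):
        # percent-vs-fraction confusion: f=0.04 would be accepted (legal %),
        # but CV=5 or f=60 cannot be a percent value on this assay
        with pytest.raises(UnitsError):
            expected_z(6, 5.0)
        with pytest.raises(UnitsError):
            expected_z(60, 0.5)


class TestDensities:
    def test_euploid_pdf_values(self):
        assert euploid_density(0.0) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-9)
        assert euploid_density(3.0) == pytest.approx(0.0044318, abs=1e-7)
        assert euploid_density(-3.0) == euploid_density(3.0)

    def test_fixed_is_shifted_normal(self, fixed4):
        # z_exp = 4: density at z=3 is phi(-1)
        assert trisomy_density(3.0, fixed4, 0.5) == pytest.approx(0.2419707, abs=1e-7)

    def test_fixed_zero_shift_reduces_to_euploid(self):
        # tiny f => z_exp ~ 0 => trisomic and diploid curves coincide
        ff = FetalFractionPrior.fixed(1e-9)
        assert trisomy_density(0.0, ff, 0.5) == pytest.approx(euploid_density(0.0), abs=1e-9)

    @pytest.mark.parametrize("z", [-2.0, 0.0, 3.0, 4.0, 8.0, 25.0])
    def test_mixture_matches_trapezoid_oracle(self, default_mixture, z):
        ours = trisomy_density(z, default_mixture, 0.5)
        oracle = trapezoid_density_oracle(z, default_mixture, 0.5)
        assert ours == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize(
        "ff",
        [
            FetalFractionPrior.fixed(5.0),
            FetalFractionPrior.uniform(2.0, 10.0),
            FetalFractionPrior.default(),
        ],
        ids=["fixed", "uniform", "mixture"],
    )
    def test_density_normalises_to_one(self, ff):
        zmax = max(hi for _, hi, _ in ff.components) / (2 * 0.5)
        zgrid = np.linspace(-10.0, zmax + 10.0, 200_001)
        mass = np.trapezoid(trisomy_density(zgrid, ff, 0.5), zgrid)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_marginal_collapse_lo_equals_hi(self):
        fixed = FetalFractionPrior.fixed(7.0)
        degenerate = FetalFractionPrior.uniform(7.0, 7.0)
        for z in [-1.0, 0.0, 3.0, 6.5]:
            assert trisomy_density(z, degenerate, 0.5) == pytest.approx(
                trisomy_density(z, fixed, 0.5), abs=1e-9
            )

    def test_deep_tail_is_stable(self, default_mixture):
        # far above every component's expected Z the cdf difference cancels;
        # the survival-function branch must keep the density positive
        d = trisomy_density(48.0, default_mixture, 0.5)
        assert 0 < d < 1e-3


class TestLikelihoodRatio:
    def test_closed_form_fixed(self, fixed4):
        # phi(z - 4)/phi(z) = exp(4 z - 8)
        assert likelihood_ratio(3.0, fixed4, 0.5) == pytest.approx(math.exp(4.0), rel=1e-10)
        assert likelihood_ratio(2.5, fixed4, 0.5) == pytest.approx(math.exp(2.0), rel=1e-10)

    def test_midpoint_gives_unity(self):
        ff = FetalFractionPrior.fixed(6.0)
        z_exp = expected_z(6.0, 0.5)
        assert likelihood_ratio(z_exp / 2, ff, 0.5) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        z=st.floats(-5.0, 30.0),
        f=st.floats(0.1, 24.0),
        cv=st.floats(0.18, 0.8),
    )
    def test_closed_form_equivalence_property(self, z, f, cv):
        """Density-ratio path equals exp(z_exp*z - z_exp^2/2) for fixed f."""
        z_exp = (f / 2) / cv
        if z_exp > 30:
            return
        ours = likelihood_ratio(z, FetalFractionPrior.fixed(f), cv)
        closed = math.exp(z_exp * z - z_exp**2 / 2)
        assert ours == pytest.approx(closed, rel=1e-10)


class TestPosterior:
    @pytest.mark.parametrize(
        "prior, z, display",
        [(0.001, 3.0, "5"), (0.01, 3.0, "36"), (0.1, 3.0, "86"), (0.1, 2.5, "45")],
    )
    def test_worked_examples(self, fixed4, prior, z, display):
        res = posterior_risk(prior, z, fixed4, 0.5)
        assert res.display_percent == display

    def test_result_internal_consistency(self, fixed4):
        res = posterior_risk(0.01, 3.5, fixed4, 0.5)
        p, lr = res.prior, res.likelihood_ratio
        assert res.ppr == pytest.approx(p * lr / (p * lr + 1 - p), abs=1e-12)
        assert res.likelihood_ratio == pytest.approx(
            res.likelihood_trisomy / res.likelihood_diploid, rel=1e-12
        )

    def test_prior_neutral_point(self):
        for f, cv, p in [(4.0, 0.5, 0.001), (6.0, 0.5, 0.3), (8.0, 0.4, 0.02)]:
            ff = FetalFractionPrior.fixed(f)
            z_mid = expected_z(f, cv) / 2
            assert posterior_ppr(p, z_mid, ff, cv) == pytest.approx(p, abs=1e-12)

    @settings(max_examples=150, derandomize=True)
    @given(
        p=st.floats(1e-5, 0.5),
        z1=st.floats(-4.0, 10.0),
        dz=st.floats(0.01, 5.0),
        dp=st.floats(1e-6, 0.4),
    )
    def test_monotone_in_z_and_prior(self, p, z1, dz, dp):
        """Posterior rises strictly with the Z-score and with the prior."""
        fixed4 = FetalFractionPrior.fixed(4.0)
        lo = posterior_ppr(p, z1, fixed4, 0.5)
        hi = posterior_ppr(p, z1 + dz, fixed4, 0.5)
        assert hi > lo
        assert posterior_ppr(min(p + dp, 0.999), z1, fixed4, 0.5) > lo

    def test_negative_z_lowers_risk(self, default_mixture):
        # one-sided trisomy model: z below the neutral point argues euploid
        assert posterior_ppr(0.1, -2.0, default_mixture, 0.5) < 0.1

    def test_saturation_above_z6(self, default_mixture):
        for p in [0.001, 0.01, 0.1, 0.5]:
            for cv in [0.3, 0.4, 0.5]:
                assert posterior_ppr(p, 6.0, default_mixture, cv) > 0.99

    def test_extreme_z_saturates_without_overflow(self, default_mixture):
        assert posterior_ppr(0.001, 45.0, default_mixture, 0.5) == pytest.approx(1.0)
        assert posterior_ppr(0.001, -45.0, default_mixture, 0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_prior_rejected(self, fixed4, bad):
        with pytest.raises(DegeneratePriorError):
            posterior_risk(bad, 3.0, fixed4, 0.5)

    def test_nonfinite_or_huge_z_rejected(self, fixed4):
        with pytest.raises(InvalidParameterError):
            posterior_risk(0.01, float("nan"), fixed4, 0.5)
        with pytest.raises(InvalidParameterError):
            posterior_risk(0.01, 51.0, fixed4, 0.5)


class TestSensitivityAnalytics:
    def test_printed_anchor_values(self):
        assert 100 * sensitivity(6, 0.5, 3) == pytest.approx(99.87, abs=0.005)
        assert 100 * sensitivity(4, 0.5, 3) == pytest.approx(84.13, abs=0.005)
        assert required_cv(4, sensitivity(6, 0.5, 3), 3) == pytest.approx(1 / 3, abs=5e-4)

    def test_mean_on_cutoff_gives_half(self):
        # z_exp == threshold: half the trisomic distribution is called
        assert sensitivity(3.0, 0.5, 3.0) == pytest.approx(0.5, abs=1e-12)

    def test_required_cv_roundtrip(self):
        for f, target in [(4.0, 0.9987), (6.0, 0.99), (10.0, 0.75)]:
            cv = required_cv(f, target, 3.0)
            assert sensitivity(f, cv, 3.0) == pytest.approx(target, abs=1e-9)

    def test_required_cv_unreachable_target(self):
        with pytest.raises(InvalidParameterError):
            required_cv(4.0, 0.5, 3.0)

    def test_central_coverage(self):
        assert 100 * euploid_central_coverage(3.0) == pytest.approx(99.73, abs=0.005)
        assert euploid_central_coverage(0.0) == 0.0
        assert euploid_central_coverage(1.959964) == pytest.approx(0.95, abs=1e-6)


class TestDisplayAndTypes:
    @pytest.mark.parametrize(
        "ppr, text",
        [
            (0.0005, "<0.1"),
            (0.004, "<1"),
            (0.0095, "<1"),
            (0.012, "1"),
            (0.45085, "45"),
            (0.994, "99"),
            (0.9951, "99.9"),
            (1.0, "99.9"),
        ],
    )
    def test_display_rounding(self, ppr, text):
        assert format_ppr_percent(ppr) == text

    @pytest.mark.parametrize("raw", [13, "18", "chr21", "T21"])
    def test_target_parsing(self, raw):
        assert TrisomyTarget.parse(raw) in (TrisomyTarget.T13, TrisomyTarget.T18, TrisomyTarget.T21)

    @pytest.mark.parametrize("raw", [12, "chrX", "21q", "7"])
    def test_target_rejection(self, raw):
        with pytest.raises(InvalidParameterError):
            TrisomyTarget.parse(raw)

    def test_ff_prior_validation(self):
        with pytest.raises(InvalidParameterError):
            FetalFractionPrior.mixture([(1, 23, 0.5), (6, 18, 0.6)])  # weights sum 1.1
        with pytest.raises(InvalidParameterError):
            FetalFractionPrior.uniform(8, 5)  # hi < lo
        with pytest.raises(InvalidParameterError):
            FetalFractionPrior.fixed(-2)

    def test_default_mixture_is_expected(self, default_mixture):
        assert default_mixture.components == ((1.0, 23.0, 0.4), (6.0, 18.0, 0.6))
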