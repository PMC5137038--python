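"""Bayesian core of the posterior-risk calculator.

A genome-wide NIPT result for chromosome 13, 18 or 21 is summarised as a
Z-score: the number of control-group standard deviations by which the
sample's target-chromosome read fraction deviates from the diploid mean.
Under the euploid hypothesis Z is standard normal.  Under a (non-mosaic)
trisomy the extra chromosome copy raises the target fraction by half the
fetal fraction, so the trisomic Z distribution is a unit-variance Gaussian
shifted to

    z_exp = (f / 2) / CV

with the fetal DNA percentage ``f`` and the control-group coefficient of
variation ``CV`` both expressed in percent.  When ``f`` is only known as a
range (or not at all) it is a nuisance parameter: the trisomic likelihood is
the average of the shifted Gaussian over a prior on ``f`` — here a fixed
value, a uniform range, or a weighted mixture of uniform ranges.  For a
uniform component on ``[lo, hi]`` the average has the closed form

    (Phi(z - lo/(2 CV)) - Phi(z - hi/(2 CV))) / ((hi - lo)/(2 CV)),

a difference of normal CDFs, which this module evaluates directly (no
quadrature error, stable in both tails).

The posterior ("personalised a posteriori risk", PPR) is the Bayes odds
update of the pre-test risk ``p`` with the likelihood ratio
``LR = trisomy density / euploid density``:

    PPR = p * LR / (p * LR + 1 - p).

Everything here is deterministic and vectorised over ``z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .errors import DegeneratePriorError, InvalidParameterError, UnitsError

__all__ = [
    "TrisomyTarget",
    "AssayProfile",
    "FetalFractionPrior",
    "NiptMeasurement",
    "PosteriorResult",
    "expected_z",
    "euploid_density",
    "trisomy_density",
    "likelihood_ratio",
    "posterior_risk",
    "sensitivity",
    "required_cv",
    "euploid_central_coverage",
    "format_ppr_percent",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# Units guards: f and CV are percentages.  CV >= 5% or f > 50% almost
# certainly means the caller passed a fraction or a raw percentage where
# the other was expected; reject loudly rather than produce nonsense.
MAX_CV_PERCENT = 5.0
MAX_FF_PERCENT = 50.0
MAX_ABS_Z = 50.0


class TrisomyTarget(IntEnum):
    """Autosomal trisomy targeted by the screen (chromosome 13, 18 or 21)."""

    T13 = 13
    T18 = 18
    T21 = 21

    @classmethod
    def parse(cls, value) -> "TrisomyTarget":
        """Coerce ``13 / "18" / "chr21"`` style labels; reject anything else."""
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        if text.startswith("chr"):
            text = text[3:]
        if text.startswith("t") and text[1:].isdigit():
            text = text[1:]
        try:
            return cls(int(text))
        except (KeyError, ValueError):
            raise InvalidParameterError(
                f"unsupported trisomy target {value!r}: expected 13, 18 or 21"
            ) from None


def _check_cv(cv_percent: float) -> float:
    cv = float(cv_percent)
    if not math.isfinite(cv) or cv <= 0:
        raise InvalidParameterError(f"coefficient of variation must be > 0, got {cv_percent!r}")
    if cv >= MAX_CV_PERCENT:
        raise UnitsError(
            f"coefficient of variation {cv} looks wrong: expected percent of the "
            f"mean in (0, {MAX_CV_PERCENT}); typical assay values are 0.18-0.5"
        )
    return cv


def _check_ff(f_percent: float) -> float:
    f = float(f_percent)
    if not math.isfinite(f) or f <= 0:
        raise InvalidParameterError(f"fetal DNA percentage must be > 0, got {f_percent!r}")
    if f > MAX_FF_PERCENT:
        raise UnitsError(
            f"fetal DNA percentage {f} looks wrong: expected percent in "
            f"(0, {MAX_FF_PERCENT}]"
        )
    return f


def _check_z(z) -> np.ndarray:
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("Z-score must be finite")
    if np.any(np.abs(arr) > MAX_ABS_Z):
        raise InvalidParameterError(f"|Z| > {MAX_ABS_Z} is outside the plausible assay range")
    return arr


@dataclass(frozen=True)
class AssayProfile:
    """Per-chromosome assay precision and positive-call cutoff.

    Parameters
    ----------
    cv_percent
        Coefficient of variation of the diploid control group, in percent of
        the mean chromosome fraction.  Recommended defaults: 0.5 for
        chromosome 21, 0.4 for chromosomes 13 and 18.
    z_threshold
        Z-score above which a sample is called positive (default 3.0).
    """

    cv_percent: float
    z_threshold: float = 3.0

    def __post_init__(self) -> None:
        _check_cv(self.cv_percent)
        if not (self.z_threshold > 0):
            raise InvalidParameterError(f"z_threshold must be > 0, got {self.z_threshold!r}")


@dataclass(frozen=True)
class FetalFractionPrior:
    """Prior knowledge of the fetal DNA percentage.

    ``kind`` is one of ``fixed`` (exact measurement), ``uniform`` (a measured
    range) or ``mixture`` (weighted uniform components).  ``components`` holds
    ``(low_percent, high_percent, weight)`` triples; for ``fixed`` there is a
    single zero-width component with weight 1.

    The default, used when no measurement is available, over-weights extreme
    fetal fractions relative to a Gaussian: 0.4 * U(1, 23) + 0.6 * U(6, 18).
    """

    kind: str
    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "uniform", "mixture"}:
            raise InvalidParameterError(f"unknown fetal-fraction prior kind {self.kind!r}")
        if not self.components:
            raise InvalidParameterError("fetal-fraction prior needs at least one component")
        total = 0.0
        for lo, hi, w in self.components:
            _check_ff(lo)
            _check_ff(hi)
            if hi < lo:
                raise InvalidParameterError(
                    f"fetal-fraction component has high {hi} < low {lo}"
                )
            if not (w > 0):
                raise InvalidParameterError(f"component weight must be > 0, got {w!r}")
            total += w
        if abs(total - 1.0) > 1e-12:
            raise InvalidParameterError(f"component weights must sum to 1, got {total!r}")

    @classmethod
    def fixed(cls, f_percent: float) -> "FetalFractionPrior":
        f = _check_ff(f_percent)
        return cls("fixed", ((f, f, 1.0),))

    @classmethod
    def uniform(cls, low_percent: float, high_percent: float) -> "FetalFractionPrior":
        return cls("uniform", ((float(low_percent), float(high_percent), 1.0),))

    @classmethod
    def mixture(
        cls, components: Iterable[tuple[float, float, float]]
    ) -> "FetalFractionPrior":
        return cls("mixture", tuple((float(a), float(b), float(w)) for a, b, w in components))

    @classmethod
    def default(cls) -> "FetalFractionPrior":
        """Unknown fetal fraction: 0.4 * U(1, 23) + 0.6 * U(6, 18) percent."""
        return cls.mixture([(1.0, 23.0, 0.4), (6.0, 18.0, 0.6)])

    def mean(self) -> float:
        return sum(w * 0.5 * (lo + hi) for lo, hi, w in self.components)

    def describe(self) -> str:
        if self.kind == "fixed":
            return f"fixed {self.components[0][0]:g}%"
        parts = [f"{w:g}*U({lo:g},{hi:g})" for lo, hi, w in self.components]
        return " + ".join(parts) + " %"


@dataclass(frozen=True)
class NiptMeasurement:
    """A single NIPT read-out: target chromosome and observed Z-score."""

    target: TrisomyTarget
    z: float

    def __post_init__(self) -> None:
        _check_z(self.z)


def expected_z(f_percent: float, cv_percent: float) -> float:
    """Mean of the trisomic Z distribution: ``(f / 2) / CV``.

    One extra copy of the target chromosome in the fetal compartment raises
    the chromosome fraction by half the fetal fraction relative to the
    diploid mean; dividing by the control-group CV converts that excess to
    the Z scale.  Strictly increasing in ``f``, strictly decreasing in ``CV``.
    """
    f = _check_ff(f_percent)
    cv = _check_cv(cv_percent)
    return (f / 2.0) / cv


def euploid_density(z) -> np.ndarray | float:
    """Standard normal density of the Z-score under the diploid model."""
    arr = _check_z(z)
    out = np.exp(-0.5 * arr * arr - _LOG_SQRT_2PI)
    return float(out) if out.ndim == 0 else out


def _component_bounds(lo: float, hi: float, cv: float) -> tuple[float, float]:
    """Map a fetal-fraction interval to expected-Z units."""
    return lo / (2.0 * cv), hi / (2.0 * cv)


def _log_interval_mass(x_low, x_high) -> np.ndarray:
    """log(Phi(x_high) - Phi(x_low)) elementwise, stable in both tails.

    Far in the right tail both CDFs approach 1 and the naive difference
    cancels; there the survival-function difference Q(x_low) - Q(x_high)
    is exact.  Pick per element based on the interval midpoint's sign.
    """
    x_low = np.asarray(x_low, dtype=float)
    x_high = np.asarray(x_high, dtype=float)
    use_sf = (x_low + x_high) > 0
    diff = np.where(
        use_sf,
        ndtr(-x_low) - ndtr(-x_high),
        ndtr(x_high) - ndtr(x_low),
    )
    with np.errstate(divide="ignore"):
        return np.log(np.clip(diff, 0.0, None))


def _log_trisomy_density(z: np.ndarray, ff: FetalFractionPrior, cv: float) -> np.ndarray:
    """Log marginal density of z under trisomy, averaging over the ff prior."""
    z = np.asarray(z, dtype=float)
    comp_logs = []
    for lo, hi, w in ff.components:
        a, b = _component_bounds(lo, hi, cv)
        if b - a < 1e-12:  # point mass: plain shifted Gaussian
            mid = 0.5 * (a + b)
            lp = -0.5 * (z - mid) ** 2 - _LOG_SQRT_2PI
        else:
            lp = _log_interval_mass(z - b, z - a) - math.log(b - a)
        comp_logs.append(math.log(w) + lp)
    stacked = np.stack(comp_logs, axis=0)
    # logsumexp over components; guard the all -inf column
    mx = np.max(stacked, axis=0)
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(divide="ignore"):
        out = safe_mx + np.log(np.sum(np.exp(stacked - safe_mx), axis=0))
    return np.where(np.isfinite(mx), out, -np.inf)


def trisomy_density(z, ff: FetalFractionPrior, cv_percent: float) -> np.ndarray | float:
    """Marginal density of the Z-score under the trisomic model.

    For a fixed fetal fraction this is the unit-variance normal density
    centred at :func:`expected_z`; for uniform and mixture priors the fetal
    fraction is integrated out in closed form (see module docstring).
    """
    arr = _check_z(z)
    cv = _check_cv(cv_percent)
    out = np.exp(_log_trisomy_density(arr, ff, cv))
    return float(out) if out.ndim == 0 else out


def _log_lr(z: np.ndarray, ff: FetalFractionPrior, cv: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    log_eu = -0.5 * z * z - _LOG_SQRT_2PI
    return _log_trisomy_density(z, ff, cv) - log_eu


def likelihood_ratio(z, ff: FetalFractionPrior, cv_percent: float) -> np.ndarray | float:
    """Density ratio trisomic / euploid at the observed Z-score.

    Computed in log space; for a fixed fetal fraction it equals
    ``exp(z_exp * z - z_exp**2 / 2)`` exactly.
    """
    arr = _check_z(z)
    cv = _check_cv(cv_percent)
    out = np.exp(_log_lr(arr, ff, cv))
    return float(out) if out.ndim == 0 else out


def format_ppr_percent(ppr: float) -> str:
    """Clinician-facing rendering of a posterior probability.

    Integer percent in 1-99; below 1% the string degrades to ``<1`` and then
    ``<0.1``; values that would round to 100% are capped at ``99.9`` — a
    positive screen is never reported as certainty.
    """
    pct = 100.0 * ppr
    if pct < 0.1:
        return "<0.1"
    if pct < 1.0:
        return "<1"
    rounded = int(math.floor(pct + 0.5))
    if rounded >= 100:
        return "99.9"
    return str(rounded)


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior risk together with the quantities that produced it."""

    likelihood_diploid: float
    likelihood_trisomy: float
    likelihood_ratio: float
    ppr: float
    prior: float
    display_percent: str = field(default="")

    def __post_init__(self) -> None:
        if not self.display_percent:
            object.__setattr__(self, "display_percent", format_ppr_percent(self.ppr))


def posterior_ppr(prior, z, ff: FetalFractionPrior, cv_percent: float) -> np.ndarray | float:
    """Vectorised posterior probability (Bayes odds update), no wrapper object.

    Works in log-odds space so extreme likelihood ratios saturate cleanly at
    0 or 1 instead of overflowing.
    """
    p = np.asarray(prior, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise DegeneratePriorError("prior probability must lie strictly in (0, 1)")
    arr = _check_z(z)
    cv = _check_cv(cv_percent)
    logit_post = np.log(p) - np.log1p(-p) + _log_lr(arr, ff, cv)
    out = expit(logit_post)
    return float(out) if out.ndim == 0 else out


def posterior_risk(prior: float, z: float, ff: FetalFractionPrior, cv_percent: float) -> PosteriorResult:
    """Full posterior update for one sample.

    Parameters
    ----------
    prior
        Pre-test trisomy probability, strictly inside (0, 1).
    z
        Observed Z-score.
    ff
        Prior on the fetal DNA percentage.
    cv_percent
        Control-group coefficient of variation in percent.

    Returns
    -------
    PosteriorResult
        Likelihoods, likelihood ratio, raw posterior and display string.
    """
    p = float(prior)
    if not (0.0 < p < 1.0):
        raise DegeneratePriorError(f"prior probability must lie strictly in (0, 1), got {p!r}")
    lik_eu = euploid_density(z)
    lik_tri = trisomy_density(z, ff, cv_percent)
    lr = likelihood_ratio(z, ff, cv_percent)
    ppr = posterior_ppr(p, z, ff, cv_percent)
    return PosteriorResult(
        likelihood_diploid=lik_eu,
        likelihood_trisomy=lik_tri,
        likelihood_ratio=lr,
        ppr=ppr,
        prior=p,
    )


def sensitivity(f_percent: float, cv_percent: float, z_threshold: float = 3.0) -> float:
    """Probability that a trisomic sample exceeds the call threshold.

    ``Phi(z_exp - z_threshold)`` with ``z_exp = (f/2)/CV``: e.g. 99.87% at
    6% fetal DNA with CV 0.5 and threshold 3, dropping to 84.13% at 4%.
    """
    if not (z_threshold > 0):
        raise InvalidParameterError(f"z_threshold must be > 0, got {z_threshold!r}")
    return float(ndtr(expected_z(f_percent, cv_percent) - z_threshold))


def required_cv(
    f_percent: float, target_sensitivity: float, z_threshold: float = 3.0
) -> float:
    """Coefficient of variation needed to reach a target sensitivity.

    Inverts the sensitivity formula: ``CV = (f/2) / (z_threshold +
    Phi^-1(target))``.  Targets at or below 0.5 would require the trisomic
    mean not to exceed the threshold and are rejected as unreachable.
    """
    f = _check_ff(f_percent)
    t = float(target_sensitivity)
    if not (0.5 < t < 1.0):
        raise InvalidParameterError(
            f"target sensitivity must lie in (0.5, 1), got {t!r}"
        )
    if not (z_threshold > 0):
        raise InvalidParameterError(f"z_threshold must be > 0, got {z_threshold!r}")
    return (f / 2.0) / (z_threshold + float(ndtri(t)))


def euploid_central_coverage(z_bound: float) -> float:
    """Fraction of diploid samples with |Z| <= z_bound: ``2 Phi(z_bound) - 1``."""
    zb = float(z_bound)
    if not (zb >= 0):
        raise InvalidParameterError(f"z_bound must be >= 0, got {z_bound!r}")
    return float(2.0 * ndtr(zb) - 1.0)
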