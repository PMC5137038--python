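"""Synthetic NIPT cohorts: the sampling dual of the scoring model.

Each simulated pregnancy is euploid or trisomic with a given prevalence.
Every row draws a fetal DNA percentage from a :class:`FetalFractionPrior`;
euploid rows then draw ``z ~ N(0, 1)`` and trisomic rows
``z ~ N((f/2)/CV, 1)``.  Because the generator and the scorer share the
model exactly, two properties follow and serve as validation: the empirical
detection rate at threshold ``t`` equals ``Phi(z_exp - t)``, and the
posterior computed with prior = prevalence is calibrated (among samples
scored at posterior q, a fraction q are truly trisomic).

Only the Z-score abstraction is simulated — no read counts, GC bias or
sequencing error.

RNG policy: one ``numpy`` generator per cohort, seeded explicitly, drawing
in a fixed order (status, then component index, then fetal fraction, then
z-noise) so cohorts are reproducible at the stream level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import FetalFractionPrior, TrisomyTarget, posterior_ppr
from .errors import ContractError, InvalidParameterError

__all__ = ["SimulatedCohort", "simulate_cohort", "calibration_check"]


@dataclass(frozen=True)
class SimulatedCohort:
    """Cohort table plus the parameters that generated it.

    ``table`` columns: sample_id, true_status ("euploid"/"trisomic"),
    f_percent, z.  The generating prevalence, CV, fetal-fraction prior and
    seed are stored so any downstream check can reproduce the setup.
    """

    table: pd.DataFrame
    prevalence: float
    cv_percent: float
    ff: FetalFractionPrior
    seed: int
    target: TrisomyTarget = TrisomyTarget.T21

    def as_sample_table(self) -> pd.DataFrame:
        """Batch-scorer input format, with prevalence as the shared prior."""
        return pd.DataFrame(
            {
                "sample_id": self.table["sample_id"],
                "chrom": int(self.target),
                "z": self.table["z"],
                "cv_percent": self.cv_percent,
                "prior": repr(self.prevalence),
            }
        )


def _sample_ff(ff: FetalFractionPrior, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for _, _, w in ff.components])
    lows = np.array([lo for lo, _, _ in ff.components])
    highs = np.array([hi for _, hi, _ in ff.components])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    u = rng.random(n)
    return lows[comp] + u * (highs[comp] - lows[comp])


def simulate_cohort(
    n: int,
    prevalence: float,
    ff: FetalFractionPrior,
    cv_percent: float,
    seed: int,
    target: TrisomyTarget | int = 21,
) -> SimulatedCohort:
    """Draw a cohort of ``n`` pregnancies under the two-Gaussian model."""
    if n < 1:
        raise InvalidParameterError(f"cohort size must be >= 1, got {n}")
    if not (0.0 < prevalence < 1.0):
        raise InvalidParameterError(f"prevalence must lie in (0, 1), got {prevalence!r}")
    cv = float(cv_percent)
    rng = np.random.default_rng(seed)
    trisomic = rng.random(n) < prevalence
    f = _sample_ff(ff, n, rng)
    z = rng.standard_normal(n) + np.where(trisomic, (f / 2.0) / cv, 0.0)
    table = pd.DataFrame(
        {
            "sample_id": [f"sim{i:06d}" for i in range(n)],
            "true_status": np.where(trisomic, "trisomic", "euploid"),
            "f_percent": f,
            "z": z,
        }
    )
    return SimulatedCohort(table, float(prevalence), cv, ff, int(seed), TrisomyTarget.parse(target))


def calibration_check(
    cohort: SimulatedCohort,
    n_bins: int = 10,
    prior: float | None = None,
    allow_mismatch: bool = False,
) -> pd.DataFrame:
    """Bin samples by posterior and compare mean posterior to observed truth.

    Scores every sample with ``prior`` (default: the cohort's generating
    prevalence) and the cohort's own fetal-fraction prior and CV, bins the
    posteriors into ``n_bins`` equal-width bins on [0, 1], and reports per
    bin the count, mean posterior, observed trisomy frequency, the binomial
    standard error sqrt(q(1-q)/n) at q = mean posterior, and a status:
    ``ok`` if |observed - mean| <= 3 SE, ``deviates`` otherwise, ``no_data``
    for empty bins.

    Calibration is only guaranteed when scorer and generator match; passing
    a ``prior`` different from the generating prevalence raises
    :class:`ContractError` unless ``allow_mismatch=True`` (the deliberate
    negative control).
    """
    if n_bins < 1:
        raise InvalidParameterError(f"n_bins must be >= 1, got {n_bins}")
    p = cohort.prevalence if prior is None else float(prior)
    if p != cohort.prevalence and not allow_mismatch:
        raise ContractError(
            f"scorer prior {p} != generating prevalence {cohort.prevalence}; "
            "pass allow_mismatch=True for a deliberate miscalibration check"
        )
    ppr = np.asarray(
        posterior_ppr(p, cohort.table["z"].to_numpy(), cohort.ff, cohort.cv_percent)
    )
    truth = (cohort.table["true_status"] == "trisomic").to_numpy()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(ppr, edges[1:-1]), 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        mask = which == b
        n_in = int(mask.sum())
        if n_in == 0:
            rows.append(
                {
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "n": 0,
                    "mean_ppr": np.nan,
                    "observed_rate": np.nan,
                    "se": np.nan,
                    "status": "no_data",
                }
            )
            continue
        q = float(ppr[mask].mean())
        obs = float(truth[mask].mean())
        se = float(np.sqrt(max(q * (1.0 - q), 0.0) / n_in))
        status = "ok" if abs(obs - q) <= 3.0 * se else "deviates"
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": n_in,
                "mean_ppr": q,
                "observed_rate": obs,
                "se": se,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
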