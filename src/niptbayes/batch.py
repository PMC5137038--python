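"""Batch scoring of sample tables and PPR grid generation.

A sample table (TSV or CSV) has one row per NIPT result with columns

    sample_id  chrom  z  [cv_percent]  [prior]  [maternal_age]
    [gestational_age]  [ff]  [ff_low]  [ff_high]

Exactly one prior pathway must be present per row: either a ``prior`` string
(decimal or odds notation), or ``maternal_age`` + ``gestational_age`` looked
up in a risk table.  Missing ``cv_percent`` or fetal-fraction columns fall
back to the configured defaults with a logged warning.  Rows failing
validation are collected into an error report, never silently dropped, and
row order is preserved.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import Settings
from .engine import FetalFractionPrior, TrisomyTarget, posterior_risk
from .errors import NiptBayesError, SchemaError
from .priors import PriorRisk, RiskTable, interpolate_risk, parse_prior

log = logging.getLogger("niptbayes")

__all__ = ["SampleRecord", "BatchResult", "read_sample_table", "run_batch", "generate_grid"]

REQUIRED_COLUMNS = ("sample_id", "chrom", "z")
OPTIONAL_COLUMNS = (
    "cv_percent",
    "prior",
    "maternal_age",
    "gestational_age",
    "ff",
    "ff_low",
    "ff_high",
)


@dataclass(frozen=True)
class SampleRecord:
    """One validated input row, with the effective settings resolved."""

    sample_id: str
    target: TrisomyTarget
    z: float
    cv_percent: float
    prior: PriorRisk
    ff: FetalFractionPrior


@dataclass
class BatchResult:
    """Scored rows plus the per-row error report."""

    results: pd.DataFrame
    errors: list[tuple[int, str, str]]  # (row index, sample_id, message)

    @property
    def ok(self) -> bool:
        return not self.errors


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def read_sample_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV sample table; delimiter is sniffed unless given."""
    path = Path(path)
    if sep is None:
        sample = path.read_text()[:4096]
        try:
            sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
        except csv.Error:
            sep = "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "prior": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"sample table {path} is missing required columns {missing}; "
            f"required: {list(REQUIRED_COLUMNS)}, optional: {list(OPTIONAL_COLUMNS)}"
        )
    return df


def _resolve_row(
    row: pd.Series, settings: Settings, risk_table: RiskTable | None
) -> SampleRecord:
    target = TrisomyTarget.parse(row["chrom"])
    z = float(row["z"])

    has_prior = not _is_missing(row.get("prior"))
    has_age = not _is_missing(row.get("maternal_age")) and not _is_missing(
        row.get("gestational_age")
    )
    if has_prior and has_age:
        raise SchemaError("give either a prior or maternal+gestational age, not both")
    if has_prior:
        prior = parse_prior(str(row["prior"]))
    elif has_age:
        if risk_table is None:
            raise SchemaError("age-based prior requested but no risk table supplied")
        prior = interpolate_risk(
            risk_table, float(row["maternal_age"]), float(row["gestational_age"])
        )
    else:
        raise SchemaError("no prior pathway: need a prior string or maternal+gestational age")

    if _is_missing(row.get("cv_percent")):
        cv = settings.cv_for(target)
        log.warning("sample %s: no CV given, using default %.2f%%", row["sample_id"], cv)
    else:
        cv = float(row["cv_percent"])

    has_fixed = not _is_missing(row.get("ff"))
    has_low = not _is_missing(row.get("ff_low"))
    has_high = not _is_missing(row.get("ff_high"))
    if has_fixed:
        ff = FetalFractionPrior.fixed(float(row["ff"]))
    elif has_low and has_high:
        ff = FetalFractionPrior.uniform(float(row["ff_low"]), float(row["ff_high"]))
    elif has_low or has_high:
        raise SchemaError("fetal-fraction range needs both ff_low and ff_high")
    else:
        ff = settings.fetal_fraction
        log.warning(
            "sample %s: no fetal fraction given, using default %s",
            row["sample_id"],
            ff.describe(),
        )
    return SampleRecord(str(row["sample_id"]), target, z, cv, prior, ff)


def run_batch(
    samples: pd.DataFrame,
    settings: Settings | None = None,
    risk_table: RiskTable | None = None,
) -> BatchResult:
    """Score every row of a sample table.

    Each output row echoes the effective CV and fetal-fraction prior used so
    results are auditable; rows failing validation appear in ``errors`` with
    their original index and are absent from ``results``.
    """
    settings = settings or Settings()
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table is missing required columns {missing}")
    log.info("scoring %d samples with %s", len(samples), settings.describe())

    out_rows = []
    errors: list[tuple[int, str, str]] = []
    for idx, row in samples.iterrows():
        sid = str(row.get("sample_id", idx))
        try:
            rec = _resolve_row(row, settings, risk_table)
            res = posterior_risk(rec.prior.probability, rec.z, rec.ff, rec.cv_percent)
        except (NiptBayesError, ValueError, TypeError) as exc:
            errors.append((idx, sid, str(exc)))
            continue
        out_rows.append(
            {
                "sample_id": rec.sample_id,
                "chrom": int(rec.target),
                "z": rec.z,
                "prior_probability": rec.prior.probability,
                "prior_source": rec.prior.source,
                "cv_percent": rec.cv_percent,
                "ff_prior": rec.ff.describe(),
                "likelihood_ratio": res.likelihood_ratio,
                "ppr": res.ppr,
                "ppr_display": res.display_percent,
            }
        )
    return BatchResult(results=pd.DataFrame(out_rows), errors=errors)


def generate_grid(
    priors: Sequence[float],
    z_values: Sequence[float],
    ff: FetalFractionPrior,
    cv_percent: float,
) -> pd.DataFrame:
    """Long-format PPR table over a prior x Z-score grid.

    Returns columns (prior, z, ppr, ppr_display); deterministic, one row per
    grid point in row-major (prior-outer) order.
    """
    if len(priors) == 0 or len(z_values) == 0:
        raise SchemaError("grid axes must be non-empty")
    rows = []
    for p in priors:
        for z in z_values:
            res = posterior_risk(float(p), float(z), ff, cv_percent)
            rows.append(
                {
                    "prior": float(p),
                    "z": float(z),
                    "ppr": res.ppr,
                    "ppr_display": res.display_percent,
                }
            )
    return pd.DataFrame(rows)


def plot_grid(grid: pd.DataFrame, path: str | Path) -> None:
    """Line plot of PPR (%) vs Z, one curve per prior; written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p, sub in grid.groupby("prior"):
        ax.plot(sub["z"], 100.0 * sub["ppr"], marker="o", label=f"prior {p:g}")
    ax.set_xlabel("Z-score")
    ax.set_ylabel("posterior risk (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
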