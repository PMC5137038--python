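"""Pre-test (a priori) trisomy risk: odds parsing and risk-table lookup.

Clinical priors arrive in three ways: directly as a probability (from a
first-trimester combined test, FCT, or a previous affected pregnancy),
as odds notation ("1:200", "1/4"), or from population risk tables indexed
by maternal age and gestational age.  "1:n" and "1/n" are both read as a
risk of 1 in n, i.e. probability 1/n — the notations are used
interchangeably in clinical reporting (e.g. "1:1000 (0.001)").

No clinical risk table is bundled: published tables are licensed works.
:func:`synthetic_risk_table` builds a clearly-synthetic grid with the same
schema for tests and demonstrations, and :meth:`RiskTable.from_csv` loads a
user-supplied table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .engine import TrisomyTarget
from .errors import InvalidParameterError, PriorParseError, TableRangeError

__all__ = [
    "PriorRisk",
    "RiskTable",
    "parse_prior",
    "format_prior",
    "interpolate_risk",
    "synthetic_risk_table",
]

_ODDS_RE = re.compile(r"^\s*1\s*[:/]\s*(\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class PriorRisk:
    """A pre-test trisomy probability with its provenance.

    ``source`` records where the number came from: ``direct`` (decimal
    probability), ``odds_notation`` ("1:n"/"1/n" string), ``fct``
    (first-trimester combined test) or ``age_table`` (interpolated).
    ``notation`` keeps the original string when one was parsed.
    """

    probability: float
    source: str = "direct"
    notation: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.probability < 1.0):
            raise InvalidParameterError(
                f"prior probability must lie strictly in (0, 1), got {self.probability!r}"
            )
        if self.source not in {"direct", "odds_notation", "fct", "age_table"}:
            raise InvalidParameterError(f"unknown prior source {self.source!r}")


def parse_prior(text: str, source: str | None = None) -> PriorRisk:
    """Parse a prior from decimal ("0.001") or odds ("1:1000", "1/4") notation.

    Both odds forms map to probability 1/n; n must be at least 2 so the
    probability stays below 1.  Raises :class:`PriorParseError` naming the
    offending token otherwise.
    """
    if not isinstance(text, str) or not text.strip():
        raise PriorParseError(f"empty or non-string prior {text!r}")
    token = text.strip()
    m = _ODDS_RE.match(token)
    if m:
        n = float(m.group(1))
        if n < 2:
            raise PriorParseError(f"odds {token!r}: denominator must be >= 2")
        return PriorRisk(1.0 / n, source=source or "odds_notation", notation=token)
    try:
        p = float(token)
    except ValueError:
        raise PriorParseError(
            f"cannot parse prior {token!r}: expected a decimal probability or '1:n'/'1/n'"
        ) from None
    if not (0.0 < p < 1.0):
        raise PriorParseError(f"prior {token!r} is outside (0, 1)")
    return PriorRisk(p, source=source or "direct", notation=None)


def format_prior(prior: PriorRisk) -> str:
    """Inverse of :func:`parse_prior`: original notation if present, else decimal."""
    if prior.notation is not None:
        return prior.notation
    return repr(prior.probability)


@dataclass(frozen=True)
class RiskTable:
    """Maternal-age x gestational-age grid of trisomy risks.

    Axes are strictly ascending; ``risks[i, j]`` is the probability at
    ``maternal_ages[i]`` years and ``gestational_ages[j]`` weeks.
    """

    trisomy: TrisomyTarget
    maternal_ages: tuple[float, ...]
    gestational_ages: tuple[float, ...]
    risks: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.maternal_ages, dtype=float)
        weeks = np.asarray(self.gestational_ages, dtype=float)
        grid = np.asarray(self.risks, dtype=float)
        if grid.shape != (ages.size, weeks.size):
            raise InvalidParameterError(
                f"risk grid shape {grid.shape} does not match axes "
                f"({ages.size} ages x {weeks.size} weeks)"
            )
        for name, axis in (("maternal_ages", ages), ("gestational_ages", weeks)):
            if axis.size < 2 or np.any(np.diff(axis) <= 0):
                raise InvalidParameterError(f"{name} must be strictly ascending, length >= 2")
        if np.any(grid <= 0) or np.any(grid >= 1):
            raise InvalidParameterError("all table risks must lie strictly in (0, 1)")
        object.__setattr__(self, "risks", grid)

    @classmethod
    def from_csv(cls, path: str | Path, trisomy: TrisomyTarget | int = 21) -> "RiskTable":
        """Load a table: first row gestational weeks, first column maternal
        ages, cells decimal probabilities or "1:n" strings."""
        df = pd.read_csv(path, index_col=0)
        weeks = [float(c) for c in df.columns]
        ages = [float(i) for i in df.index]
        grid = np.empty(df.shape, dtype=float)
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                cell = df.iat[i, j]
                grid[i, j] = (
                    parse_prior(cell).probability if isinstance(cell, str) else float(cell)
                )
        return cls(TrisomyTarget.parse(trisomy), tuple(ages), tuple(weeks), grid)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.risks,
            index=pd.Index(self.maternal_ages, name="maternal_age"),
            columns=[f"{w:g}" for w in self.gestational_ages],
        )
        df.to_csv(path)


def interpolate_risk(
    table: RiskTable, maternal_age: float, gestational_age: float
) -> PriorRisk:
    """Bilinear interpolation of the risk grid at (age, week).

    Exact at grid nodes and linear along rows and columns.  Queries outside
    the table hull raise :class:`TableRangeError` — no extrapolation, since
    an extrapolated clinical prior would be unsafe.
    """
    interp = RegularGridInterpolator(
        (np.asarray(table.maternal_ages), np.asarray(table.gestational_ages)),
        table.risks,
        method="linear",
        bounds_error=True,
    )
    try:
        value = float(interp([[float(maternal_age), float(gestational_age)]])[0])
    except ValueError:
        raise TableRangeError(
            f"query (age {maternal_age}, week {gestational_age}) is outside the "
            f"table range ages [{table.maternal_ages[0]}, {table.maternal_ages[-1]}], "
            f"weeks [{table.gestational_ages[0]}, {table.gestational_ages[-1]}]"
        ) from None
    return PriorRisk(value, source="age_table")


def synthetic_risk_table(
    trisomy: TrisomyTarget | int = 21,
    maternal_ages: Sequence[float] = tuple(range(20, 46)),
    gestational_ages: Sequence[float] = tuple(range(10, 21)),
) -> RiskTable:
    """A SYNTHETIC risk table for tests and demos — not clinical data.

    Shaped like the published tables (risk rises steeply with maternal age
    and falls slightly with gestation as affected pregnancies miscarry) but
    the numbers are invented:

        risk(age, week) = 1 / (30 + 12 * (45 - age) + 8 * (week - 10))

    which spans roughly 1:30 (age 45, week 10) to 1:410 (age 20, week 20).
    """
    ages = np.asarray(maternal_ages, dtype=float)
    weeks = np.asarray(gestational_ages, dtype=float)
    denom = 30.0 + 12.0 * (45.0 - ages[:, None]) + 8.0 * (weeks[None, :] - 10.0)
    return RiskTable(
        TrisomyTarget.parse(trisomy), tuple(ages), tuple(weeks), 1.0 / denom
    )
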