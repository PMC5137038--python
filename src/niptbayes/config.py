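"""Runtime settings: per-chromosome CV defaults, fetal-fraction prior, cutoff.

Precedence is CLI flags > config file > built-ins.  The config file is flat
YAML or JSON:

    cv_default:
      "13": 0.4
      "18": 0.4
      "21": 0.5
    z_threshold: 3.0
    fetal_fraction:
      components:        # [low %, high %, weight]
        - [1, 23, 0.4]
        - [6, 18, 0.6]
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import FetalFractionPrior, TrisomyTarget
from .errors import InvalidParameterError

log = logging.getLogger("niptbayes")

# Recommended assay CVs (percent): chromosome 21 sees fewer reads than 13/18.
BUILTIN_CV_DEFAULTS = {TrisomyTarget.T13: 0.4, TrisomyTarget.T18: 0.4, TrisomyTarget.T21: 0.5}


@dataclass(frozen=True)
class Settings:
    cv_defaults: dict = field(default_factory=lambda: dict(BUILTIN_CV_DEFAULTS))
    fetal_fraction: FetalFractionPrior = field(default_factory=FetalFractionPrior.default)
    z_threshold: float = 3.0

    def cv_for(self, target: TrisomyTarget) -> float:
        return self.cv_defaults[TrisomyTarget.parse(target)]

    def describe(self) -> str:
        cvs = ", ".join(f"chr{int(k)}={v:g}" for k, v in sorted(self.cv_defaults.items()))
        return (
            f"CV defaults ({cvs}) %; fetal fraction {self.fetal_fraction.describe()}; "
            f"call threshold Z={self.z_threshold:g}"
        )


def load_config(path: str | Path | None) -> Settings:
    """Build Settings from a YAML/JSON file layered over the built-ins."""
    if path is None:
        return Settings()
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"config {path} must be a mapping, got {type(raw).__name__}")

    cv = dict(BUILTIN_CV_DEFAULTS)
    for key, value in (raw.get("cv_default") or {}).items():
        cv[TrisomyTarget.parse(key)] = float(value)

    ff = FetalFractionPrior.default()
    ff_raw = raw.get("fetal_fraction")
    if ff_raw:
        if "fixed" in ff_raw:
            ff = FetalFractionPrior.fixed(float(ff_raw["fixed"]))
        elif "components" in ff_raw:
            comps = [(float(a), float(b), float(w)) for a, b, w in ff_raw["components"]]
            ff = FetalFractionPrior.mixture(comps)
        else:
            raise InvalidParameterError(
                "fetal_fraction config needs 'fixed' or 'components'"
            )

    settings = Settings(
        cv_defaults=cv,
        fetal_fraction=ff,
        z_threshold=float(raw.get("z_threshold", 3.0)),
    )
    log.info("loaded config %s: %s", path, settings.describe())
    return settings
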