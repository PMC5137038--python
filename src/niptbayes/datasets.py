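"""Small built-in datasets.

:func:`validation_samples` returns the 14 positive-call samples (Z > 3) from
a published clinical evaluation cohort of 209 NIPT pregnancies, as printed
in the source report: sample id, target chromosome, FCT prior in odds
notation, per-run coefficient of variation, and observed Z-score.  Samples
1-13 concern chromosome 21; sample 14 is a chromosome-13 call.  These rows
exercise the batch scorer end to end: the ten samples with Z > 6 must all
report the capped display risk "99.9".
"""

from __future__ import annotations

import pandas as pd

__all__ = ["validation_samples"]

_ROWS = [
    # sample_id, chrom, prior (odds), cv_percent, z
    ("1", 21, "1/4", 0.40, 13.7),
    ("2", 21, "1/2", 0.29, 27.2),
    ("3", 21, "1/79", 0.31, 12.4),
    ("4", 21, "1/118", 0.40, 11.6),
    ("5", 21, "1/141", 0.33, 14.4),
    ("6", 21, "1/119", 0.47, 11.9),
    ("7", 21, "1/13", 0.32, 19.7),
    ("8", 21, "1/20", 0.36, 16.9),
    ("9", 21, "1/115", 0.29, 26.2),
    ("10", 21, "1/25", 0.33, 28.8),
    ("11", 21, "1/43", 0.33, 4.9),
    ("12", 21, "1/147", 0.34, 4.4),
    ("13", 21, "1/80", 0.32, 4.2),
    ("14", 13, "1:5000", 0.18, 4.4),
]


def validation_samples() -> pd.DataFrame:
    """Positive-call samples (Z > 3) of the published evaluation cohort."""
    return pd.DataFrame(
        _ROWS, columns=["sample_id", "chrom", "prior", "cv_percent", "z"]
    )
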