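import numpy as np
import pytest
from scipy.stats import norm

from niptbayes import FetalFractionPrior


@pytest.fixture
def fixed4():
    return FetalFractionPrior.fixed(4.0)


@pytest.fixture
def default_mixture():
    return FetalFractionPrior.default()


def trapezoid_density_oracle(z, ff, cv_percent, nodes=100_001):
    """Independent brute-force marginal density: fine-grid trapezoid over f.

    Averages the shifted unit-normal density over each uniform component on
    a dense fetal-fraction grid.  Deliberately naive — it shares no code
    with the closed-form implementation it cross-checks.
    """
    total = 0.0
    for lo, hi, w in ff.components:
        if hi == lo:
            total += w * norm.pdf(z - (lo / 2.0) / cv_percent)
            continue
        f = np.linspace(lo, hi, nodes)
        vals = norm.pdf(z - (f / 2.0) / cv_percent)
        total += w * np.trapezoid(vals, f) / (hi - lo)
    return total
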