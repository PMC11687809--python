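import pytest

from geomgof import FrequencyTable

# Summary rows for the four packaged market run-length datasets (total runs,
# mean length, theta_hat, 95% CI, W2, A2 at 3-decimal rounding, and the
# p-value bracket of each statistic between tabulated levels).  The W2
# bracket for "ipc" follows the tabulated alpha=0.50 point near theta=0.476
# (~0.057), which 0.091 exceeds.
MARKET_EXPECTED = {
    "nasdaq": dict(n=1032, mean=1.952, theta=0.512, ci=(0.490, 0.534),
                   w2=0.060, a2=0.314, w2_bracket=(0.25, 0.50), a2_bracket=(0.50, 1.0)),
    "djia": dict(n=1019, mean=1.976, theta=0.506, ci=(0.484, 0.528),
                 w2=0.027, a2=0.181, w2_bracket=(0.50, 1.0), a2_bracket=(0.50, 1.0)),
    "nikkei225": dict(n=993, mean=1.965, theta=0.509, ci=(0.487, 0.531),
                      w2=0.022, a2=0.206, w2_bracket=(0.50, 1.0), a2_bracket=(0.50, 1.0)),
    "ipc": dict(n=958, mean=2.101, theta=0.476, ci=(0.454, 0.498),
                w2=0.091, a2=0.638, w2_bracket=(0.25, 0.50), a2_bracket=(0.15, 0.25)),
}


@pytest.fixture
def toy_table() -> FrequencyTable:
    """The hand-computed sample {1, 1, 2, 4}: mean 2, theta_hat 0.5."""
    return FrequencyTable.from_counts({1: 2, 2: 1, 4: 1})
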