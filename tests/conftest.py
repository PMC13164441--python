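import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive and separate from
# the package implementations they check)


def naive_binning(values, edges):
    """Per-value loop binning with half-open bins, last bin closed."""
    counts = [0] * (len(edges) - 1)
    for v in values:
        v = min(max(v, edges[0]), edges[-1])
        for i in range(len(edges) - 1):
            last = i == len(edges) - 2
            if edges[i] <= v < edges[i + 1] or (last and v == edges[-1]):
                counts[i] += 1
                break
    return counts


def naive_sd(x):
    n = len(x)
    m = sum(x) / n
    return (sum((v - m) ** 2 for v in x) / (n - 1)) ** 0.5


def naive_skew_g1(x):
    n = len(x)
    m = sum(x) / n
    m2 = sum((v - m) ** 2 for v in x) / n
    m3 = sum((v - m) ** 3 for v in x) / n
    g1 = m3 / m2**1.5
    return g1 * (n * (n - 1)) ** 0.5 / (n - 2)


def naive_kurt_g2(x):
    n = len(x)
    m = sum(x) / n
    m2 = sum((v - m) ** 2 for v in x) / n
    m4 = sum((v - m) ** 4 for v in x) / n
    g2 = m4 / m2**2 - 3.0
    return ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))


def naive_pooled_t(x, y):
    import math

    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def naive_anova_f(groups):
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    return (ssb / df1) / (ssw / df2)


def discretized_gaussian_entropy_bits(sigma, mu=0.0, lo=-40.0, hi=60.0, n_bins=100):
    """Numeric entropy of the exactly discretized Gaussian pmf (oracle)."""
    from scipy.special import ndtr

    edges = np.linspace(lo, hi, n_bins + 1)
    cdf = ndtr((edges - mu) / sigma)
    p = np.diff(cdf)
    p[0] += cdf[0]
    p[-1] += 1 - cdf[-1]
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
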