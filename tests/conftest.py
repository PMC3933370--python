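import numpy as np
import pytest

from lungsound.signal_io import LungSoundSignal
from lungsound.synthetic_data import GeneratorConfig, generate_normal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_signal():
    """1 s of a 0.5-amplitude 300 Hz tone at 8 kHz."""
    t = np.arange(8000) / 8000.0
    return LungSoundSignal(0.5 * np.sin(2 * np.pi * 300 * t), 8000.0)


@pytest.fixture
def normal_recording():
    """One deterministic synthetic healthy recording (clean lung sound)."""
    return generate_normal(GeneratorConfig(seed=7, n_cycles=3, mix_ratio_ls=1.0))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def moment_oracle(x):
    """Direct-summation population moments: (mean, sd, skew, excess kurt)."""
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    sd = m2**0.5
    return mu, sd, m3 / sd**3, m4 / m2**2 - 3.0


def lacunarity_oracle(x, l, transform=abs):
    """Exhaustive gliding-box enumeration of M2/M1^2."""
    masses = []
    for start in range(len(x) - l + 1):
        masses.append(sum(transform(v) for v in x[start : start + l]))
    n_boxes = len(masses)
    m1 = sum(masses) / n_boxes
    m2 = sum(m * m for m in masses) / n_boxes
    return m2 / m1**2


def sample_entropy_oracle(x, m, r_abs):
    """O(N^2) double-loop template count, self-matches excluded."""
    import math

    n = len(x)
    counts = []
    for dim in (m, m + 1):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(dim)) <= r_abs:
                    c += 1
        counts.append(c)
    b, a = counts
    if b == 0 or a == 0:
        raise ValueError("no matches")
    return -math.log(a / b)


def band_power(x, rate_hz, lo_hz, hi_hz):
    """Periodogram power in [lo, hi] Hz."""
    from scipy.signal import periodogram

    f, p = periodogram(x, rate_hz)
    sel = (f >= lo_hz) & (f <= hi_hz)
    return float(np.sum(p[sel]))


def cohens_d(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return (a.mean() - b.mean()) / pooled
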