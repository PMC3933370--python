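"""Morphological complexity features of respiratory cycles.

Four statistics summarise the amplitude morphology of one breathing
cycle:

* **excess kurtosis** (chi) — tailedness of the amplitude distribution,
  ``m4/sigma**4 - 3`` with population moments;
* **skewness** (xi) — asymmetry, ``m3/sigma**3``;
* **lacunarity** (zeta) — texture/heterogeneity of the rectified
  waveform, the ratio ``M2/M1**2`` of the second moment of gliding-box
  masses to the squared first moment. A homogeneous series gives 1; gappy
  or bursty series (crackles!) give larger values;
* **sample entropy** (alpha) — irregularity, the negative log conditional
  probability that template vectors matching for ``m`` points (Chebyshev
  distance within tolerance ``r``, self-matches excluded) still match at
  ``m + 1``.

Abnormal lung sounds carry adventitious components (crackles, wheezes,
squawks) that make the waveform more heterogeneous and irregular, so
lacunarity and sample entropy run higher than in normal breath sounds;
kurtosis and skewness capture the heavier, more asymmetric amplitude
distribution. Feature set 1 is (chi, xi), set 2 adds zeta, set 3 adds
alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .cycle_segmentation import RespiratoryCycle
from .signal_io import LungSoundSignal

__all__ = [
    "FeatureVector",
    "LacunarityConfig",
    "LacunarityProfile",
    "SampEnConfig",
    "excess_kurtosis",
    "skewness",
    "lacunarity",
    "lacunarity_profile",
    "sample_entropy",
    "cycle_sample_entropy",
    "extract_features",
    "FEATURE_SETS",
]

logger = logging.getLogger(__name__)

#: Feature-set definitions: which fields each classifier input uses.
FEATURE_SETS = {
    "set1": ("kurtosis_chi", "skewness_xi"),
    "set2": ("kurtosis_chi", "skewness_xi", "lacunarity_zeta"),
    "set3": ("kurtosis_chi", "skewness_xi", "lacunarity_zeta", "sample_entropy_alpha"),
}

#: Per-cycle sample entropy is averaged over contiguous windows of this
#: length at the native rate (the template count grows quadratically with
#: window length), over at most SAMPEN_MAX_WINDOWS windows evenly spaced
#: across the cycle.
SAMPEN_WINDOW_SAMPLES = 1500
SAMPEN_MAX_WINDOWS = 4


@dataclass(frozen=True)
class FeatureVector:
    """Per-cycle morphological features; unset fields are None."""

    cycle_id: str
    label: str = "unknown"
    kurtosis_chi: float | None = None
    skewness_xi: float | None = None
    lacunarity_zeta: float | None = None
    sample_entropy_alpha: float | None = None
    feature_set: str = "set3"
    source: str = ""
    start_sample: int = -1
    end_sample: int = -1

    def values(self) -> np.ndarray:
        """The populated dimensions, in the order chi, xi, zeta, alpha."""
        fields = FEATURE_SETS[self.feature_set]
        return np.array([getattr(self, f) for f in fields], dtype=np.float64)


@dataclass(frozen=True)
class LacunarityConfig:
    """Gliding-box settings.

    ``box_lengths`` default (None) means a dyadic sweep 2, 4, 8, ... up to
    L/4; ``mass_transform`` makes the signed acoustic samples nonnegative
    before box masses are formed.
    """

    box_lengths: tuple | None = None
    mass_transform: str = "abs"

    def resolve_lengths(self, series_length: int) -> tuple:
        if self.box_lengths is not None:
            lengths = tuple(int(l) for l in self.box_lengths)
        else:
            # dyadic sweep up to L/4, capped at 256 samples (32 ms at 8 kHz,
            # the scale of adventitious events); longer boxes mostly measure
            # the breathing-cycle AM shared by both classes
            cap = min(max(series_length // 4, 2), 256)
            lengths, l = [], 2
            while l <= cap and l < series_length:
                lengths.append(l)
                l *= 2
            lengths = tuple(lengths) or (1,)
        for l in lengths:
            if not 1 <= l < series_length:
                raise ValueError(
                    f"box length {l} invalid for series of length {series_length}"
                )
        return lengths


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy settings: embedding dimension and tolerance.

    ``r`` is a multiple of the series standard deviation unless
    ``r_is_absolute`` is set.
    """

    m: int = 2
    r: float = 0.2
    r_is_absolute: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not self.r > 0:
            raise ValueError("tolerance r must be positive")


def _moments(x: np.ndarray, min_len: int):
    x = np.asarray(x, dtype=np.float64)
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {x.size}")
    mu = x.mean()
    dev = x - mu
    var = np.mean(dev**2)
    if var <= 0:
        raise ValueError("degenerate distribution: zero variance")
    return dev, var


def excess_kurtosis(x) -> float:
    """Fourth standardised moment minus 3 (population normalisation)."""
    dev, var = _moments(x, 4)
    return float(np.mean(dev**4) / var**2 - 3.0)


def skewness(x) -> float:
    """Third standardised moment (population normalisation)."""
    dev, var = _moments(x, 3)
    return float(np.mean(dev**3) / var**1.5)


# ---------------------------------------------------------------------------
# Lacunarity (gliding-box)
# ---------------------------------------------------------------------------


def _box_masses(x: np.ndarray, l: int, mass_transform: str) -> np.ndarray:
    if mass_transform == "abs":
        mass = np.abs(x)
    elif mass_transform == "square":
        mass = x**2
    else:
        raise ValueError(f"unknown mass_transform {mass_transform!r}")
    # moving sum over all L - l + 1 stride-1 windows
    csum = np.concatenate(([0.0], np.cumsum(mass)))
    return csum[l:] - csum[:-l]


def lacunarity(x, l: int, config: LacunarityConfig = LacunarityConfig()) -> float:
    """Gliding-box lacunarity at a single box length ``l``.

    Box masses are sums of the mass-transformed samples over every
    stride-1 window of length ``l``; the return value is
    ``mean(b**2) / mean(b)**2`` over the ``L - l + 1`` boxes. Always
    >= 1 by Jensen's inequality; equals 1 iff all box masses coincide.
    """
    x = np.asarray(x, dtype=np.float64)
    if not 1 <= l < x.size:
        raise ValueError(f"box length must satisfy 1 <= l < L={x.size}, got {l}")
    b = _box_masses(x, int(l), config.mass_transform)
    m1 = b.mean()
    if m1 <= 0:
        raise ValueError("undefined lacunarity: all box masses are zero")
    return float(np.mean(b**2) / m1**2)


@dataclass(frozen=True)
class LacunarityProfile:
    """Lacunarity across box lengths plus its scalar summary.

    The summary is the geometric mean of zeta(l) over the sweep — a
    scale-balanced single number for the classifier; the full profile is
    retained for inspection.
    """

    box_lengths: tuple
    values: tuple
    summary: float


def lacunarity_profile(
    x, config: LacunarityConfig = LacunarityConfig()
) -> LacunarityProfile:
    """Lacunarity over a sweep of box lengths, summarised geometrically."""
    x = np.asarray(x, dtype=np.float64)
    lengths = config.resolve_lengths(x.size)
    values = tuple(lacunarity(x, l, config) for l in lengths)
    summary = float(np.exp(np.mean(np.log(values))))
    return LacunarityProfile(box_lengths=lengths, values=values, summary=summary)


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------


def sample_entropy(x, config: SampEnConfig = SampEnConfig()) -> float:
    """Sample entropy ``-ln(A/B)`` with Chebyshev template matching.

    ``B`` counts ordered template pairs (i != j) of length ``m`` whose
    Chebyshev distance is within the tolerance; ``A`` the same at
    ``m + 1``. Templates are restricted to the first ``N - m`` start
    points so both dimensions use the same template count.
    """
    x = np.asarray(x, dtype=np.float64)
    m = config.m
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {n}")
    if config.r_is_absolute:
        r_abs = config.r
    else:
        sd = x.std()
        if sd <= 0:
            raise ValueError("zero standard deviation: relative tolerance undefined")
        r_abs = config.r * sd

    def _count(dim: int) -> int:
        # templates U_dim(j), j = 0 .. n - m - 1 (same count for m and m+1)
        n_templates = n - m
        emb = np.lib.stride_tricks.sliding_window_view(x, dim)[:n_templates]
        dists = cdist(emb, emb, metric="chebyshev")
        within = dists <= r_abs
        np.fill_diagonal(within, False)
        return int(within.sum())

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        raise ValueError(
            f"SampEn undefined (no matches): B={b}, A={a} at m={m}, r={r_abs:g}"
        )
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# Per-cycle extraction
# ---------------------------------------------------------------------------


def cycle_sample_entropy(
    x: np.ndarray,
    config: SampEnConfig = SampEnConfig(),
    window_samples: int = SAMPEN_WINDOW_SAMPLES,
    max_windows: int = SAMPEN_MAX_WINDOWS,
) -> float:
    """Sample entropy of a cycle, averaged over native-rate windows.

    Long cycles are not resampled (that would low-pass away the breath
    band); instead SampEn is computed on up to ``max_windows`` contiguous
    windows of ``window_samples`` evenly spaced across the cycle and the
    values are averaged. Windows where SampEn is undefined (no template
    matches) are skipped; if every window is undefined the error
    propagates.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= window_samples:
        return sample_entropy(x, config)
    n_windows = min(max_windows, x.size // window_samples)
    starts = np.linspace(0, x.size - window_samples, n_windows).astype(int)
    values, last_error = [], None
    for s in starts:
        try:
            values.append(sample_entropy(x[s : s + window_samples], config))
        except ValueError as exc:
            last_error = exc
    if not values:
        raise ValueError(f"SampEn undefined in every window: {last_error}")
    return float(np.mean(values))


def extract_features(
    signal: LungSoundSignal,
    cycles,
    feature_set: str = "set3",
    lacunarity_config: LacunarityConfig = LacunarityConfig(),
    sampen_config: SampEnConfig = SampEnConfig(),
    source: str = "",
) -> list[FeatureVector]:
    """One :class:`FeatureVector` per respiratory cycle.

    Fields outside the requested set are left unset; cycles with a
    degenerate (zero-variance) waveform are skipped with a warning rather
    than failing the whole recording. Sample entropy of long cycles is
    computed by :func:`cycle_sample_entropy` (windowed, native rate).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {tuple(FEATURE_SETS)}")
    if not cycles:
        raise ValueError("cycles must be non-empty")
    wanted = FEATURE_SETS[feature_set]
    out: list[FeatureVector] = []
    for k, cycle in enumerate(cycles):
        if cycle.end_sample > len(signal):
            raise ValueError(f"cycle {k} extends past the end of the signal")
        x = cycle.extract(signal)
        try:
            fields: dict = {}
            fields["kurtosis_chi"] = excess_kurtosis(x)
            fields["skewness_xi"] = skewness(x)
            if "lacunarity_zeta" in wanted:
                fields["lacunarity_zeta"] = lacunarity_profile(
                    x, lacunarity_config
                ).summary
            if "sample_entropy_alpha" in wanted:
                fields["sample_entropy_alpha"] = cycle_sample_entropy(
                    x, sampen_config
                )
        except ValueError as exc:
            logger.warning("skipping cycle %d: %s", k, exc)
            continue
        out.append(
            FeatureVector(
                cycle_id=f"{source or 'signal'}:{k}",
                label=signal.label,
                feature_set=feature_set,
                source=source,
                start_sample=cycle.start_sample,
                end_sample=cycle.end_sample,
                **fields,
            )
        )
    return out
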