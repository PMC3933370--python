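"""Signal enhancement: baseline-disturbance and heart-sound removal.

Two stages clean a raw auscultation recording before feature extraction:

1. **First-order differentiation** suppresses slowly varying instrumental
   disturbances (DC offset, baseline drift) by replacing the signal with
   its discrete first difference.

2. **Heart-sound removal by empirical mode decomposition (EMD).** Chest
   recordings mix lung sound (broadband, roughly 150-900 Hz) with heart
   sound (S1/S2 valve bursts, mostly below ~150 Hz). EMD splits the signal
   into intrinsic mode functions (IMFs) ordered fast to slow; IMFs whose
   spectral centroid falls below a cutoff are attributed to the cardiac
   component and discarded, and the lung sound is reconstructed from the
   remainder.

The sifting procedure here is the classic cubic-spline EMD with a
Cauchy-type stopping criterion and mirror extension of edge extrema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

from .signal_io import LungSoundSignal

__all__ = [
    "EMDResult",
    "HeartSoundSeparation",
    "first_difference",
    "emd_decompose",
    "remove_heart_sound",
    "spectral_centroid",
]

logger = logging.getLogger(__name__)

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_IMFS = 12
DEFAULT_MAX_SIFT_ITERS = 10
DEFAULT_HS_CUTOFF_HZ = 150.0


def first_difference(signal: LungSoundSignal) -> LungSoundSignal:
    """Discrete first derivative, ``out[n] = x[n+1] - x[n]``.

    The output is one sample shorter than the input; rate and label are
    preserved. Removes constant offsets exactly and attenuates slow
    baseline drift relative to the audio band.
    """
    if len(signal) < 2:
        raise ValueError("first_difference needs at least 2 samples")
    return signal.with_samples(np.diff(signal.samples))


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EMDResult:
    """Decomposition of a signal into IMFs plus a residual trend.

    ``sum(imfs) + residue`` reproduces the input exactly (each IMF is
    subtracted from the running residue, so the identity holds to floating
    point).
    """

    imfs: list  # of ndarray, fastest oscillation first
    residue: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray):
    """Indices of strict-or-plateau local maxima and minima of x."""
    # collapse exact plateaus so argrelextrema sees strict changes
    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    # drop plateau runs: keep the first index of consecutive runs
    def _dedupe(idx):
        if idx.size == 0:
            return idx
        keep = np.concatenate(([True], np.diff(idx) > 1))
        return idx[keep]

    maxima = _dedupe(maxima[(maxima > 0) & (maxima < x.size - 1)])
    minima = _dedupe(minima[(minima > 0) & (minima < x.size - 1)])
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n_mirror: int = 2):
    """Cubic-spline envelope through x[idx], mirror-extending extrema.

    Mirroring ``n_mirror`` extrema about each end suppresses the spline's
    end swings without inventing data.
    """
    n = x.size
    t = idx.astype(np.float64)
    v = x[idx]
    k = min(n_mirror, idx.size)
    left_t = 2 * 0.0 - t[1 : k + 1][::-1] if idx.size > 1 else np.array([-1.0])
    left_v = v[1 : k + 1][::-1] if idx.size > 1 else v[:1]
    right_t = 2 * (n - 1.0) - t[-k - 1 : -1][::-1] if idx.size > 1 else np.array([float(n)])
    right_v = v[-k - 1 : -1][::-1] if idx.size > 1 else v[-1:]
    # anchor the ends if the first/last extremum is interior
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    keep = np.concatenate(([True], np.diff(tt) > 0))
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n, dtype=np.float64))


def _is_imf(h: np.ndarray) -> bool:
    """Extrema count and zero-crossing count differ by at most one."""
    maxima, minima = _local_extrema(h)
    n_ext = maxima.size + minima.size
    signs = np.sign(h)
    signs = signs[signs != 0]
    n_zc = int(np.count_nonzero(np.diff(signs)))
    return abs(n_ext - n_zc) <= 1


def emd_decompose(
    signal: LungSoundSignal,
    max_imfs: int = DEFAULT_MAX_IMFS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
) -> EMDResult:
    """Decompose a signal into intrinsic mode functions by sifting.

    Each IMF is extracted by repeatedly subtracting the mean of the
    cubic-spline upper and lower extrema envelopes. Sifting for one IMF
    stops when the Cauchy-type criterion
    ``sum((h_prev - h)**2) / sum(h_prev**2) < sd_threshold`` is met and the
    mode property (extrema and zero crossings differing by at most one)
    holds, or after ``max_sift_iters`` iterations. Decomposition stops at
    ``max_imfs`` or when the residue has fewer than 2 interior extrema.
    """
    x = signal.samples
    if x.size < 8:
        raise ValueError("emd_decompose needs at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    if max_imfs < 1:
        raise ValueError("max_imfs must be positive")
    if not sd_threshold > 0:
        raise ValueError("sd_threshold must be positive")

    imfs: list[np.ndarray] = []
    residue = x.astype(np.float64).copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residue)
        if maxima.size + minima.size < 2 or maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        for _ in range(max_sift_iters):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _mirrored_envelope(h, maxima)
            lower = _mirrored_envelope(h, minima)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold and _is_imf(h):
                break
        imfs.append(h)
        residue = residue - h
    return EMDResult(imfs=imfs, residue=residue)


# ---------------------------------------------------------------------------
# Heart-sound removal
# ---------------------------------------------------------------------------


def spectral_centroid(x: np.ndarray, rate_hz: float) -> float:
    """Power-weighted mean frequency of ``x`` in Hz (DC bin excluded)."""
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate_hz)
    power = spectrum[1:]
    total = float(np.sum(power))
    if total <= 0:
        return 0.0
    return float(np.sum(freqs[1:] * power) / total)


@dataclass(frozen=True)
class HeartSoundSeparation:
    """Result of EMD-based heart-sound suppression.

    ``signal`` is the reconstructed lung sound (IMFs whose spectral
    centroid is at or above the cutoff); ``heart_component`` collects the
    low-centroid IMFs plus the residue trend, kept for inspection.
    """

    signal: LungSoundSignal
    heart_component: LungSoundSignal
    imf_centroids_hz: tuple
    kept_imfs: tuple  # indices of IMFs attributed to the lung sound


def remove_heart_sound(
    signal: LungSoundSignal,
    cutoff_hz: float = DEFAULT_HS_CUTOFF_HZ,
    **emd_kwargs,
) -> HeartSoundSeparation:
    """Suppress cardiac interference by selective IMF reconstruction.

    The signal is decomposed by :func:`emd_decompose`; IMFs whose spectral
    centroid is at least ``cutoff_hz`` are summed into the cleaned lung
    sound, while the remaining IMFs and the residue form the heart-sound /
    trend estimate. If the decomposition yields a single IMF there is
    nothing separable: the input is returned unchanged with a warning.
    """
    if not cutoff_hz > 0:
        raise ValueError("cutoff_hz must be positive")
    result = emd_decompose(signal, **emd_kwargs)
    rate = signal.sampling_rate_hz
    centroids = tuple(spectral_centroid(imf, rate) for imf in result.imfs)

    if result.n_imfs <= 1:
        logger.warning(
            "EMD produced %d IMF(s); nothing separable, returning input unchanged",
            result.n_imfs,
        )
        zero = signal.with_samples(np.zeros_like(signal.samples))
        return HeartSoundSeparation(
            signal=signal,
            heart_component=zero,
            imf_centroids_hz=centroids,
            kept_imfs=tuple(range(result.n_imfs)),
        )

    kept = tuple(i for i, c in enumerate(centroids) if c >= cutoff_hz)
    lung = np.zeros_like(signal.samples)
    heart = result.residue.copy()
    for i, imf in enumerate(result.imfs):
        if i in kept:
            lung += imf
        else:
            heart += imf
    return HeartSoundSeparation(
        signal=signal.with_samples(lung),
        heart_component=signal.with_samples(heart),
        imf_centroids_hz=centroids,
        kept_imfs=kept,
    )
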