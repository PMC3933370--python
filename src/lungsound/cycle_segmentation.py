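"""Respiratory-cycle detection from the smoothed Hilbert envelope.

Breathing modulates the amplitude of the lung sound: each inspiration and
expiration raises the acoustic envelope and the envelope dips at phase
boundaries. The detector therefore

1. computes the instantaneous amplitude (Hilbert envelope) of the signal,
2. low-pass filters it (default 5 Hz, zero phase) so only the breathing
   modulation remains,
3. locates envelope minima via a sign change of the discrete first
   derivative — these are the phase transition points t_p, and
4. pairs consecutive inter-minima phases into complete respiratory cycles
   (one inspiration plus one expiration) with duration C^d.

Which phase of a cycle is inspiration cannot be told from the envelope
alone, so cycles are reported phase-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import (
    butter,
    filtfilt,
    firwin,
    hilbert,
    peak_prominences,
    sosfiltfilt,
)

from .signal_io import LungSoundSignal

__all__ = [
    "EnvelopeTrace",
    "RespiratoryCycle",
    "hilbert_envelope",
    "smooth_envelope",
    "find_transition_points",
    "assemble_cycles",
    "segment_cycles",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_CUTOFF_HZ = 5.0
DEFAULT_MIN_PHASE_S = 0.3
DEFAULT_MIN_PROMINENCE_FRAC = 0.2


@dataclass(frozen=True)
class EnvelopeTrace:
    """Raw and smoothed amplitude envelopes of a recording."""

    raw_envelope: np.ndarray
    sampling_rate_hz: float
    smoothed_envelope: np.ndarray | None = None


@dataclass(frozen=True)
class RespiratoryCycle:
    """One inspiration+expiration span, as a half-open sample interval.

    ``transition_points`` holds the envelope minima interior to the cycle
    (the boundary between its two phases).
    """

    start_sample: int
    end_sample: int
    transition_points: tuple
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("cycle must have end_sample > start_sample")

    @property
    def duration_s(self) -> float:
        return (self.end_sample - self.start_sample) / self.sampling_rate_hz

    def extract(self, signal: LungSoundSignal) -> np.ndarray:
        return signal.samples[self.start_sample : self.end_sample]


def hilbert_envelope(signal: LungSoundSignal) -> EnvelopeTrace:
    """Magnitude of the analytic signal, ``sqrt(y**2 + H{y}**2)``.

    Uses the frequency-domain analytic-signal construction; the envelope
    bounds ``|y|`` pointwise up to numeric tolerance.
    """
    analytic = hilbert(signal.samples)
    return EnvelopeTrace(
        raw_envelope=np.abs(analytic), sampling_rate_hz=signal.sampling_rate_hz
    )


def smooth_envelope(
    trace: EnvelopeTrace,
    cutoff_hz: float = DEFAULT_SMOOTH_CUTOFF_HZ,
    filter_kind: str = "iir_butterworth",
    order: int = 4,
) -> EnvelopeTrace:
    """Zero-phase low-pass of the raw envelope.

    The default is an order-4 Butterworth applied forward-backward, which
    has exactly zero group delay — essential because the minima of the
    smoothed envelope are read off as phase boundaries. A linear-phase
    windowed-sinc FIR with matched -3 dB point is available as
    ``filter_kind="fir_sinc"`` (also applied forward-backward).
    """
    nyquist = trace.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff_hz must lie in (0, Nyquist={nyquist:g}), got {cutoff_hz}"
        )
    x = trace.raw_envelope
    if filter_kind == "iir_butterworth":
        sos = butter(order, cutoff_hz / nyquist, btype="low", output="sos")
        smoothed = sosfiltfilt(sos, x)
    elif filter_kind == "fir_sinc":
        numtaps = int(4 * trace.sampling_rate_hz / cutoff_hz) | 1
        b = firwin(numtaps, cutoff_hz / nyquist)
        padlen = min(3 * numtaps, x.size - 1)
        smoothed = filtfilt(b, np.array([1.0]), x, padlen=padlen)
    else:
        raise ValueError(f"unknown filter_kind {filter_kind!r}")
    return EnvelopeTrace(
        raw_envelope=x,
        smoothed_envelope=smoothed,
        sampling_rate_hz=trace.sampling_rate_hz,
    )


def find_transition_points(
    trace: EnvelopeTrace,
    min_phase_s: float = DEFAULT_MIN_PHASE_S,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    include_edges: bool = True,
) -> np.ndarray:
    """Breathing-phase transition points: minima of the smoothed envelope.

    A minimum is an index where the discrete first derivative changes sign
    from non-positive to positive; ties are broken toward the earlier
    index. Two guards reject minima caused by residual envelope ripple
    rather than a phase boundary: candidates whose dip prominence is less
    than ``min_prominence_frac`` of the envelope's global range are
    dropped, and surviving candidates closer than ``min_phase_s`` are
    merged keeping the deeper one. With ``include_edges`` the first/last
    sample counts as a transition point when the envelope rises away from
    it (falls into it), so a recording that starts or ends at a phase
    boundary keeps that boundary.
    """
    if trace.smoothed_envelope is None:
        raise ValueError("smoothed envelope not computed; call smooth_envelope first")
    env = trace.smoothed_envelope
    rate = trace.sampling_rate_hz
    d = np.diff(env)
    # sign change (<= 0) -> (> 0) at position t: d[t-1] <= 0 < d[t]
    idx = np.nonzero((d[:-1] <= 0) & (d[1:] > 0))[0] + 1
    # ties toward the earlier index: walk left over a flat/zero-derivative run
    adjusted = []
    for t in idx:
        while t > 0 and d[t - 1] == 0:
            t -= 1
        adjusted.append(t)
    candidates = list(dict.fromkeys(adjusted))
    # robust envelope range: crackle spikes and near-zero filter edges make
    # the raw min/max unrepresentative of the breathing modulation
    lo, hi = np.percentile(env, [5.0, 95.0])
    span = float(hi - lo)
    if min_prominence_frac > 0 and candidates and span > 0:
        threshold = min_prominence_frac * span
        prominences = peak_prominences(-env, candidates)[0]
        candidates = [
            t for t, p in zip(candidates, prominences) if p >= threshold
        ]
    if include_edges:
        # an edge counts as a boundary when it sits in an envelope trough
        # (derivative sign at a single edge sample is numerically fragile)
        trough = lo + 0.4 * span
        if env[0] <= trough and (not candidates or candidates[0] != 0):
            candidates.insert(0, 0)
        last = env.size - 1
        if env[last] <= trough and (not candidates or candidates[-1] != last):
            candidates.append(last)

    # merge minima closer than min_phase_s, keeping the deeper one
    min_gap = int(round(min_phase_s * rate))
    merged: list[int] = []
    for t in candidates:
        if merged and t - merged[-1] < min_gap:
            if env[t] < env[merged[-1]]:
                merged[-1] = t
        else:
            merged.append(t)

    if len(merged) < 2:
        raise ValueError("no complete phase detectable (fewer than 2 envelope minima)")
    return np.asarray(merged, dtype=np.int64)


def assemble_cycles(
    transition_points,
    signal_length: int,
    rate: float,
) -> list[RespiratoryCycle]:
    """Pair consecutive inter-minima phases into respiratory cycles.

    Consecutive minima delimit phases; consecutive phase pairs form cycles
    ``[t_0, t_2), [t_2, t_4), ...`` each recording its interior transition
    point. A trailing unpaired phase is dropped and logged.
    """
    points = np.asarray(transition_points, dtype=np.int64)
    if points.size < 3:
        raise ValueError("need at least 3 transition points (two phases = one cycle)")
    if np.any(np.diff(points) <= 0):
        raise ValueError("transition points must be strictly increasing")
    if points[0] < 0 or points[-1] > signal_length:
        raise ValueError("transition points outside the signal")

    cycles = []
    n_phases = points.size - 1
    for k in range(0, n_phases - 1, 2):
        cycles.append(
            RespiratoryCycle(
                start_sample=int(points[k]),
                end_sample=int(points[k + 2]),
                transition_points=(int(points[k + 1]),),
                sampling_rate_hz=rate,
            )
        )
    if n_phases % 2 == 1:
        logger.info(
            "dropping trailing unpaired phase [%d, %d)", points[-2], points[-1]
        )
    return cycles


def segment_cycles(
    signal: LungSoundSignal,
    cutoff_hz: float = DEFAULT_SMOOTH_CUTOFF_HZ,
    min_phase_s: float = DEFAULT_MIN_PHASE_S,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    filter_kind: str = "iir_butterworth",
) -> list[RespiratoryCycle]:
    """Envelope -> smoothing -> minima -> cycles, in one call."""
    trace = smooth_envelope(
        hilbert_envelope(signal), cutoff_hz=cutoff_hz, filter_kind=filter_kind
    )
    points = find_transition_points(
        trace, min_phase_s=min_phase_s, min_prominence_frac=min_prominence_frac
    )
    return assemble_cycles(points, len(signal), signal.sampling_rate_hz)
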