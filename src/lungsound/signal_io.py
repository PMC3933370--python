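"""Reading and writing lung-sound recordings.

Auscultation recordings are stored as 16-bit PCM mono WAV files, the
standard format of single-channel electronic-stethoscope acquisition
systems. The :class:`LungSoundSignal` container carries the samples and
sampling rate through every stage of the pipeline.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["LungSoundSignal", "read_wav", "write_wav"]

#: Recognised class tags for a recording.
LABELS = ("normal", "abnormal", "unknown")


@dataclass(frozen=True)
class LungSoundSignal:
    """A uniformly sampled single-channel acoustic signal.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitudes, nominally within ``[-1, 1]``.
    sampling_rate_hz : float
        Sampling rate in Hz; auscultation recordings default to 8000 Hz.
    label : str, optional
        Class tag, one of ``{"normal", "abnormal", "unknown"}``.
    """

    samples: np.ndarray
    sampling_rate_hz: float = 8000.0
    label: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "LungSoundSignal":
        """A copy carrying new samples but the same rate and label."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def read_wav(path) -> LungSoundSignal:
    """Read a 16-bit PCM mono WAV file into a :class:`LungSoundSignal`.

    Integer PCM samples are scaled to ``[-1, 1]`` by dividing by
    ``2**(bits-1)``; the sampling rate is taken from the file header.

    Raises
    ------
    ValueError
        If the file is multi-channel or not integer PCM.
    """
    path = Path(path)
    with wave.open(str(path), "rb") as wf:
        n_channels = wf.getnchannels()
        if n_channels != 1:
            raise ValueError(
                f"{path.name}: expected mono audio, file has {n_channels} channels"
            )
        comptype = wf.getcomptype()
        if comptype != "NONE":
            raise ValueError(
                f"{path.name}: expected uncompressed PCM, file encoding is {comptype!r}"
            )
        sampwidth = wf.getsampwidth()
        if sampwidth not in (1, 2, 4):
            raise ValueError(
                f"{path.name}: unsupported sample width {sampwidth} bytes"
            )
        rate = wf.getframerate()
        raw = wf.readframes(wf.getnframes())

    if sampwidth == 1:
        # 8-bit WAV is unsigned, offset binary.
        data = np.frombuffer(raw, dtype=np.uint8).astype(np.float64) - 128.0
        scale = 128.0
    else:
        dtype = np.int16 if sampwidth == 2 else np.int32
        data = np.frombuffer(raw, dtype=dtype).astype(np.float64)
        scale = float(2 ** (8 * sampwidth - 1))
    return LungSoundSignal(samples=data / scale, sampling_rate_hz=float(rate))


def write_wav(signal: LungSoundSignal, path, *, clip: bool = False) -> None:
    """Write a signal as a 16-bit PCM mono WAV file.

    Amplitudes are mapped to integers by multiplying by 32768 and rounding
    half away from zero, with the one overflowing code +1.0 -> 32768 clamped
    to 32767. This makes ``read_wav`` followed by ``write_wav`` lossless for
    any 16-bit source and stores 0.0 exactly.

    Parameters
    ----------
    clip : bool
        If True, amplitudes outside ``[-1, 1]`` are clipped; if False
        (default) they raise an error naming the worst offending sample.
    """
    samples = signal.samples
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        if clip:
            samples = np.clip(samples, -1.0, 1.0)
        else:
            worst = int(np.argmax(np.abs(samples)))
            raise ValueError(
                f"amplitude {samples[worst]:+.6f} at sample {worst} exceeds [-1, 1]; "
                "enable clipping or rescale"
            )
    scaled = samples * 32768.0
    # round half away from zero; clamp the single overflowing code at +1.0
    quantized = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    pcm = np.clip(quantized, -32768, 32767).astype(np.int16)
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(int(round(signal.sampling_rate_hz)))
        wf.writeframes(pcm.tobytes())
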