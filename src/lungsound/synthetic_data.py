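"""Seeded generator of synthetic lung-sound recordings with ground truth.

Clinical auscultation recordings are rarely shareable, so the test bed
is synthetic. The generator emulates the statistical structure the
pipeline assumes rather than airway physics:

* **Breath carrier** — Gaussian noise band-passed to the breath band
  (default 150-900 Hz, the range where normal vesicular/bronchial sound
  energy lives), amplitude-modulated by smooth raised-cosine envelopes,
  one per phase, with expiration quieter than inspiration.
* **Crackles** (abnormal) — short exponentially damped sinusoid bursts
  (default 10 ms at 600 Hz) Poisson-placed within inspirations: explosive
  airway-reopening transients that make the waveform bursty and
  heavy-tailed.
* **Wheezes** (abnormal) — continuous musical tones (default 400 Hz,
  >= 0.25 s) appearing with some probability per cycle.
* **Turbulent-flow noise** (abnormal) — envelope-modulated broadband
  noise above the vesicular band (default 500-1500 Hz), the harsher
  stochastic component of obstructed-airway breathing.
* **Heart sounds** — periodic S1/S2 double bursts of low-frequency
  (30-60 Hz) damped oscillation at a ~1 s beat period, mixed at a
  controlled lung-sound energy fraction (e.g. 20% LS + 80% HS).

Every recording carries its ground-truth phase boundaries, class label
and the clean lung/heart components, so segmentation and denoising can
be scored against known truth. Generation is fully deterministic under
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .signal_io import LungSoundSignal

__all__ = [
    "GeneratorConfig",
    "CrackleConfig",
    "WheezeConfig",
    "TurbulenceConfig",
    "HeartConfig",
    "SyntheticRecording",
    "generate_normal",
    "generate_abnormal",
    "generate_heart_sound",
    "mix",
    "generate_dataset",
]


@dataclass(frozen=True)
class CrackleConfig:
    """Damped-sinusoid transient bursts within inspirations.

    The default rate emulates a fine-crackle shower (fibrosis-like), many
    short 600 Hz transients per inspiration.
    """

    rate_per_cycle: float = 15.0  # Poisson mean
    duration_ms: float = 10.0
    center_freq_hz: float = 600.0
    amplitude_ratio: float = 5.0  # peak relative to breath RMS


@dataclass(frozen=True)
class WheezeConfig:
    """Continuous musical tone over part of a cycle."""

    probability_per_cycle: float = 0.3
    freq_hz: float = 400.0
    duration_s: float = 0.6
    amplitude_ratio: float = 0.4  # relative to breath RMS


@dataclass(frozen=True)
class HeartConfig:
    """Periodic S1/S2 cardiac bursts."""

    beat_period_s: float = 1.0
    period_jitter_s: float = 0.05
    s1_freq_hz: float = 35.0
    s2_freq_hz: float = 50.0
    s1_duration_s: float = 0.12
    s2_duration_s: float = 0.08
    s2_delay_s: float = 0.30
    amplitude: float = 1.0


@dataclass(frozen=True)
class TurbulenceConfig:
    """Broadband turbulent-flow noise of obstructed airways.

    Normal vesicular sound concentrates below ~500 Hz; bronchial and
    adventitious breathing adds harsher, higher-frequency stochastic
    content. Only the abnormal generator mixes this in, modulated by the
    same breathing envelope as the carrier.
    """

    band_hz: tuple = (500.0, 1500.0)
    amplitude_ratio: float = 0.15  # relative to breath-carrier RMS


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic recording generator."""

    rate_hz: float = 8000.0
    n_cycles: int = 4
    inspiration_s: float = 1.2
    expiration_s: float = 1.8
    phase_jitter_sd_s: float = 0.1
    breath_band_hz: tuple = (150.0, 450.0)
    expiration_level: float = 0.5  # expiration amplitude relative to inspiration
    envelope_floor: float = 0.25  # residual envelope between phases
    crackle: CrackleConfig = field(default_factory=CrackleConfig)
    wheeze: WheezeConfig = field(default_factory=WheezeConfig)
    turbulence: TurbulenceConfig = field(default_factory=TurbulenceConfig)
    heart: HeartConfig = field(default_factory=HeartConfig)
    mix_ratio_ls: float = 1.0  # fraction of total energy from lung sound
    severity: float = 1.0  # scales crackle rate and wheeze amplitude together
    peak_target: float = 0.9  # post-mix peak normalisation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("rate_hz", "inspiration_s", "expiration_s", "peak_target"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.mix_ratio_ls <= 1.0:
            raise ValueError("mix_ratio_ls must lie in [0, 1]")
        lo, hi = self.breath_band_hz
        if not 0 < lo < hi < self.rate_hz / 2:
            raise ValueError("breath_band_hz must satisfy 0 < low < high < Nyquist")


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated recording plus everything needed to score against it."""

    signal: LungSoundSignal
    true_boundaries: np.ndarray  # phase-transition sample indices, ends included
    true_label: str
    clean_ls: np.ndarray
    clean_hs: np.ndarray
    config: GeneratorConfig


def _phase_timeline(cfg: GeneratorConfig, rng: np.random.Generator):
    """Per-phase durations (with jitter) and boundary sample indices."""
    durations = []
    for _ in range(cfg.n_cycles):
        for mean in (cfg.inspiration_s, cfg.expiration_s):
            d = mean + cfg.phase_jitter_sd_s * rng.standard_normal()
            durations.append(max(d, 0.3 * mean))
    edges_s = np.concatenate(([0.0], np.cumsum(durations)))
    boundaries = np.round(edges_s * cfg.rate_hz).astype(np.int64)
    return durations, boundaries


def _bandpassed_noise(n: int, band, rate_hz: float,
                      rng: np.random.Generator,
                      stabilize_envelope: bool = False) -> np.ndarray:
    lo, hi = band
    nyq = rate_hz / 2.0
    sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    if stabilize_envelope:
        # breath-sound intensity tracks airflow smoothly; raw bandpass noise
        # has large slow envelope fluctuations of its own, so divide them out
        env = np.abs(hilbert(x))
        sos_lp = butter(2, 5.0 / nyq, btype="low", output="sos")
        env = sosfiltfilt(sos_lp, env)
        env = np.maximum(env, 0.5 * np.median(env))
        x = x / env
    return x / np.std(x)


def _breath_envelope(cfg: GeneratorConfig, boundaries: np.ndarray) -> np.ndarray:
    envelope = np.full(int(boundaries[-1]), cfg.envelope_floor)
    for k in range(boundaries.size - 1):
        a, b = int(boundaries[k]), int(boundaries[k + 1])
        level = 1.0 if k % 2 == 0 else cfg.expiration_level
        t = np.arange(b - a)
        envelope[a:b] += level * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / max(b - a - 1, 1)))
    return envelope


def _breath_component(cfg: GeneratorConfig, boundaries: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    carrier = _bandpassed_noise(
        int(boundaries[-1]), cfg.breath_band_hz, cfg.rate_hz, rng,
        stabilize_envelope=True,
    )
    return carrier * _breath_envelope(cfg, boundaries)


def _insert_crackles(x: np.ndarray, cfg: GeneratorConfig, boundaries: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    rate = cfg.crackle.rate_per_cycle * cfg.severity
    dur = int(round(cfg.crackle.duration_ms * 1e-3 * cfg.rate_hz))
    if dur < 4:
        dur = 4
    t = np.arange(dur) / cfg.rate_hz
    tau = (cfg.crackle.duration_ms * 1e-3) / 4.0
    template = np.exp(-t / tau) * np.sin(2 * np.pi * cfg.crackle.center_freq_hz * t)
    breath_rms = float(np.std(x))
    out = x.copy()
    # inspiration phases are the even-numbered ones
    for k in range(0, boundaries.size - 1, 2):
        a, b = int(boundaries[k]), int(boundaries[k + 1])
        n_crackles = rng.poisson(rate)
        for _ in range(n_crackles):
            pos = rng.integers(a, max(b - dur, a + 1))
            amp = cfg.crackle.amplitude_ratio * breath_rms * (0.7 + 0.6 * rng.random())
            out[pos : pos + dur] += amp * template[: max(0, min(dur, out.size - pos))]
    return out


def _insert_wheezes(x: np.ndarray, cfg: GeneratorConfig, boundaries: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    breath_rms = float(np.std(x))
    out = x.copy()
    amp = cfg.wheeze.amplitude_ratio * cfg.severity * breath_rms
    dur = int(round(max(cfg.wheeze.duration_s, 0.25) * cfg.rate_hz))
    for k in range(0, boundaries.size - 1, 2):  # one draw per cycle
        if rng.random() >= cfg.wheeze.probability_per_cycle:
            continue
        a = int(boundaries[k])
        b = int(boundaries[min(k + 2, boundaries.size - 1)])
        if b - a <= dur:
            pos, length = a, b - a
        else:
            pos = int(rng.integers(a, b - dur))
            length = dur
        t = np.arange(length) / cfg.rate_hz
        ramp = np.hanning(max(length, 2))[:length]
        phase = 2 * np.pi * rng.random()
        out[pos : pos + length] += amp * ramp * np.sin(
            2 * np.pi * cfg.wheeze.freq_hz * t + phase
        )
    return out


def _burst(freq_hz: float, duration_s: float, rate_hz: float) -> np.ndarray:
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    tau = duration_s / 3.0
    return np.exp(-t / tau) * np.sin(2 * np.pi * freq_hz * t)


def generate_heart_sound(cfg: GeneratorConfig, n_samples: int | None = None,
                         rng: np.random.Generator | None = None) -> LungSoundSignal:
    """Periodic S1/S2 double bursts over the recording duration."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if n_samples is None:
        total_s = cfg.n_cycles * (cfg.inspiration_s + cfg.expiration_s)
        n_samples = int(round(total_s * cfg.rate_hz))
    h = cfg.heart
    out = np.zeros(n_samples)
    s1 = _burst(h.s1_freq_hz, h.s1_duration_s, cfg.rate_hz)
    s2 = _burst(h.s2_freq_hz, h.s2_duration_s, cfg.rate_hz)
    t = 0.2 * h.beat_period_s  # first beat not at the very edge
    while t * cfg.rate_hz < n_samples:
        for burst, delay in ((s1, 0.0), (s2, h.s2_delay_s)):
            pos = int(round((t + delay) * cfg.rate_hz))
            if pos >= n_samples:
                break
            seg = burst[: n_samples - pos]
            out[pos : pos + seg.size] += h.amplitude * seg
        t += h.beat_period_s + h.period_jitter_s * rng.standard_normal()
    return LungSoundSignal(out, cfg.rate_hz)


def _finalise(ls: np.ndarray, cfg: GeneratorConfig, boundaries: np.ndarray,
              label: str, rng: np.random.Generator) -> SyntheticRecording:
    """Mix the lung component with heart sound at the configured energy ratio."""
    hs = generate_heart_sound(cfg, n_samples=ls.size, rng=rng).samples
    e_ls = float(np.sum(ls**2))
    e_hs = float(np.sum(hs**2))
    if cfg.mix_ratio_ls >= 1.0 or e_hs <= 0:
        ls_scaled, hs_scaled = ls, np.zeros_like(ls)
    elif cfg.mix_ratio_ls <= 0.0:
        ls_scaled, hs_scaled = np.zeros_like(ls), hs
    else:
        # scale HS so that e_ls / (e_ls + e_hs') = mix_ratio_ls
        target_e_hs = e_ls * (1.0 - cfg.mix_ratio_ls) / cfg.mix_ratio_ls
        hs_scaled = hs * np.sqrt(target_e_hs / e_hs)
        ls_scaled = ls
    mixture = ls_scaled + hs_scaled
    peak = float(np.max(np.abs(mixture)))
    if peak > 0:
        g = cfg.peak_target / peak
        mixture, ls_scaled, hs_scaled = mixture * g, ls_scaled * g, hs_scaled * g
    return SyntheticRecording(
        signal=LungSoundSignal(mixture, cfg.rate_hz, label=label),
        true_boundaries=boundaries,
        true_label=label,
        clean_ls=ls_scaled,
        clean_hs=hs_scaled,
        config=cfg,
    )


def generate_normal(cfg: GeneratorConfig) -> SyntheticRecording:
    """Healthy recording: enveloped breath-band noise, no adventitious sounds."""
    rng = np.random.default_rng(cfg.seed)
    _, boundaries = _phase_timeline(cfg, rng)
    ls = _breath_component(cfg, boundaries, rng)
    return _finalise(ls, cfg, boundaries, "normal", rng)


def generate_abnormal(cfg: GeneratorConfig) -> SyntheticRecording:
    """Pathological recording: crackles, wheezes and turbulent-flow noise.

    The breath carrier is built exactly as for the normal class, then
    crackle showers are Poisson-placed within inspirations, wheeze tones
    appear per cycle with the configured probability, and an
    envelope-modulated broadband turbulence component (the harsher noise
    of obstructed airways) is mixed in. With crackle rate 0 and wheeze
    probability 0 there is no pathology to synthesise and the output is
    the normal recording for the same seed, relabelled.
    """
    no_pathology = (
        cfg.crackle.rate_per_cycle * cfg.severity <= 0
        and cfg.wheeze.probability_per_cycle <= 0
    )
    if no_pathology:
        rec = generate_normal(cfg)
        return replace(
            rec,
            true_label="abnormal",
            signal=LungSoundSignal(
                rec.signal.samples, rec.signal.sampling_rate_hz, "abnormal"
            ),
        )
    rng = np.random.default_rng(cfg.seed)
    _, boundaries = _phase_timeline(cfg, rng)
    ls = _breath_component(cfg, boundaries, rng)
    carrier_rms = float(np.std(ls))
    if cfg.crackle.rate_per_cycle * cfg.severity > 0:
        ls = _insert_crackles(ls, cfg, boundaries, rng)
    if cfg.wheeze.probability_per_cycle > 0:
        ls = _insert_wheezes(ls, cfg, boundaries, rng)
    if cfg.turbulence.amplitude_ratio > 0:
        turb = _bandpassed_noise(ls.size, cfg.turbulence.band_hz, cfg.rate_hz, rng)
        ls = ls + (
            cfg.turbulence.amplitude_ratio
            * carrier_rms
            * turb
            * _breath_envelope(cfg, boundaries)
        )
    return _finalise(ls, cfg, boundaries, "abnormal", rng)


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> list[SyntheticRecording]:
    """A cohort of recordings, one sub-seed per subject.

    Sub-seeds are drawn from a master generator so the whole cohort is
    reproducible from ``seed`` while every recording is a distinct
    realisation. Normal subjects come first.
    """
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_normal + n_abnormal)
    out = []
    for i in range(n_normal):
        out.append(generate_normal(replace(config, seed=int(sub_seeds[i]))))
    for i in range(n_abnormal):
        out.append(
            generate_abnormal(replace(config, seed=int(sub_seeds[n_normal + i])))
        )
    return out


def mix(recording: SyntheticRecording, mix_ratio_ls: float) -> SyntheticRecording:
    """Re-mix a recording's clean components at a new LS energy fraction."""
    cfg = replace(recording.config, mix_ratio_ls=mix_ratio_ls)
    rng = np.random.default_rng(cfg.seed)
    # reproduce the recording's own lung component at unit mix, then re-mix
    _, boundaries = _phase_timeline(cfg, rng)
    e_ls = float(np.sum(recording.clean_ls**2))
    ls = recording.clean_ls.copy()
    if e_ls <= 0:
        raise ValueError("cannot re-mix a recording with an all-zero lung component")
    return _finalise(ls, cfg, recording.true_boundaries, recording.true_label, rng)
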