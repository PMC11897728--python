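"""Synthetic EEG and behavioral data with known injected structure.

The generator emulates the acquisition and effect structure the analysis
pipeline is built for: 32-channel 10-20 EEG at 512 Hz, trials epoched from
-8 s to +18 s around the onset of a divergent-thinking (alternate uses)
trial, three emotion-induction conditions (neutral / happy / sad), a pink
1/f^beta broadband background, condition-dependent narrowband oscillations,
fronto-parietal phase-amplitude coupling with a configurable modulation
depth, and a participant x condition behavioral table of arousal, pleasure
and originality ratings on a 1-5 scale.

Every effect is injected explicitly, so downstream stages can be tested
against ground truth: an oscillation spec raises band power only in its
channels and time window; a coupling spec modulates the envelope of a fast
oscillation on the amplitude channels as ``a(t) = A0 * (1 + m * cos(phi(t)))``
where ``phi`` is the instantaneous phase of a slow carrier added to the
phase channels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert, welch

from .io import EpochedDataset
from .montage import CLUSTERS, DEFAULT_32

CONDITIONS = ("neutral", "happy", "sad")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _resolve_channels(spec_channels, layout: Sequence[str]) -> list[str]:
    """Accept a cluster name ('LF') or an explicit list of channel labels."""
    if isinstance(spec_channels, str):
        if spec_channels not in CLUSTERS:
            raise ConfigurationError(f"unknown cluster name {spec_channels!r}")
        names = list(CLUSTERS[spec_channels])
    else:
        names = list(spec_channels)
    missing = [ch for ch in names if ch not in layout]
    if missing:
        raise ConfigurationError(f"channels {missing} not in channel layout")
    return names


@dataclasses.dataclass
class OscillationSpec:
    """A narrowband oscillation injected into a channel set and time window."""

    channels: object  # cluster name or list of labels
    freq: float  # Hz
    amplitude: float  # µV
    time_window: tuple[float, float]  # s, relative to trial onset
    condition: str | None = None  # None = all conditions


@dataclasses.dataclass
class CouplingSpec:
    """A directed fronto-parietal phase-amplitude coupling.

    A slow carrier at ``phase_freq`` is added to the phase channels; a fast
    oscillation at ``amp_freq`` whose envelope follows the carrier phase with
    modulation depth ``m`` is added to the amplitude channels.
    """

    phase_channels: object
    amp_channels: object
    phase_freq: float  # Hz
    amp_freq: float  # Hz
    modulation_depth: float  # m in [0, 1]
    condition: str | None = None
    time_window: tuple[float, float] = (0.0, 10.0)
    carrier_amp: float = 5.0  # µV
    base_amp: float = 2.0  # µV, A0 of the fast oscillation

    def __post_init__(self):
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ConfigurationError("modulation depth m must lie in [0, 1]")
        if self.phase_freq >= self.amp_freq:
            raise ConfigurationError("phase_freq must be below amp_freq")


@dataclasses.dataclass
class SimulationConfig:
    n_participants: int = 26
    n_trials_per_condition: int = 15
    sampling_rate: float = 512.0
    epoch_window: tuple[float, float] = (-8.0, 18.0)
    channel_layout: list[str] = dataclasses.field(default_factory=lambda: list(DEFAULT_32))
    noise_exponent: float = 1.0  # beta of the 1/f^beta background
    noise_scale: float = 10.0  # µV broadband standard deviation per channel
    shared_noise_scale: float = 0.0  # optional common source across channels
    oscillation_specs: list[OscillationSpec] = dataclasses.field(default_factory=list)
    coupling_specs: list[CouplingSpec] = dataclasses.field(default_factory=list)
    behavior_means: dict = dataclasses.field(default_factory=lambda: {
        # per-condition (arousal, pleasure, originality) means on the 1-5 scale
        "neutral": {"arousal": 2.4, "pleasure": 3.0, "originality": 2.6},
        "happy": {"arousal": 3.4, "pleasure": 4.2, "originality": 3.1},
        "sad": {"arousal": 3.1, "pleasure": 1.9, "originality": 3.0},
    })
    subject_sd: float = 0.45  # between-participant intercept SD of ratings
    behavior_sd: float = 0.32  # residual rating noise SD
    conditions: tuple = CONDITIONS
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigurationError("need at least 2 participants")
        t0, t1 = self.epoch_window
        if not (t0 <= -3.0 and t1 >= 10.0):
            raise ConfigurationError(
                "epoch window must contain the baseline [-3, 0] s and task [0, 10] s"
            )
        for spec in self.oscillation_specs:
            _resolve_channels(spec.channels, self.channel_layout)
        for spec in self.coupling_specs:
            _resolve_channels(spec.phase_channels, self.channel_layout)
            _resolve_channels(spec.amp_channels, self.channel_layout)

    @classmethod
    def study_default(cls, **overrides) -> "SimulationConfig":
        """The default study conditions: condition-specific band-power
        changes and fronto-parietal couplings mirroring the qualitative
        effect structure the pipeline is meant to detect.

        Happy: broad gamma enhancement 2-4 s after trial onset, strongest on
        the left, plus left theta->low-gamma fronto-parietal coupling. Sad:
        sustained left-frontal slow power increase and a cross-hemisphere
        theta->high-gamma coupling. All conditions share a weaker
        contralateral RF(alpha)->LP(low gamma) coupling.
        """
        oscillations = [
            OscillationSpec("LF", 40.0, 2.5, (2.0, 4.0), "happy"),
            OscillationSpec("LP", 40.0, 2.5, (2.0, 4.0), "happy"),
            OscillationSpec("RF", 40.0, 1.5, (2.0, 4.0), "happy"),
            OscillationSpec("RP", 40.0, 1.5, (2.0, 4.0), "happy"),
            OscillationSpec("LF", 40.0, 1.2, (2.0, 4.0), "neutral"),
            OscillationSpec("RF", 40.0, 1.2, (2.0, 4.0), "neutral"),
            OscillationSpec("LF", 5.0, 3.0, (0.0, 10.0), "sad"),
            OscillationSpec("LF", 10.0, 2.0, (0.0, 10.0), "sad"),
        ]
        couplings = [
            CouplingSpec("LF", "LP", 5.0, 40.0, 0.8, "happy"),
            CouplingSpec("LF", "RP", 5.0, 60.0, 0.5, "sad"),
            CouplingSpec("RF", "LP", 10.0, 40.0, 0.4, None),
        ]
        params = dict(oscillation_specs=oscillations, coupling_specs=couplings)
        params.update(overrides)
        return cls(**params)


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
               sampling_rate: float, exponent: float, scale: float) -> np.ndarray:
    """1/f^beta noise via spectral synthesis, std ``scale`` per series.

    ``shape`` indexes independent series; the returned array has shape
    ``shape + (n_samples,)``.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    real = rng.standard_normal(shape + (len(freqs),))
    imag = rng.standard_normal(shape + (len(freqs),))
    real *= amp
    imag *= amp
    spectrum = np.empty(real.shape, dtype=np.complex128)
    spectrum.real = real
    spectrum.imag = imag
    series = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    std = series.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return series / std * scale


def _taper(times: np.ndarray, window: tuple[float, float], ramp: float = 0.05) -> np.ndarray:
    """Unit-amplitude mask over ``window`` with cosine on/off ramps (s)."""
    t0, t1 = window
    mask = np.zeros_like(times)
    inside = (times >= t0) & (times < t1)
    mask[inside] = 1.0
    up = inside & (times < t0 + ramp)
    mask[up] = 0.5 * (1 - np.cos(np.pi * (times[up] - t0) / ramp))
    down = inside & (times >= t1 - ramp)
    mask[down] = 0.5 * (1 - np.cos(np.pi * (t1 - times[down]) / ramp))
    return mask


def inject_pac(carrier: np.ndarray, amp_freq: float, m: float, base_amp: float,
               sampling_rate: float) -> np.ndarray:
    """Fast oscillation whose envelope follows the carrier's phase.

    Returns ``base_amp * (1 + m * cos(phi(t))) * cos(2*pi*amp_freq*t)`` where
    ``phi(t)`` is the instantaneous (analytic-signal) phase of ``carrier``.
    """
    if not 0.0 <= m <= 1.0:
        raise ConfigurationError("modulation depth m must lie in [0, 1]")
    phi = np.angle(hilbert(carrier))
    t = np.arange(carrier.shape[-1]) / sampling_rate
    return base_amp * (1.0 + m * np.cos(phi)) * np.cos(2 * np.pi * amp_freq * t)


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

def _participant_rng(config: SimulationConfig, participant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, participant]))


def simulate_eeg(config: SimulationConfig, participant: int = 0) -> EpochedDataset:
    """One participant's epoched dataset under the configured conditions.

    Trials are ordered condition-block-wise (all neutral, all happy, all
    sad); downstream stages select trials by label, so order carries no
    information. Deterministic given ``config.seed`` and ``participant``.
    """
    rng = _participant_rng(config, participant)
    sr = config.sampling_rate
    t0, t1 = config.epoch_window
    n_samples = int(round((t1 - t0) * sr))
    times = t0 + np.arange(n_samples) / sr
    layout = config.channel_layout
    n_ch = len(layout)
    n_trials = config.n_trials_per_condition
    conditions = [c for c in config.conditions for _ in range(n_trials)]

    data = pink_noise(rng, (len(conditions), n_ch), n_samples, sr,
                      config.noise_exponent, config.noise_scale)
    if config.shared_noise_scale > 0:
        shared = pink_noise(rng, (len(conditions),), n_samples, sr,
                            config.noise_exponent, config.shared_noise_scale)
        data += shared[:, None, :]

    ch_index = {ch: i for i, ch in enumerate(layout)}

    for spec in config.oscillation_specs:
        idx = [ch_index[ch] for ch in _resolve_channels(spec.channels, layout)]
        mask = _taper(times, spec.time_window)
        for trial, cond in enumerate(conditions):
            if spec.condition is not None and cond != spec.condition:
                continue
            theta = rng.uniform(0, 2 * np.pi)
            wave = spec.amplitude * np.cos(2 * np.pi * spec.freq * times + theta) * mask
            data[trial, idx, :] += wave

    for spec in config.coupling_specs:
        p_idx = [ch_index[ch] for ch in _resolve_channels(spec.phase_channels, layout)]
        a_idx = [ch_index[ch] for ch in _resolve_channels(spec.amp_channels, layout)]
        mask = _taper(times, spec.time_window)
        for trial, cond in enumerate(conditions):
            if spec.condition is not None and cond != spec.condition:
                continue
            theta = rng.uniform(0, 2 * np.pi)
            psi = rng.uniform(0, 2 * np.pi)
            phi = 2 * np.pi * spec.phase_freq * times + theta
            carrier = spec.carrier_amp * np.cos(phi)
            fast = (spec.base_amp * (1.0 + spec.modulation_depth * np.cos(phi))
                    * np.cos(2 * np.pi * spec.amp_freq * times + psi))
            data[trial, p_idx, :] += carrier * mask
            data[trial, a_idx, :] += fast * mask

    return EpochedDataset(
        data=data,
        sampling_rate=sr,
        channel_names=list(layout),
        condition_labels=conditions,
        epoch_window=config.epoch_window,
        participant_id=f"sub-{participant:02d}",
    )


def simulate_study(config: SimulationConfig) -> list[EpochedDataset]:
    """Epoched datasets for every participant in the configuration."""
    return [simulate_eeg(config, p) for p in range(config.n_participants)]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(config: SimulationConfig) -> pd.DataFrame:
    """Participant x condition ratings table.

    Each rating is a condition mean plus a participant intercept
    (``subject_sd``) plus residual noise (``behavior_sd``), clipped to the
    1-5 scale. Columns: participant, gender, condition, arousal, pleasure,
    originality.
    """
    measures = ("arousal", "pleasure", "originality")
    for cond in config.conditions:
        if cond not in config.behavior_means:
            raise ConfigurationError(f"behavior_means missing condition {cond!r}")
        for m in measures:
            if m not in config.behavior_means[cond]:
                raise ConfigurationError(f"behavior_means[{cond!r}] missing {m!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    rows = []
    for p in range(config.n_participants):
        gender = "male" if p % 2 == 0 else "female"
        intercepts = {m: rng.normal(0.0, config.subject_sd) for m in measures}
        for cond in config.conditions:
            row = {"participant": f"sub-{p:02d}", "gender": gender, "condition": cond}
            for m in measures:
                value = (config.behavior_means[cond][m] + intercepts[m]
                         + rng.normal(0.0, config.behavior_sd))
                row[m] = float(np.clip(value, 1.0, 5.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def spectral_slope(data: np.ndarray, sampling_rate: float,
                   fmin: float = 1.0, fmax: float = 70.0) -> float:
    """Least-squares log-log slope beta of the average power spectrum.

    ``data`` may have any leading shape; spectra are averaged over all
    leading axes. Returns the exponent beta of a 1/f^beta fit.
    """
    freqs, psd = welch(data, fs=sampling_rate, nperseg=min(data.shape[-1], 4096),
                       axis=-1)
    psd = psd.reshape(-1, len(freqs)).mean(axis=0)
    sel = (freqs >= fmin) & (freqs <= fmax)
    coeffs = np.polyfit(np.log(freqs[sel]), np.log(psd[sel]), 1)
    return -coeffs[0]
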