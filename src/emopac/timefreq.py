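"""Morlet-wavelet time-frequency decomposition and baseline normalisation.

The analysing wavelet is ``w(t, f0) = A exp(-t^2 / (2 sigma_t^2))
exp(2 i pi f0 t)`` with a constant centre-frequency-to-bandwidth ratio
``f0 / sigma_f = 7`` and ``sigma_t = 1 / (2 pi sigma_f)``; ``A`` is chosen
so the wavelet has unit total energy. Power is the squared magnitude of
the convolution, computed per electrode and trial on a 1-70 Hz grid, then
averaged over the electrodes of a cluster.

Power is expressed relative to the pre-stimulus baseline: natural-log
power minus the per-frequency mean log power over the baseline window
(-3 to 0 s), i.e. signed log-change units. A percent-change mode
(``100 * (P - B) / B``) is available behind a flag.

Samples closer than 3 sigma_t to an epoch edge carry incomplete wavelet
support; they are flagged in a validity mask that widens towards low
frequencies.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal as sp_signal

DEFAULT_FREQS = np.arange(1.0, 71.0)  # Hz, 1-Hz grid
DEFAULT_RATIO = 7.0
BASELINE_WINDOW = (-3.0, 0.0)


def wavelet_sigmas(f0: float, ratio: float = DEFAULT_RATIO) -> tuple[float, float]:
    """(sigma_f, sigma_t) for a centre frequency, constant-ratio family."""
    sigma_f = f0 / ratio
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    return sigma_f, sigma_t


def make_wavelet(f0: float, sampling_rate: float,
                 ratio: float = DEFAULT_RATIO) -> np.ndarray:
    """Discrete unit-energy complex Morlet wavelet, support +-6 sigma_t
    (truncation sidelobes fall below the baseline epsilon floor)."""
    if f0 <= 0:
        raise ValueError("centre frequency must be positive")
    _, sigma_t = wavelet_sigmas(f0, ratio)
    half = int(np.ceil(6.0 * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    w = np.exp(-t ** 2 / (2 * sigma_t ** 2)) * np.exp(2j * np.pi * f0 * t)
    # unit energy on the discrete grid: sum |w|^2 dt = 1
    energy = np.sum(np.abs(w) ** 2) / sampling_rate
    return w / np.sqrt(energy)


def wavelet_power(
    data: np.ndarray,
    sampling_rate: float,
    freqs: np.ndarray = DEFAULT_FREQS,
    ratio: float = DEFAULT_RATIO,
    decim: int = 1,
) -> np.ndarray:
    """Squared-magnitude wavelet transform.

    ``data`` is (..., n_samples); the result is (..., n_freqs, n_times)
    with the time axis decimated by ``decim``. Same-length ("same" mode)
    convolution keeps the event-onset alignment of the input time axis.
    """
    from scipy import fft as sp_fft

    data = np.asarray(data, dtype=np.float64)
    n_samples = data.shape[-1]
    out_len = len(range(0, n_samples, decim))
    power = np.empty(data.shape[:-1] + (len(freqs), out_len))
    wavelets = [make_wavelet(float(f0), sampling_rate, ratio) for f0 in freqs]
    for f0, w in zip(freqs, wavelets):
        if len(w) > n_samples:
            warnings.warn(
                f"wavelet support at {f0} Hz ({len(w)} samples) exceeds the "
                f"epoch ({n_samples} samples); values are edge-dominated",
                stacklevel=2,
            )
    # one forward FFT of the signals, shared across all analysis frequencies
    n_fft = sp_fft.next_fast_len(n_samples + max(len(w) for w in wavelets) - 1)
    spectra = sp_fft.fft(data, n_fft, axis=-1)
    for i, w in enumerate(wavelets):
        # 1/sr: discrete convolution as a Riemann sum of the continuous one,
        # so unit-energy normalisation carries over to power units
        kernel = sp_fft.fft(w, n_fft) / sampling_rate
        conv = sp_fft.ifft(spectra * kernel, axis=-1)
        start = (len(w) - 1) // 2  # "same" alignment: keep onset at t=0
        seg = conv[..., start:start + n_samples:decim]
        power[..., i, :] = np.abs(seg) ** 2
    return power


def edge_valid_mask(freqs: np.ndarray, times: np.ndarray,
                    epoch_window: tuple[float, float],
                    ratio: float = DEFAULT_RATIO) -> np.ndarray:
    """(n_freqs, n_times) mask, False within 3 sigma_t of an epoch edge."""
    t0, t1 = epoch_window
    mask = np.empty((len(freqs), len(times)), dtype=bool)
    for i, f0 in enumerate(freqs):
        _, sigma_t = wavelet_sigmas(float(f0), ratio)
        mask[i] = (times >= t0 + 3 * sigma_t) & (times <= t1 - 3 * sigma_t)
    return mask


def baseline_normalize(
    power: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    mode: str = "log",
    eps_scale: float = 1e-12,
) -> np.ndarray:
    """Express power relative to the per-frequency baseline mean.

    ``log`` mode (default): ``ln(P) - mean(ln(P))`` over the baseline
    window, per frequency. ``percent`` mode: ``100 * (P - B) / B`` with B
    the baseline mean power. Zero baseline power is floored at
    ``eps_scale`` times the array maximum, with a warning.
    """
    sel = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not sel.any():
        raise ValueError(f"baseline window {baseline_window} outside the time axis")
    floor = max(power.max(), 1.0) * eps_scale
    if (power <= 0).any():
        warnings.warn("non-positive power values floored before log", stacklevel=2)
    safe = np.maximum(power, floor)
    if mode == "log":
        logp = np.log(safe)
        base = logp[..., sel].mean(axis=-1, keepdims=True)
        return logp - base
    if mode == "percent":
        base = safe[..., sel].mean(axis=-1, keepdims=True)
        return 100.0 * (safe - base) / base
    raise ValueError(f"unknown baseline mode {mode!r}")


@dataclasses.dataclass
class TFMap:
    """Baseline-normalised time-frequency map for one electrode cluster."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, t=0 at event onset
    valid: np.ndarray | None = None  # edge-validity mask, same shape
    cluster: str = ""
    condition: str = ""
    level: str = "participant"  # trial | participant | grand_average
    participant_id: str = ""

    def __post_init__(self):
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise ValueError("TFMap axes do not match the value matrix")

    def crop(self, window: tuple[float, float]) -> "TFMap":
        sel = (self.times >= window[0]) & (self.times < window[1])
        return dataclasses.replace(
            self,
            values=self.values[:, sel],
            times=self.times[sel],
            valid=None if self.valid is None else self.valid[:, sel],
        )


def cluster_tf_map(
    dataset,
    cluster: str,
    condition: str,
    freqs: np.ndarray = DEFAULT_FREQS,
    ratio: float = DEFAULT_RATIO,
    decim: int = 1,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    baseline_mode: str = "log",
) -> TFMap:
    """Participant-level TF map for one cluster and condition.

    Per trial: per-electrode wavelet power, averaged over the cluster's
    electrodes, baseline-normalised; trial maps are then averaged.
    """
    from .montage import cluster_indices

    idx = cluster_indices(dataset.channel_names, cluster)
    trials = dataset.trials_for(condition)[:, idx, :]  # (n_trials, 3, n_samples)
    power = wavelet_power(trials, dataset.sampling_rate, freqs, ratio, decim)
    power = power.mean(axis=1)  # over cluster electrodes -> (n_trials, F, T)
    times = dataset.times[::decim]
    normed = baseline_normalize(power, times, baseline_window, baseline_mode)
    values = normed.mean(axis=0)
    valid = edge_valid_mask(freqs, times, dataset.epoch_window, ratio)
    return TFMap(values=values, freqs=np.asarray(freqs, dtype=float), times=times,
                 valid=valid, cluster=cluster, condition=condition,
                 level="participant", participant_id=dataset.participant_id)


def aggregate_tf(maps: list[TFMap], level: str = "grand_average") -> TFMap:
    """Mean of TF maps sharing axes (e.g. participants -> grand average)."""
    if not maps:
        raise ValueError("no TF maps to aggregate")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or not np.allclose(m.freqs, first.freqs):
            raise ValueError("TF maps have inconsistent axes")
    values = np.mean([m.values for m in maps], axis=0)
    valid = first.valid
    return dataclasses.replace(first, values=values, valid=valid, level=level,
                               participant_id="")
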