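"""Fronto-parietal phase-amplitude coupling.

Coupling between the phase of slow frontal oscillations (1-12 Hz; delta
1-3, theta 3-7, alpha 7-12) and the envelope of parietal gamma (low 30-50,
high 50-70 Hz) is estimated with the mean vector length (MVL),

    MVL = | (1/N) * sum_t a(t) * exp(i * phi(t)) |,

over samples concatenated across trials, where ``phi`` is the
instantaneous phase of the band-passed frontal cluster signal and ``a``
the instantaneous envelope of the band-passed parietal cluster signal
(analytic signal via the Hilbert transform).

The raw MVL scales with overall amplitude and with incidental spectral
structure, so it is normalised against trial-shuffled surrogates: the
phase series of trial j is paired with the amplitude series of a different
trial k != j, destroying the within-trial phase-amplitude relationship
while preserving both marginals. The reported value is
``(raw - mean(surrogates)) / sd(surrogates)`` (a surrogate z-score; a
``(raw - mean) / mean`` mode is available).

Comodulograms tile a fine grid of (phase frequency x amplitude frequency)
bins over the four directed fronto-parietal paths LF-LP, RF-RP, LF-RP and
RF-LP. Condition PAC is reported by default as the activation-window value
minus the reference-window value, so positive values mean stronger
coupling during idea generation than during fixation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import norm

from .permstats import PermutationConfig, SignificanceMask, cluster_filter, smooth_map

PHASE_BANDS = {"delta": (1.0, 3.0), "theta": (3.0, 7.0), "alpha": (7.0, 12.0)}
AMP_BANDS = {"low_gamma": (30.0, 50.0), "high_gamma": (50.0, 70.0)}
#: short labels used in correlation-table feature names
BAND_CODES = {"delta": "D", "theta": "T", "alpha": "A",
              "low_gamma": "LG", "high_gamma": "HG"}

PATHS = ("LF-LP", "RF-RP", "LF-RP", "RF-LP")

ACTIVATION_WINDOW = (0.0, 10.0)
REFERENCE_WINDOW = (-6.0, -1.0)


@dataclasses.dataclass
class CouplingPath:
    name: str

    def __post_init__(self):
        if self.name not in PATHS:
            raise ValueError(f"unknown coupling path {self.name!r}")

    @property
    def phase_cluster(self) -> str:
        return self.name.split("-")[0]

    @property
    def amp_cluster(self) -> str:
        return self.name.split("-")[1]


@dataclasses.dataclass
class BandGrid:
    """Fine comodulogram grid: phase bins 1 Hz apart (2 Hz wide) over
    1-12 Hz, amplitude bins 2 Hz apart (10 Hz wide) over 30-70 Hz."""

    phase_step: float = 1.0
    phase_width: float = 2.0
    phase_range: tuple[float, float] = (1.0, 12.0)
    amp_step: float = 2.0
    amp_width: float = 10.0
    amp_range: tuple[float, float] = (30.0, 70.0)

    @property
    def phase_centers(self) -> np.ndarray:
        lo, hi = self.phase_range
        half = self.phase_width / 2
        return np.arange(lo + half, hi - half + 1e-9, self.phase_step)

    @property
    def amp_centers(self) -> np.ndarray:
        lo, hi = self.amp_range
        half = self.amp_width / 2
        return np.arange(lo + half, hi - half + 1e-9, self.amp_step)

    def phase_bins(self) -> list[tuple[float, float]]:
        half = self.phase_width / 2
        return [(c - half, c + half) for c in self.phase_centers]

    def amp_bins(self) -> list[tuple[float, float]]:
        half = self.amp_width / 2
        return [(c - half, c + half) for c in self.amp_centers]


@dataclasses.dataclass
class PACMatrix:
    """Normalised coupling values on the (phase freq x amp freq) grid."""

    values: np.ndarray  # (n_phase_bins, n_amp_bins)
    phase_freqs: np.ndarray  # bin centres, Hz
    amp_freqs: np.ndarray  # bin centres, Hz
    path: str = ""
    condition: str = ""
    level: str = "participant"
    window: str = "activation"  # activation | reference | contrast
    participant_id: str = ""

    def __post_init__(self):
        if self.values.shape != (len(self.phase_freqs), len(self.amp_freqs)):
            raise ValueError("PACMatrix axes do not match the value matrix")


# ---------------------------------------------------------------------------
# band-limited phase / envelope extraction
# ---------------------------------------------------------------------------

def _bandpass(data: np.ndarray, band: tuple[float, float], sampling_rate: float,
              order: int = 3) -> np.ndarray:
    lo, hi = band
    nyq = sampling_rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid at {sampling_rate} Hz")
    sos = sp_signal.butter(order, (lo, hi), btype="bandpass", fs=sampling_rate,
                           output="sos")
    return sp_signal.sosfiltfilt(sos, data, axis=-1)


def extract_phase(signals: np.ndarray, band: tuple[float, float],
                  sampling_rate: float) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] of the band-limited analytic signal.

    ``signals`` is (n_trials, n_samples); filtering and the Hilbert
    transform run over the full epoch so window cropping can happen after.
    """
    return np.angle(sp_signal.hilbert(_bandpass(signals, band, sampling_rate),
                                      axis=-1))


def extract_amplitude(signals: np.ndarray, band: tuple[float, float],
                      sampling_rate: float) -> np.ndarray:
    """Non-negative instantaneous envelope of the band-limited signal."""
    return np.abs(sp_signal.hilbert(_bandpass(signals, band, sampling_rate),
                                    axis=-1))


# ---------------------------------------------------------------------------
# MVL and surrogate normalisation
# ---------------------------------------------------------------------------

def mvl(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Mean vector length of amplitude-weighted phase vectors."""
    phase = np.ravel(phase)
    amplitude = np.ravel(amplitude)
    if phase.size == 0:
        raise ValueError("empty phase/amplitude series")
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude lengths differ")
    return float(np.abs(np.mean(amplitude * np.exp(1j * phase))))


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random permutation with no fixed point (phase of trial j never
    keeps its own amplitude)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def surrogate_normalize(phase_trials: np.ndarray, amp_trials: np.ndarray,
                        n_surrogates: int = 200, seed: int | np.random.Generator = 0,
                        mode: str = "zscore") -> dict:
    """Normalise the MVL against trial-shuffled surrogates.

    ``phase_trials`` and ``amp_trials`` are (n_trials, n_samples). Each
    surrogate pairs the phase of trial j with the amplitude of a different
    trial (a random derangement of trial indices) and recomputes the MVL.
    Returns raw MVL, surrogate mean/sd, and the normalised value:
    ``(raw - mean) / sd`` (``zscore``) or ``(raw - mean) / mean``
    (``relative``).
    """
    phase_trials = np.atleast_2d(phase_trials)
    amp_trials = np.atleast_2d(amp_trials)
    n_trials, n_samples = phase_trials.shape
    if amp_trials.shape != (n_trials, n_samples):
        raise ValueError("phase and amplitude trial arrays differ in shape")
    if n_trials < 5:
        raise ValueError("surrogate normalisation needs at least 5 trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # C[j, k] = sum_t amp[k, t] * exp(i * phase[j, t]); the raw MVL uses the
    # diagonal pairing, each surrogate a derangement of the columns.
    phasors = np.exp(1j * phase_trials)
    cross = phasors @ amp_trials.T  # (n_trials, n_trials) complex
    total = n_trials * n_samples
    raw = float(np.abs(np.trace(cross)) / total)
    idx = np.arange(n_trials)
    surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        perm = _derangement(rng, n_trials)
        surr[s] = np.abs(cross[idx, perm].sum()) / total
    mean, sd = float(surr.mean()), float(surr.std())
    if mode == "zscore":
        value = (raw - mean) / sd if sd > 0 else 0.0
    elif mode == "relative":
        value = (raw - mean) / mean if mean > 0 else 0.0
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return {"value": float(value), "raw": raw, "surrogate_mean": mean,
            "surrogate_sd": sd}


# ---------------------------------------------------------------------------
# comodulograms
# ---------------------------------------------------------------------------

def _window_slice(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError(f"window {window} outside the epoch time axis")
    return sel


def comodulogram(
    dataset,
    path: str,
    condition: str,
    grid: BandGrid | None = None,
    window: tuple[float, float] = ACTIVATION_WINDOW,
    n_surrogates: int = 200,
    seed: int = 0,
    mode: str = "zscore",
    smooth_halfwidth: int = 0,
    window_label: str = "activation",
) -> PACMatrix:
    """Surrogate-normalised PAC over the full band grid for one path.

    Phase comes from the frontal cluster mean, amplitude from the parietal
    cluster mean; band-limited phase/envelope are extracted over the whole
    epoch and then cropped to ``window``. Deterministic given ``seed``.
    """
    grid = grid or BandGrid()
    cp = CouplingPath(path)
    phase_sig = dataset.cluster_signal(cp.phase_cluster, condition)
    amp_sig = dataset.cluster_signal(cp.amp_cluster, condition)
    sel = _window_slice(dataset.times, window)
    sr = dataset.sampling_rate

    phases = [extract_phase(phase_sig, band, sr)[:, sel]
              for band in grid.phase_bins()]
    amps = [extract_amplitude(amp_sig, band, sr)[:, sel]
            for band in grid.amp_bins()]

    rng = np.random.default_rng(seed)
    values = np.empty((len(phases), len(amps)))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            values[i, j] = surrogate_normalize(ph, am, n_surrogates, rng, mode)["value"]
    if smooth_halfwidth:
        values = smooth_map(values, smooth_halfwidth)
    return PACMatrix(values=values, phase_freqs=grid.phase_centers,
                     amp_freqs=grid.amp_centers, path=path, condition=condition,
                     level="participant", window=window_label,
                     participant_id=getattr(dataset, "participant_id", ""))


def condition_pac(
    dataset,
    path: str,
    condition: str,
    grid: BandGrid | None = None,
    activation_window: tuple[float, float] = ACTIVATION_WINDOW,
    reference_window: tuple[float, float] = REFERENCE_WINDOW,
    n_surrogates: int = 200,
    seed: int = 0,
    mode: str = "zscore",
    contrast: bool = True,
) -> PACMatrix:
    """Condition-level PAC: activation-window coupling, by default minus
    the reference-window coupling (signed change relative to fixation)."""
    act = comodulogram(dataset, path, condition, grid, activation_window,
                       n_surrogates, seed, mode, window_label="activation")
    if not contrast:
        return act
    ref = comodulogram(dataset, path, condition, grid, reference_window,
                       n_surrogates, seed + 1, mode, window_label="reference")
    return dataclasses.replace(act, values=act.values - ref.values,
                               window="contrast")


def grand_average_pac(matrices: list[PACMatrix],
                      smooth_halfwidth: int = 0) -> PACMatrix:
    """Mean of participant PAC matrices (optionally smoothed first)."""
    if not matrices:
        raise ValueError("no PAC matrices to average")
    values = [smooth_map(m.values, smooth_halfwidth) if smooth_halfwidth
              else m.values for m in matrices]
    return dataclasses.replace(matrices[0], values=np.mean(values, axis=0),
                               level="grand_average", participant_id="")


def pac_significance(act_matrices: np.ndarray, ref_matrices: np.ndarray,
                     config: PermutationConfig | None = None) -> SignificanceMask:
    """Across-participant permutation significance of PAC matrices.

    Delegates to the time-frequency permutation machinery with the
    coupling-specific cluster threshold (k >= 12); axes are phase frequency
    by amplitude frequency.
    """
    from .permstats import run_permutation_test

    config = config or PermutationConfig(cluster_k=12)
    return run_permutation_test(np.asarray(act_matrices),
                                np.asarray(ref_matrices), config)


def zscore_mask(matrix: PACMatrix, alpha: float = 0.001, cluster_k: int = 12,
                connectivity: int = 4) -> np.ndarray:
    """Single-dataset significance from the surrogate z-scores themselves.

    Surrogate-normalised values are standard-normal under no coupling, so
    bins with |z| above the two-sided alpha quantile, cluster-filtered at
    k, flag coupled regions without an across-participant permutation.
    """
    crit = norm.isf(alpha / 2.0)
    raw = np.abs(matrix.values) > crit
    direction = np.sign(matrix.values).astype(np.int8)
    return cluster_filter(raw, direction, cluster_k, connectivity)


def band_feature(matrix: PACMatrix, phase_band: str, amp_band: str) -> float:
    """Mean normalised PAC over a named band rectangle (the scalar that
    enters the correlation analyses, e.g. theta x low gamma)."""
    if phase_band not in PHASE_BANDS:
        raise KeyError(f"unknown phase band {phase_band!r}")
    if amp_band not in AMP_BANDS:
        raise KeyError(f"unknown amplitude band {amp_band!r}")
    plo, phi_ = PHASE_BANDS[phase_band]
    alo, ahi = AMP_BANDS[amp_band]
    prows = (matrix.phase_freqs >= plo) & (matrix.phase_freqs < phi_)
    acols = (matrix.amp_freqs >= alo) & (matrix.amp_freqs < ahi)
    if not prows.any() or not acols.any():
        raise ValueError("band rectangle contains no grid bins")
    return float(matrix.values[np.ix_(prows, acols)].mean())


def feature_label(condition: str, phase_band: str, amp_band: str) -> str:
    """Correlation-table label, e.g. ``Happy-T-HG``."""
    return f"{condition.capitalize()}-{BAND_CODES[phase_band]}-{BAND_CODES[amp_band]}"
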