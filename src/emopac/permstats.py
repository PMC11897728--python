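"""Permutation significance for time-frequency and coupling matrices.

The procedure tests, element by element, whether the grand-average
difference between an activation-period map and a reference-period map is
larger than expected under exchange of time points and frequency bands:

1. for each of ``n_permutations`` draws, independently permute the time
   axis and the frequency axis of every participant's activation and
   reference maps, recompute the grand-average activation minus reference
   difference, and smooth it by a truncated moving average over
   neighbouring matrix elements (centre plus first and second neighbours,
   i.e. a 5 x 5 window by default);
2. z-score the observed smoothed difference against the per-element mean
   and standard deviation of the permutation distribution and convert to a
   two-sided p-value through the normal cumulative distribution function;
3. keep only elements with p below alpha that belong to a same-sign
   connected component of at least ``cluster_k`` elements (k >= 100 for
   time-frequency maps, k >= 12 for coupling matrices).

Activation and reference maps may have different numbers of time points
(task window vs fixation window); the difference is taken against the
reference map's per-frequency time average. An empirical-quantile test is
available as an alternative to the normal approximation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import norm


@dataclasses.dataclass
class PermutationConfig:
    n_permutations: int = 2000
    alpha: float = 0.001  # two-sided
    cluster_k: int = 100  # 100 for TF maps, 12 for PAC matrices
    smoothing_halfwidth: int = 2
    connectivity: int = 4  # 4- or 8-neighbour adjacency
    seed: int = 0
    use_empirical: bool = False  # empirical quantiles instead of normal CDF

    def __post_init__(self):
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass
class SignificanceMask:
    mask: np.ndarray  # bool, after cluster filtering
    direction: np.ndarray  # int8 sign of the observed difference
    p_values: np.ndarray
    z_values: np.ndarray
    observed: np.ndarray  # smoothed grand-average difference
    raw_mask: np.ndarray  # before cluster filtering


def smooth_map(matrix: np.ndarray, halfwidth: int = 2) -> np.ndarray:
    """Truncated moving average over a (2h+1)^2 neighbourhood.

    Edge elements average over the part of the window inside the matrix,
    so a constant matrix is left exactly unchanged everywhere.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be non-negative")
    if halfwidth == 0:
        return np.asarray(matrix, dtype=np.float64)
    size = 2 * halfwidth + 1
    num = ndimage.uniform_filter(np.asarray(matrix, dtype=np.float64),
                                 size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones(matrix.shape), size=size,
                                 mode="constant", cval=0.0)
    return num / den


def activation_minus_reference(act: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Difference of an activation map against a reference map.

    Equal-shape maps (e.g. coupling matrices) are differenced element-wise.
    When the time axes differ (task window vs fixation window), the
    reference map is collapsed to its per-frequency time mean first.
    """
    if act.shape[0] != ref.shape[0]:
        raise ValueError("activation and reference maps differ in frequency axis")
    if act.shape == ref.shape:
        return act - ref
    return act - ref.mean(axis=1, keepdims=True)


def observed_difference(act_maps: np.ndarray, ref_maps: np.ndarray,
                        halfwidth: int = 2) -> np.ndarray:
    """Smoothed grand-average activation-reference difference.

    ``act_maps`` is (n_participants, n_freqs, n_times_act), ``ref_maps``
    (n_participants, n_freqs, n_times_ref); see
    :func:`activation_minus_reference` for how unequal time axes are
    handled.
    """
    if act_maps.shape == ref_maps.shape:
        diffs = act_maps - ref_maps
    else:
        diffs = act_maps - ref_maps.mean(axis=2, keepdims=True)
    return smooth_map(diffs.mean(axis=0), halfwidth)


@dataclasses.dataclass
class NullDistribution:
    mean: np.ndarray
    sd: np.ndarray
    n_permutations: int
    samples: np.ndarray | None = None  # (n_perm, F, T) when stored


def build_null(act_maps: np.ndarray, ref_maps: np.ndarray,
               config: PermutationConfig,
               store_samples: bool = False) -> NullDistribution:
    """Permutation null of the smoothed grand-average difference.

    For every permutation, the time-axis and frequency-axis indices of each
    participant's activation and reference maps are permuted independently
    (axis-wise shuffling, preserving each map's marginal value set), the
    grand-average difference is recomputed and smoothed, and its value is
    recorded per matrix element.
    """
    act_maps = np.asarray(act_maps, dtype=np.float64)
    ref_maps = np.asarray(ref_maps, dtype=np.float64)
    if act_maps.ndim != 3 or ref_maps.ndim != 3:
        raise ValueError("expected (participants, freqs, times) map stacks")
    if act_maps.shape[0] != ref_maps.shape[0]:
        raise ValueError("participant counts differ between activation and reference")
    if act_maps.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if act_maps.shape[1] != ref_maps.shape[1]:
        raise ValueError("frequency axes differ between activation and reference")

    n_part, n_freq, n_ta = act_maps.shape
    n_tr = ref_maps.shape[2]
    rng = np.random.default_rng(config.seed)
    h = config.smoothing_halfwidth

    acc = np.zeros((n_freq, n_ta))
    acc_sq = np.zeros((n_freq, n_ta))
    samples = np.empty((config.n_permutations, n_freq, n_ta)) if store_samples else None

    elementwise = act_maps.shape == ref_maps.shape
    for perm in range(config.n_permutations):
        mean_diff = np.zeros((n_freq, n_ta))
        for p in range(n_part):
            fa = rng.permutation(n_freq)
            ta = rng.permutation(n_ta)
            fr = rng.permutation(n_freq)
            tr = rng.permutation(n_tr)
            act = act_maps[p][np.ix_(fa, ta)]
            ref = ref_maps[p][np.ix_(fr, tr)]
            mean_diff += act - ref if elementwise else act - ref.mean(axis=1, keepdims=True)
        mean_diff /= n_part
        smoothed = smooth_map(mean_diff, h)
        acc += smoothed
        acc_sq += smoothed ** 2
        if store_samples:
            samples[perm] = smoothed

    mean = acc / config.n_permutations
    var = acc_sq / config.n_permutations - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    return NullDistribution(mean=mean, sd=sd,
                            n_permutations=config.n_permutations, samples=samples)


def threshold_normal(observed: np.ndarray, null: NullDistribution,
                     alpha: float = 0.001) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-element (p, z, raw mask) from the normal-CDF comparison.

    Elements with a degenerate (zero-variance) null are excluded with a
    warning: p = 1, z = 0.
    """
    sd = null.sd
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} elements have zero permutation variance; excluded",
            stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (observed - null.mean) / safe_sd
    z = np.where(degenerate, 0.0, z)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(degenerate, 1.0, p)
    mask = p < alpha
    return p, z, mask


def threshold_empirical(observed: np.ndarray, null: NullDistribution,
                        alpha: float = 0.001) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical two-sided permutation p-values (requires stored samples)."""
    if null.samples is None:
        raise ValueError("empirical thresholding needs store_samples=True")
    centered = np.abs(observed - null.mean)
    exceed = (np.abs(null.samples - null.mean) >= centered).mean(axis=0)
    p = np.minimum(1.0, exceed + 1.0 / null.n_permutations)
    sd = np.where(null.sd == 0, 1.0, null.sd)
    z = (observed - null.mean) / sd
    return p, z, p < alpha


def cluster_filter(raw_mask: np.ndarray, direction: np.ndarray,
                   cluster_k: int, connectivity: int = 4) -> np.ndarray:
    """Remove significant elements outside same-sign components of size >= k.

    Positive and negative elements are clustered separately, so
    opposite-signed neighbours never merge into one component. The result
    is always a subset of the input mask.
    """
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    out = np.zeros_like(raw_mask, dtype=bool)
    for sign in (1, -1):
        part = raw_mask & (direction == sign)
        labels, n_labels = ndimage.label(part, structure=structure)
        if n_labels == 0:
            continue
        sizes = ndimage.sum_labels(part, labels, index=np.arange(1, n_labels + 1))
        keep = np.flatnonzero(sizes >= cluster_k) + 1
        out |= np.isin(labels, keep)
    return out


def run_permutation_test(act_maps: np.ndarray, ref_maps: np.ndarray,
                         config: PermutationConfig) -> SignificanceMask:
    """The full procedure: null, threshold, cluster filter."""
    observed = observed_difference(act_maps, ref_maps, config.smoothing_halfwidth)
    null = build_null(act_maps, ref_maps, config,
                      store_samples=config.use_empirical)
    if config.use_empirical:
        p, z, raw = threshold_empirical(observed, null, config.alpha)
    else:
        p, z, raw = threshold_normal(observed, null, config.alpha)
    direction = np.sign(z).astype(np.int8)
    mask = cluster_filter(raw, direction, config.cluster_k, config.connectivity)
    return SignificanceMask(mask=mask, direction=direction, p_values=p,
                            z_values=z, observed=observed, raw_mask=raw)
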