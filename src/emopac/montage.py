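"""Standard 10-20 montage helpers.

Channel positions are taken from MNE's built-in ``standard_1020`` template
and projected onto the unit sphere, which is the convention the spherical
spline interpolation expects.
"""

from __future__ import annotations

import functools

import numpy as np

#: Default 32-channel 10-20 layout (extended 10-20 labels). Contains all
#: electrodes of the four fronto-parietal analysis clusters.
DEFAULT_32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
]

#: Electrode clusters used throughout the analysis: left/right frontal and
#: left/right parietal groups of three electrodes each.
CLUSTERS = {
    "LF": ("F3", "FC5", "FC1"),
    "RF": ("F4", "FC6", "FC2"),
    "LP": ("P3", "CP5", "CP1"),
    "RP": ("P4", "CP6", "CP2"),
}


@functools.lru_cache(maxsize=4)
def _standard_1020_positions() -> dict[str, np.ndarray]:
    import mne

    mne.set_log_level("ERROR")
    montage = mne.channels.make_standard_montage("standard_1020")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}

def channel_positions(channel_names: list[str]) -> np.ndarray:
    """Unit-sphere positions (n_channels, 3) for 10-20 labels.

    Head-centred template coordinates are normalised to unit radius; only the
    angular part matters for spherical spline interpolation.
    """
    table = _standard_1020_positions()
    missing = [ch for ch in channel_names if ch not in table]
    if missing:
        raise KeyError(f"channels not in standard 10-20 montage: {missing}")
    pos = np.stack([table[ch] for ch in channel_names])
    # template origin is close to but not exactly the sphere centre; recentre
    # on the centroid of the full montage before normalising
    all_pos = np.stack(list(table.values()))
    center = all_pos.mean(axis=0)
    pos = pos - center
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def cluster_indices(channel_names: list[str], cluster: str) -> list[int]:
    """Indices of a named electrode cluster (LF/RF/LP/RP) in a channel list."""
    if cluster not in CLUSTERS:
        raise KeyError(f"unknown cluster {cluster!r}; expected one of {sorted(CLUSTERS)}")
    try:
        return [channel_names.index(ch) for ch in CLUSTERS[cluster]]
    except ValueError as err:
        raise KeyError(f"cluster {cluster} electrode missing from layout: {err}") from err
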