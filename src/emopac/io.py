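"""Data containers and on-disk formats.

Three things live here:

* :class:`ContinuousRecording` / :class:`EpochedDataset` — the in-memory
  containers for raw and epoched multi-channel EEG (always µV, time in
  seconds, t = 0 at event onset, half-open sample windows ``[start, end)``);
* a minimal EDF (European Data Format) reader/writer for raw recordings;
* :class:`ResultContainer`, an HDF5-backed store for named result arrays
  (time-frequency maps, comodulograms, significance masks) with complete
  axis metadata and provenance.

The EDF implementation covers the plain EDF profile this pipeline needs:
identical sampling rate on every channel, 1-second data records, 16-bit
samples. Amplitudes survive a round trip up to the 16-bit quantisation of
the format; recordings whose length is not a whole number of records are
padded by repeating the final sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from pathlib import Path

import h5py
import numpy as np

from .montage import channel_positions, cluster_indices


class FormatError(ValueError):
    """Malformed or unsupported file content."""


class ValidationError(ValueError):
    """Inconsistent in-memory data passed to a writer or constructor."""


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContinuousRecording:
    """Raw multi-channel recording: ``data`` is (n_channels, n_samples) µV."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("continuous data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError("channel_names length does not match data")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class EpochedDataset:
    """Epoched EEG: ``data`` is (n_trials, n_channels, n_samples) µV.

    ``epoch_window`` is ``(t0, t1)`` in seconds relative to the event onset;
    sample ``i`` sits at time ``t0 + i / sampling_rate`` and the event onset
    maps exactly onto the sample at ``t = 0``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    condition_labels: list[str]
    epoch_window: tuple[float, float]
    channel_positions: np.ndarray | None = None
    participant_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("epoched data must be 3-D (trials × channels × samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if n_channels != len(self.channel_names):
            raise ValidationError("channel_names length does not match data")
        if n_trials != len(self.condition_labels):
            raise ValidationError("condition_labels length does not match data")
        t0, t1 = self.epoch_window
        expected = int(round((t1 - t0) * self.sampling_rate))
        if n_samples != expected:
            raise ValidationError(
                f"time axis has {n_samples} samples, window {self.epoch_window} at "
                f"{self.sampling_rate} Hz implies {expected}"
            )
        if self.channel_positions is None:
            try:
                self.channel_positions = channel_positions(self.channel_names)
            except KeyError:
                self.channel_positions = None

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, t = 0 at event onset."""
        n = self.data.shape[2]
        return self.epoch_window[0] + np.arange(n) / self.sampling_rate

    def trials_for(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.condition_labels) if c == condition]
        if not idx:
            raise KeyError(
                f"no trials for condition {condition!r} "
                f"(participant {self.participant_id or 'unknown'})"
            )
        return self.data[idx]

    def cluster_signal(self, cluster: str, condition: str | None = None) -> np.ndarray:
        """Cluster-averaged signal (n_trials, n_samples) for LF/RF/LP/RP."""
        idx = cluster_indices(self.channel_names, cluster)
        data = self.data if condition is None else self.trials_for(condition)
        return data[:, idx, :].mean(axis=1)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition_labels:
            if c not in seen:
                seen.append(c)
        return seen


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad_ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: ContinuousRecording, path: str | Path) -> None:
    """Write a recording as plain EDF (16-bit, 1-second records, µV)."""
    data = recording.data
    n_channels, n_samples = data.shape
    if n_channels == 0:
        raise ValidationError("cannot write EDF with zero channels")
    sr = recording.sampling_rate
    spr = int(round(sr))
    if abs(sr - spr) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(n_samples / spr))
    total = n_records * spr
    if total != n_samples:
        pad = np.repeat(data[:, -1:], total - n_samples, axis=1)
        data = np.concatenate([data, pad], axis=1)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    scale = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + _EDF_DIG_MIN)
    digital = digital.astype("<i2")

    header = b"".join([
        _pad_ascii("0", 8),
        _pad_ascii("X", 80),
        _pad_ascii("emopac recording", 80),
        _pad_ascii("01.01.00", 8),
        _pad_ascii("00.00.00", 8),
        _pad_ascii(str(256 * (1 + n_channels)), 8),
        _pad_ascii("", 44),
        _pad_ascii(str(n_records), 8),
        _pad_ascii("1", 8),
        _pad_ascii(str(n_channels), 4),
    ])
    fields = [
        (16, recording.channel_names),
        (80, ["" for _ in range(n_channels)]),
        (8, ["uV" for _ in range(n_channels)]),
        (8, [f"{v:.6g}"[:8] for v in pmin]),
        (8, [f"{v:.6g}"[:8] for v in pmax]),
        (8, [str(_EDF_DIG_MIN)] * n_channels),
        (8, [str(_EDF_DIG_MAX)] * n_channels),
        (80, ["" for _ in range(n_channels)]),
        (8, [str(spr)] * n_channels),
        (32, ["" for _ in range(n_channels)]),
    ]
    signal_header = b"".join(
        b"".join(_pad_ascii(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        # records: channel-major within each record
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())


def _read_field(raw: bytes, offset: int, width: int) -> str:
    return raw[offset:offset + width].decode("ascii", errors="replace").strip()


def read_raw_edf(path: str | Path) -> ContinuousRecording:
    """Read a plain EDF file into a :class:`ContinuousRecording` (µV).

    Raises :class:`FormatError` for malformed headers and for EDF features
    this pipeline does not use (per-channel sampling rates).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError("file shorter than EDF header")
    try:
        header_bytes = int(_read_field(raw, 184, 8))
        n_records = int(_read_field(raw, 236, 8))
        record_duration = float(_read_field(raw, 244, 8))
        n_channels = int(_read_field(raw, 252, 4))
    except ValueError as err:
        raise FormatError(f"malformed EDF header: {err}") from err
    if n_channels <= 0:
        raise FormatError("EDF file declares no signals")
    if len(raw) < header_bytes:
        raise FormatError("EDF header truncated")

    sig = raw[256:header_bytes]
    width_plan = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    if len(sig) < n_channels * sum(width_plan):
        raise FormatError("EDF signal header truncated")

    def column(field_index: int) -> list[str]:
        offset = sum(width_plan[:field_index]) * n_channels
        w = width_plan[field_index]
        return [_read_field(sig, offset + i * w, w) for i in range(n_channels)]

    labels = column(0)
    try:
        pmin = np.array([float(v) for v in column(3)])
        pmax = np.array([float(v) for v in column(4)])
        dmin = np.array([float(v) for v in column(5)])
        dmax = np.array([float(v) for v in column(6)])
        spr = np.array([int(v) for v in column(8)])
    except ValueError as err:
        raise FormatError(f"malformed EDF signal header: {err}") from err
    if len(set(spr.tolist())) != 1:
        raise FormatError("per-channel sampling rates are not supported")
    spr0 = int(spr[0])
    if record_duration <= 0:
        raise FormatError("non-positive record duration")
    sampling_rate = spr0 / record_duration

    payload = raw[header_bytes:]
    record_size = n_channels * spr0 * 2
    if n_records < 0:  # -1 means "unknown" in the wild
        n_records = len(payload) // record_size
    if len(payload) < n_records * record_size:
        raise FormatError("EDF data section truncated")
    records = np.frombuffer(payload[: n_records * record_size], dtype="<i2")
    records = records.reshape(n_records, n_channels, spr0)
    digital = np.moveaxis(records, 0, 1).reshape(n_channels, n_records * spr0)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return ContinuousRecording(data=data, sampling_rate=sampling_rate,
                               channel_names=labels)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_continuous(
    recording: ContinuousRecording,
    event_samples: list[int],
    window: tuple[float, float],
    condition_labels: list[str] | None = None,
    participant_id: str = "",
) -> EpochedDataset:
    """Cut trials around event samples.

    ``window`` is (t0, t1) seconds relative to each event; samples
    ``[event + round(t0·rate), event + round(t1·rate))`` are taken. Events
    whose window leaves the recording are dropped with a warning; if all are
    dropped an error is raised.
    """
    sr = recording.sampling_rate
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError("epoch window must have t1 > t0")
    lo = int(round(t0 * sr))
    hi = int(round(t1 * sr))
    if condition_labels is None:
        condition_labels = ["trial"] * len(event_samples)
    if len(condition_labels) != len(event_samples):
        raise ValidationError("condition_labels length does not match events")

    trials, kept_labels = [], []
    for ev, lab in zip(event_samples, condition_labels):
        start, stop = ev + lo, ev + hi
        if start < 0 or stop > recording.n_samples:
            warnings.warn(
                f"dropping event at sample {ev}: window [{start}, {stop}) outside recording",
                stacklevel=2,
            )
            continue
        trials.append(recording.data[:, start:stop])
        kept_labels.append(lab)
    if not trials:
        raise ValidationError("no event window fits inside the recording")
    return EpochedDataset(
        data=np.stack(trials),
        sampling_rate=sr,
        channel_names=list(recording.channel_names),
        condition_labels=kept_labels,
        epoch_window=window,
        participant_id=participant_id,
    )


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ResultArray:
    """A named result matrix with one labelled coordinate per dimension."""

    values: np.ndarray
    dims: tuple[str, ...]
    coords: dict[str, np.ndarray]
    attrs: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        values = np.asarray(self.values)
        if len(self.dims) != values.ndim:
            raise ValidationError("dims do not match array rank")
        for axis, dim in enumerate(self.dims):
            if dim not in self.coords:
                raise ValidationError(f"missing axis metadata for dimension {dim!r}")
            if len(self.coords[dim]) != values.shape[axis]:
                raise ValidationError(
                    f"coordinate {dim!r} has length {len(self.coords[dim])}, "
                    f"array axis has {values.shape[axis]}"
                )


@dataclasses.dataclass
class ResultContainer:
    """Named result arrays plus run provenance, round-tripped via HDF5."""

    arrays: dict[str, ResultArray] = dataclasses.field(default_factory=dict)
    provenance: dict = dataclasses.field(default_factory=dict)

    def add(self, name: str, array: ResultArray) -> None:
        array.validate()
        self.arrays[name] = array


def config_hash(config: dict) -> str:
    """Stable hash of a (nested, JSON-able) configuration mapping."""
    import json

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_container(container: ResultContainer, path: str | Path) -> None:
    for arr in container.arrays.values():
        arr.validate()
    with h5py.File(path, "w") as fh:
        prov = fh.create_group("provenance")
        for key, value in container.provenance.items():
            prov.attrs[key] = value
        grp = fh.create_group("arrays")
        for name, arr in container.arrays.items():
            g = grp.create_group(name)
            g.create_dataset("values", data=np.asarray(arr.values))
            g.attrs["dims"] = list(arr.dims)
            axes = g.create_group("axes")
            for dim, coord in arr.coords.items():
                coord = np.asarray(coord)
                if coord.dtype.kind in "UO":
                    axes.create_dataset(dim, data=coord.astype(object),
                                        dtype=h5py.string_dtype())
                else:
                    axes.create_dataset(dim, data=coord)
            for key, value in arr.attrs.items():
                g.attrs[key] = value


def read_container(path: str | Path) -> ResultContainer:
    container = ResultContainer()
    with h5py.File(path, "r") as fh:
        container.provenance = dict(fh["provenance"].attrs)
        for name, g in fh["arrays"].items():
            dims = tuple(g.attrs["dims"])
            coords = {}
            for dim, ds in g["axes"].items():
                data = ds[()]
                if ds.dtype.kind in "OS":
                    data = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                     for v in data])
                coords[dim] = data
            attrs = {k: v for k, v in g.attrs.items() if k != "dims"}
            container.arrays[name] = ResultArray(
                values=g["values"][()], dims=dims, coords=coords, attrs=attrs
            )
    return container


def container_checksum(container: ResultContainer) -> str:
    """Checksum over array values and axes (provenance excluded)."""
    digest = hashlib.sha256()
    for name in sorted(container.arrays):
        arr = container.arrays[name]
        digest.update(name.encode())
        digest.update(np.ascontiguousarray(np.asarray(arr.values, dtype=np.float64)))
        for dim in arr.dims:
            digest.update(str(np.asarray(arr.coords[dim]).tolist()).encode())
    return digest.hexdigest()
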