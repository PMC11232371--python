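"""Core data types and file I/O shared by all pipeline stages.

The central container is :class:`ContinuousRecording`, a channels x samples
voltage matrix in microvolts with a sample rate and optional per-sample mask
distinguishing raw samples from samples replaced by artifact interpolation.
Times exposed to users are in seconds; all internal arithmetic is in sample
indices (0-based). Time windows are half-open ``[t0, t1)``.

The canonical on-disk form is an HDF5 container with one dataset per channel
and root attributes ``sample_rate_hz``, ``start_time_s`` and ``units``.
Delimited text (CSV with a leading time column) is supported for small
recordings and interoperability; it does not carry the mask.

Behavioral event tables are plain CSV with columns
``event_code,time_s,trial_id,condition_tags`` where ``condition_tags`` is a
``key=value;key=value`` string (e.g. ``reward_size=large;target_dir=left``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "Channel",
    "ContinuousRecording",
    "PeakSet",
    "read_recording",
    "write_recording",
    "slice_recording",
    "read_event_table",
    "write_event_table",
    "validate_event_table",
]

MASK_RAW = 0
MASK_INTERPOLATED = 1


@dataclasses.dataclass(frozen=True)
class Channel:
    """Descriptor for one extracellular electrode channel.

    ``region`` tags the anatomical target: caudate nucleus (``CN``),
    ``putamen`` or ``none`` for synthetic/unknown sites.
    """

    label: str
    region: str = "none"


@dataclasses.dataclass
class ContinuousRecording:
    """Multichannel continuous extracellular voltage recording (microvolts)."""

    sample_rate: float
    data: np.ndarray
    channels: list[Channel]
    start_time: float = 0.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for "
                f"{self.data.shape[0]} data rows"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.uint8)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask must have the same shape as data")

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def get(self, label: str) -> np.ndarray:
        """Return the voltage trace for one channel (view, not a copy)."""
        return self.data[self.channel_index(label)]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            sample_rate=self.sample_rate,
            data=self.data.copy(),
            channels=list(self.channels),
            start_time=self.start_time,
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclasses.dataclass
class PeakSet:
    """Artifact peak times (sample indices) on a nominal periodic grid.

    ``origin`` records, per peak, whether it was ``detected`` by
    thresholding or ``inserted`` to fill a gap in the periodic grid.
    Peak indices are strictly increasing.  Per-peak deviation from the
    grid is at most ``tolerance`` samples, so consecutive gaps deviate
    from an integer multiple of ``nominal_period`` by at most twice the
    tolerance; construction validates that bound.
    """

    peak_times: np.ndarray
    nominal_period: float
    tolerance: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=np.int64)
        self.origin = np.asarray(self.origin, dtype=object)
        if self.peak_times.shape != self.origin.shape:
            raise ValueError("peak_times and origin must have the same length")
        if self.peak_times.size:
            gaps = np.diff(self.peak_times)
            if np.any(gaps <= 0):
                raise ValueError("peak_times must be strictly increasing")
            if self.nominal_period > 0:
                mult = np.round(gaps / self.nominal_period)
                resid = np.abs(gaps - mult * self.nominal_period)
                if np.any(resid > 2 * self.tolerance + 1):
                    raise ValueError("consecutive peak gaps violate the period grid")

    def __len__(self) -> int:
        return int(self.peak_times.size)

    @classmethod
    def empty(cls, nominal_period: float = 0.0, tolerance: float = 0.0) -> "PeakSet":
        return cls(np.empty(0, dtype=np.int64), nominal_period, tolerance,
                   np.empty(0, dtype=object))

    def to_dataframe(self, sample_rate: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_index": self.peak_times,
                "time_s": self.peak_times / sample_rate,
                "origin": self.origin,
            }
        )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: ContinuousRecording, path, format: str = "hdf5"):
    """Write a recording; round-trips bit-exactly through :func:`read_recording`.

    HDF5 stores one float64 dataset per channel plus the mask; delimited
    text stores a ``t`` column followed by one column per channel (mask
    not preserved).
    """
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["sample_rate_hz"] = float(rec.sample_rate)
            f.attrs["start_time_s"] = float(rec.start_time)
            f.attrs["units"] = "uV"
            f.attrs["channel_order"] = [c.label for c in rec.channels]
            grp = f.create_group("channels")
            for i, ch in enumerate(rec.channels):
                d = grp.create_dataset(ch.label, data=rec.data[i])
                d.attrs["region"] = ch.region
            if rec.mask is not None:
                f.create_dataset("mask", data=rec.mask)
    elif format == "delimited-text":
        t = rec.start_time + np.arange(rec.n_samples) / rec.sample_rate
        df = pd.DataFrame({"t": t})
        for i, ch in enumerate(rec.channels):
            df[ch.label] = rec.data[i]
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_recording(path, format: str = "hdf5") -> ContinuousRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "sample_rate_hz" not in f.attrs:
                raise FormatError(f"{path}: missing sample_rate_hz attribute")
            rate = float(f.attrs["sample_rate_hz"])
            start = float(f.attrs.get("start_time_s", 0.0))
            order = [
                lab.decode() if isinstance(lab, bytes) else str(lab)
                for lab in f.attrs.get("channel_order", list(f["channels"].keys()))
            ]
            chans, rows = [], []
            for lab in order:
                d = f["channels"][lab]
                region = d.attrs.get("region", "none")
                if isinstance(region, bytes):
                    region = region.decode()
                chans.append(Channel(lab, str(region)))
                rows.append(np.asarray(d[...], dtype=np.float64))
            lengths = {r.size for r in rows}
            if len(lengths) > 1:
                raise ValueError(f"{path}: ragged channel lengths {sorted(lengths)}")
            data = (np.vstack(rows) if rows
                    else np.empty((0, 0), dtype=np.float64))
            mask = np.asarray(f["mask"][...], dtype=np.uint8) if "mask" in f else None
        return ContinuousRecording(rate, data, chans, start, mask)
    if format == "delimited-text":
        df = pd.read_csv(path)
        if "t" not in df.columns:
            raise FormatError(f"{path}: delimited text must have a 't' column")
        labels = [c for c in df.columns if c != "t"]
        t = df["t"].to_numpy(dtype=np.float64)
        if t.size < 2:
            raise FormatError(f"{path}: need >= 2 rows to infer the sample rate")
        rate = 1.0 / float(np.median(np.diff(t)))
        data = df[labels].to_numpy(dtype=np.float64).T
        return ContinuousRecording(rate, data, [Channel(lab) for lab in labels],
                                   start_time=float(t[0]))
    raise ValueError(f"unknown format {format!r}")


def slice_recording(rec: ContinuousRecording, t0: float, t1: float,
                    channels: list[str] | None = None) -> ContinuousRecording:
    """Return the half-open time slice ``[t0, t1)`` of selected channels.

    Times are relative to the recording start; the slice contains
    ``round((t1 - t0) * sample_rate)`` samples and its ``start_time`` is
    advanced accordingly.
    """
    if not (0.0 <= t0 < t1 <= rec.duration + 0.5 / rec.sample_rate):
        raise ValueError(f"invalid slice bounds [{t0}, {t1}) for duration {rec.duration}")
    i0 = int(round(t0 * rec.sample_rate))
    n = int(round((t1 - t0) * rec.sample_rate))
    i1 = min(i0 + n, rec.n_samples)
    if channels is None:
        rows = list(range(rec.n_channels))
    else:
        rows = [rec.channel_index(lab) for lab in channels]
    return ContinuousRecording(
        sample_rate=rec.sample_rate,
        data=rec.data[rows, i0:i1].copy(),
        channels=[rec.channels[r] for r in rows],
        start_time=rec.start_time + i0 / rec.sample_rate,
        mask=None if rec.mask is None else rec.mask[rows, i0:i1].copy(),
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def _parse_tags(s) -> dict:
    if not isinstance(s, str) or not s:
        return {}
    out = {}
    for part in s.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_event_table(path) -> pd.DataFrame:
    """Read a behavioral event table CSV.

    Returns a DataFrame with columns ``event_code``, ``time_s``,
    ``trial_id`` plus one column per condition tag key found in
    ``condition_tags`` (e.g. ``reward_size``, ``target_dir``).
    """
    df = pd.read_csv(path)
    required = {"event_code", "time_s", "trial_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: event table must have columns {sorted(required)}")
    if "condition_tags" in df.columns:
        tags = df["condition_tags"].map(_parse_tags)
        keys = sorted({k for d in tags for k in d})
        for k in keys:
            df[k] = [d.get(k) for d in tags]
    validate_event_table(df)
    return df


def validate_event_table(df: pd.DataFrame) -> None:
    """Check event-table invariants: trial ids >= 0, times non-decreasing per trial."""
    if (df["trial_id"] < 0).any():
        raise ValueError("trial_id must be >= 0")
    for tid, grp in df.groupby("trial_id"):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"event times decrease within trial {tid}")


def write_event_table(df: pd.DataFrame, path, tag_columns: list[str] | None = None):
    """Write an event table, folding ``tag_columns`` into ``condition_tags``."""
    out = df.copy()
    if tag_columns:
        out["condition_tags"] = [
            ";".join(f"{k}={row[k]}" for k in tag_columns if pd.notna(row[k]))
            for _, row in df.iterrows()
        ]
        out = out.drop(columns=[c for c in tag_columns])
    cols = ["event_code", "time_s", "trial_id"] + (
        ["condition_tags"] if "condition_tags" in out.columns else []
    )
    out[cols].to_csv(path, index=False)
    return path
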