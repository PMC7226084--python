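"""Readers and writers for recordings, annotations and feature tables.

Signals travel either as European Data Format (EDF, read-only, via :mod:`mne`)
or as the package's array container: a ``.npy`` file holding the
``channels x samples`` float matrix next to a ``.json`` sidecar with the
sampling rate, channel ids and subject id.  Annotations and feature tables are
plain CSV (comma separator, ``.`` decimal, UTF-8, header row).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

#: Valid event classes, in increasing tie-break precedence.
EVENT_LABELS = ("R", "FR", "FRonR")
#: Segment label vocabulary (event classes plus background).
SEGMENT_LABELS = ("noHFO",) + EVENT_LABELS

ANNOTATION_COLUMNS = ["channel", "start_s", "end_s", "label"]

#: Analysis bands as (name, low Hz, high Hz).
BAND_DEFS = (("band80_250", 80.0, 250.0),
             ("band250_500", 250.0, 500.0),
             ("band80_500", 80.0, 500.0))
FEATURE_NAMES = ("line_length", "short_time_energy", "rms", "teager")
#: Band-major feature column order of the segment feature table.
FEATURE_COLUMNS = [f"{band}_{feat}" for band, _, _ in BAND_DEFS
                   for feat in FEATURE_NAMES]
PROVENANCE_COLUMNS = ["subject", "channel", "start_s", "end_s", "window_ms"]
TABLE_COLUMNS = PROVENANCE_COLUMNS + FEATURE_COLUMNS + ["label"]


@dataclass
class Recording:
    """A multichannel iEEG signal.

    signal
        ``(n_channels, n_samples)`` array in signal units (e.g. µV).
    sampling_rate
        Samples per second, identical for all channels.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_ids: list[str]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise FormatError("signal must be a channels x samples matrix")
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise FormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise FormatError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.signal.shape[0]} signal rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise FormatError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """Ground-truth event: half-open interval [start, end) on one channel."""

    channel_id: str
    start: float
    end: float
    label: str = field(compare=False, default="R")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"annotation end ({self.end}) must exceed start ({self.start})")
        if self.label not in EVENT_LABELS:
            raise FormatError(
                f"unknown label {self.label!r}; expected one of {EVENT_LABELS}")

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# recordings


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write the array container: ``<path>.npy`` plus ``<path>.json`` sidecar.

    Returns the path of the ``.npy`` file.
    """
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, recording.signal)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "channel_ids": list(recording.channel_ids),
        "subject_id": recording.subject_id,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def _read_container(path: Path) -> Recording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    signal = np.load(path)
    return Recording(signal=signal,
                     sampling_rate=float(meta["sampling_rate"]),
                     channel_ids=[str(c) for c in meta["channel_ids"]],
                     subject_id=str(meta.get("subject_id", "unknown")))


def _read_edf(path: Path) -> Recording:
    # mne silently equalizes heterogeneous per-channel rates, so probe the
    # fixed-width ASCII header first and reject multi-rate files explicitly.
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header (<256 bytes)")
        try:
            n_sig = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable EDF header at offset 252") from exc
        per_sig = fh.read(256 * n_sig)
        if len(per_sig) < 256 * n_sig:
            raise FormatError(f"{path}: truncated EDF signal headers")
        off = 216 * n_sig  # samples-per-record field block
        counts = set()
        for i in range(n_sig):
            raw = per_sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip()
            try:
                counts.add(int(raw))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: bad samples-per-record for signal {i}") from exc
        if len(counts) > 1:
            raise FormatError(
                f"{path}: channels have different sampling rates "
                f"(samples/record {sorted(counts)}); multi-rate EDF is rejected")
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(signal=raw.get_data(),
                     sampling_rate=float(raw.info["sfreq"]),
                     channel_ids=list(raw.ch_names),
                     subject_id=path.stem)


def read_recording(path: str | Path, format_hint: str | None = None) -> Recording:
    """Read a recording from EDF or the array container.

    ``format_hint`` may be ``"edf"`` or ``"npy"``; by default the file
    extension decides.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "npy":
        return _read_container(path)
    raise FormatError(f"unknown recording format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Parse the annotation CSV (header ``channel,start_s,end_s,label``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if [c.strip() for c in header.split(",")] != ANNOTATION_COLUMNS:
            raise FormatError(
                f"{path}:1: expected header {','.join(ANNOTATION_COLUMNS)!r}, "
                f"got {header!r}")
        events = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            channel, start_s, end_s, label = parts
            try:
                start, end = float(start_s), float(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable time") from exc
            if not (math.isfinite(start) and math.isfinite(end)):
                raise FormatError(f"{path}:{lineno}: non-finite time")
            if label not in EVENT_LABELS:
                raise FormatError(
                    f"{path}:{lineno}: unknown label {label!r}; "
                    f"expected one of {EVENT_LABELS}")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            events.append(EventAnnotation(channel, start, end, label))
    return events


def write_annotations(events: list[EventAnnotation], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(ANNOTATION_COLUMNS) + "\n")
        for ev in events:
            fh.write(f"{ev.channel_id},{ev.start:.6f},{ev.end:.6f},{ev.label}\n")


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a segment feature table as CSV with the stable column order."""
    if table.empty:
        raise FormatError("refusing to write an empty feature table")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table is missing columns {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = set(table["label"].unique()) - set(SEGMENT_LABELS)
    if bad:
        raise FormatError(f"{path}: unknown segment labels {sorted(bad)}")
    return table
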