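"""Data model and plain-text readers/writers.

A :class:`Recording` holds oxy- and deoxy-hemoglobin concentration-change
matrices (time x channel, arbitrary units) at a known sampling rate; an
:class:`EventSchedule` holds the block design (task onsets and durations in
seconds) that defines the true behavioral state.

Signal files are CSV/TSV with a header row of channel ids (time-major), a
transposed channel x time layout (auto-detected), or a single long-format
table with columns ``time, channel, oxy, deoxy``.  Events are JSON or
2-column CSV.  All windows throughout the package are half-open ``[start,
end)`` with sample ``k`` at time ``t0 + k / fs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventSchedule",
    "read_recording",
    "read_recording_long",
    "write_recording",
    "read_events",
    "write_events",
]

#: float format preserving doubles exactly in text round-trips
_FLOAT_FMT = "%.17g"


@dataclass
class Recording:
    """Multi-channel NIRS recording: time-major oxy/deoxy matrices."""

    sampling_rate_hz: float
    channel_ids: list[str]
    oxy: np.ndarray
    deoxy: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.ndim == 1:
            self.oxy = self.oxy[:, None]
        if self.deoxy.ndim == 1:
            self.deoxy = self.deoxy[:, None]
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.oxy.shape != self.deoxy.shape:
            raise ValueError(
                f"sample count mismatch: oxy {self.oxy.shape} vs deoxy {self.deoxy.shape}"
            )
        if self.oxy.shape[1] != len(self.channel_ids):
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.oxy.shape[1]} columns"
            )
        if not (np.isfinite(self.oxy).all() and np.isfinite(self.deoxy).all()):
            raise ValueError("recording contains NaN/Inf values")

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[0]

    @property
    def n_channels(self) -> int:
        return self.oxy.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel id: {channel_id!r}") from None

    def signal(self, chromophore: str) -> np.ndarray:
        """Return the (n_samples, n_channels) matrix for 'oxy' or 'deoxy'."""
        if chromophore == "oxy":
            return self.oxy
        if chromophore == "deoxy":
            return self.deoxy
        raise ValueError(f"chromophore must be 'oxy' or 'deoxy', got {chromophore!r}")

    def copy(self) -> "Recording":
        return replace(self, oxy=self.oxy.copy(), deoxy=self.deoxy.copy(),
                       channel_ids=list(self.channel_ids))


@dataclass(frozen=True)
class EventSchedule:
    """Ordered, non-overlapping task blocks within [0, total_duration_s]."""

    blocks: tuple[tuple[float, float], ...]
    total_duration_s: float

    def __init__(self, blocks: Sequence[Sequence[float]], total_duration_s: float | None = None):
        blk = tuple(sorted((float(o), float(d)) for o, d in blocks))
        bad = [b for b in blk if b[1] <= 0]
        if bad:
            raise ValueError(f"non-positive block durations: {bad}")
        for (o1, d1), (o2, _) in zip(blk, blk[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError(f"overlapping blocks: ({o1}, {d1}) and onset {o2}")
        if blk and blk[0][0] < 0:
            raise ValueError(f"block onset before t=0: {blk[0]}")
        if total_duration_s is None:
            total_duration_s = blk[-1][0] + blk[-1][1] if blk else 0.0
        if blk and blk[-1][0] + blk[-1][1] > total_duration_s + 1e-9:
            raise ValueError("last block extends past total_duration_s")
        object.__setattr__(self, "blocks", blk)
        object.__setattr__(self, "total_duration_s", float(total_duration_s))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.blocks])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([o + d for o, d in self.blocks])

    def subset(self, indices: Sequence[int]) -> "EventSchedule":
        return EventSchedule([self.blocks[i] for i in indices], self.total_duration_s)


def _read_signal_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read one chromophore file, auto-detecting orientation by header.

    Time-major files have channel ids in the header; channel-major files have
    an all-numeric header (sample index or time) and channel ids in the first
    column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    def _numeric(s: str) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    header = [str(c) for c in df.columns]
    if all(_numeric(h) for h in header[1:]) and not _numeric(header[0]):
        # channel x time: first column holds channel ids
        ids = [str(v) for v in df.iloc[:, 0]]
        data = df.iloc[:, 1:].to_numpy(dtype=float).T
    elif all(_numeric(h) for h in header):
        raise ValueError(f"{path}: header row of channel ids is missing")
    else:
        ids = header
        data = df.to_numpy(dtype=float)
    if not np.isfinite(data).all():
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(f"{path}: non-finite value at row {bad[0]}, column {bad[1]}")
    return ids, data


def read_recording(path_oxy: str | Path, path_deoxy: str | Path,
                   sampling_rate_hz: float, t0_s: float = 0.0) -> Recording:
    """Load a Recording from one CSV/TSV per chromophore.

    Raises ValueError on shape mismatch between files, missing headers, or
    non-numeric/non-finite cells; channels are aligned by id when both files
    name the same channels.
    """
    ids_o, oxy = _read_signal_table(path_oxy)
    ids_d, deoxy = _read_signal_table(path_deoxy)
    if oxy.shape[0] != deoxy.shape[0]:
        raise ValueError(
            f"sample count mismatch: {path_oxy} has {oxy.shape[0]} rows, "
            f"{path_deoxy} has {deoxy.shape[0]}"
        )
    if ids_o != ids_d:
        if sorted(ids_o) != sorted(ids_d):
            raise ValueError(f"channel ids differ between {path_oxy} and {path_deoxy}")
        deoxy = deoxy[:, [ids_d.index(c) for c in ids_o]]
    return Recording(sampling_rate_hz, ids_o, oxy, deoxy, t0_s)


def read_recording_long(path: str | Path, sampling_rate_hz: float) -> Recording:
    """Load a Recording from a long-format CSV (time, channel, oxy, deoxy)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time", "channel", "oxy", "deoxy"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long format needs columns {sorted(required)}")
    wide_o = df.pivot(index="time", columns="channel", values="oxy").sort_index()
    wide_d = df.pivot(index="time", columns="channel", values="deoxy").sort_index()
    ids = [str(c) for c in wide_o.columns]
    if wide_o.isna().any().any() or wide_d.isna().any().any():
        raise ValueError(f"{path}: missing (time, channel) combinations")
    return Recording(sampling_rate_hz, ids, wide_o.to_numpy(float),
                     wide_d.to_numpy(float), t0_s=float(wide_o.index[0]))


def write_recording(rec: Recording, path_oxy: str | Path, path_deoxy: str | Path) -> None:
    """Write time-major CSVs (header = channel ids) at full double precision."""
    for path, data in ((path_oxy, rec.oxy), (path_deoxy, rec.deoxy)):
        pd.DataFrame(data, columns=rec.channel_ids).to_csv(
            path, index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path, total_duration_s: float | None = None) -> EventSchedule:
    """Load an EventSchedule from JSON ([{onset, duration}, ...] or
    {"total_duration_s": ..., "blocks": [...]}) or a 2-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            total_duration_s = payload.get("total_duration_s", total_duration_s)
            payload = payload["blocks"]
        blocks = [(b["onset"], b["duration"]) for b in payload]
    else:
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        if "onset" in cols and "duration" in cols:
            blocks = list(zip(df[df.columns[cols.index("onset")]],
                              df[df.columns[cols.index("duration")]]))
        else:
            blocks = list(df.iloc[:, :2].itertuples(index=False, name=None))
    return EventSchedule(blocks, total_duration_s)


def write_events(events: EventSchedule, path: str | Path) -> None:
    payload = {
        "total_duration_s": events.total_duration_s,
        "blocks": [{"onset": o, "duration": d} for o, d in events.blocks],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
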