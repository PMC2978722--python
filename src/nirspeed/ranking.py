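"""Contrast-to-noise-ratio (CNR) channel ranking.

CNR scores how strongly a channel responds to the task:
``(mean(task) - mean(rest)) / s_pooled``, where the task window (default
6-12 s after block onset, to account for the hemodynamic delay) and the rest
window (default the 5 s before onset) are pooled across blocks and
``s_pooled`` is the classical two-sample pooled standard deviation.
Channels are entered into spatial feature spaces in decreasing CNR order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventSchedule, Recording

__all__ = ["CnrWindows", "cnr", "rank_channels"]


@dataclass(frozen=True)
class CnrWindows:
    """Task and rest windows in seconds relative to each block's onset."""

    task_window_s: tuple[float, float] = (6.0, 12.0)
    rest_window_s: tuple[float, float] = (-5.0, 0.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("task", self.task_window_s), ("rest", self.rest_window_s)):
            if lo >= hi:
                raise ValueError(f"{name} window bounds must be ordered, got ({lo}, {hi})")


def _window_indices(onset_s: float, window: tuple[float, float],
                    fs: float, n_samples: int) -> np.ndarray:
    """Sample indices k with onset + lo <= k/fs < onset + hi (half-open)."""
    lo = int(np.ceil((onset_s + window[0]) * fs - 1e-9))
    hi = int(np.ceil((onset_s + window[1]) * fs - 1e-9))
    if lo < 0 or hi > n_samples:
        raise ValueError(
            f"window ({window[0]}, {window[1]}) s around onset {onset_s} s "
            f"falls outside the recording")
    return np.arange(lo, hi)


def cnr(x: np.ndarray, events: EventSchedule, fs: float,
        windows: CnrWindows = CnrWindows(), mode: str = "pooled_samples") -> float:
    """Contrast-to-noise ratio of one channel series over a block schedule.

    ``mode='pooled_samples'`` (default) pools raw samples across blocks;
    ``mode='block_average'`` first averages the task/rest windows across
    blocks into a mean trace and computes the same statistic on it.
    """
    x = np.asarray(x, dtype=float)
    if events.n_blocks < 1:
        raise ValueError("need at least one block")
    if mode not in ("pooled_samples", "block_average"):
        raise ValueError(f"unknown CNR mode {mode!r}")

    task_idx = [_window_indices(o, windows.task_window_s, fs, x.shape[0])
                for o, _ in events.blocks]
    rest_idx = [_window_indices(o, windows.rest_window_s, fs, x.shape[0])
                for o, _ in events.blocks]
    if mode == "pooled_samples":
        task = x[np.concatenate(task_idx)]
        rest = x[np.concatenate(rest_idx)]
    else:
        task = np.mean([x[i] for i in task_idx], axis=0)
        rest = np.mean([x[i] for i in rest_idx], axis=0)

    n1, n2 = task.size, rest.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples in both the task and rest class")
    s1, s2 = np.var(task, ddof=1), np.var(rest, ddof=1)
    s_pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    return float((task.mean() - rest.mean()) / s_pooled)


#: relative tolerance below which two CNR values count as tied
_TIE_RTOL = 1e-9


def rank_channels(rec: Recording, events: EventSchedule,
                  windows: CnrWindows = CnrWindows(), chromophore: str = "oxy",
                  mode: str = "pooled_samples") -> list[tuple[str, float]]:
    """Channels sorted by decreasing CNR; ties keep original channel order.

    Two CNR values within a relative 1e-9 of each other are treated as tied
    (pure floating-point rounding must not reorder genuinely identical
    channels, e.g. channels differing only by a positive gain).  ``events``
    should contain only the training blocks so that ranking never sees test
    data.
    """
    data = rec.signal(chromophore)
    values = np.array([cnr(data[:, c], events, rec.sampling_rate_hz, windows, mode)
                       for c in range(rec.n_channels)])
    scale = np.max(np.abs(values))
    keys = np.round(values / (scale * _TIE_RTOL)) if scale > 0 else values
    order = np.argsort(-keys, kind="stable")
    return [(rec.channel_ids[i], float(values[i])) for i in order]
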