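"""Block-design fNIRS simulator with known ground truth.

Emulates a finger-tapping-style optical topography session: task blocks
(default 10 s) alternating with rest (default 20 s) at 10 Hz, recorded over
many channels whose activation amplitudes decay geometrically — so channel
ranking has a well-defined true order.  Each channel's oxy-Hb trace is an
amplitude-scaled boxcar-convolved hemodynamic response plus low-frequency
drift and white instrument noise; deoxy-Hb is the anti-correlated,
optionally lagged mirror (default ratio -0.35).

The schedule starts with one full rest period before the first block, so a
pre-onset baseline window always exists, and ends with a trailing rest so
offset detection has room to search.

Amplitudes are in the same arbitrary concentration-change units as real
recordings; defaults (peak response 1.0, noise SD 0.15, drift 0.1) are
chosen so a single-threshold baseline decoder detects onsets near the
hemodynamic peak delay, matching the qualitative behavior of human
block-design data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import EventSchedule, Recording

__all__ = [
    "HrfParams",
    "DriftParams",
    "SimulationSpec",
    "hemodynamic_response",
    "generate_recording",
    "enumerate_probe_channels",
    "probe_channel_count",
]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response: a ~6 s-peaking positive lobe minus
    a delayed undershoot, normalized to unit peak amplitude.

    ``dispersion_s`` is the gamma time scale; the default (0.5 s, with a
    0.4 undershoot) gives the brisk rise and prompt post-stimulus return of
    a strong motor response, so that a single-threshold decoder detects
    block onsets near the peak delay rather than never at all."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    undershoot_ratio: float = 0.4
    dispersion_s: float = 0.5

    def __post_init__(self) -> None:
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("HRF delays must be positive")
        if self.dispersion_s <= 0:
            raise ValueError("dispersion_s must be positive")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must be in [0, 1)")


@dataclass(frozen=True)
class DriftParams:
    """Slow nuisance drift: random-phase sinusoids below max_freq_hz plus a
    linear trend; amplitude 0 disables drift entirely."""

    n_sinusoids: int = 3
    max_freq_hz: float = 0.05
    amplitude: float = 0.1


@dataclass(frozen=True)
class SimulationSpec:
    n_channels: int = 48
    n_trials: int = 10
    task_s: float = 10.0
    rest_s: float = 20.0
    fs_hz: float = 10.0
    hrf: HrfParams = field(default_factory=HrfParams)
    #: per-channel oxy activation gains; None -> geometric decay a * r**c
    channel_amplitudes: tuple[float, ...] | None = None
    amplitude_scale: float = 1.0
    amplitude_decay: float = 0.85
    deoxy_ratio: float = -0.35
    deoxy_lag_s: float = 0.0
    drift: DriftParams = field(default_factory=DriftParams)
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials (train/test split needs both halves)")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.noise_sd < 0 or self.deoxy_lag_s < 0:
            raise ValueError("noise_sd and deoxy_lag_s must be non-negative")
        amps = self.resolved_amplitudes()
        if not (amps >= 0).all() or not (amps > 0).any():
            raise ValueError("channel amplitudes must be >= 0 with at least one > 0")
        if self.channel_amplitudes is not None and len(self.channel_amplitudes) != self.n_channels:
            raise ValueError("channel_amplitudes length must equal n_channels")

    def resolved_amplitudes(self) -> np.ndarray:
        if self.channel_amplitudes is not None:
            return np.asarray(self.channel_amplitudes, dtype=float)
        c = np.arange(self.n_channels)
        return self.amplitude_scale * self.amplitude_decay**c

    def schedule(self) -> EventSchedule:
        """Lead-in rest, then n_trials alternating task/rest blocks."""
        onsets = self.rest_s + np.arange(self.n_trials) * (self.task_s + self.rest_s)
        total = self.rest_s + self.n_trials * (self.task_s + self.rest_s)
        return EventSchedule([(o, self.task_s) for o in onsets], total)


def hemodynamic_response(t_grid: np.ndarray, hrf: HrfParams = HrfParams()) -> np.ndarray:
    """Canonical double-gamma response sampled at ``t_grid`` (seconds).

    The positive lobe is a gamma density with mode at ``peak_delay_s``
    (time scale ``dispersion_s``, shape = delay / scale + 1), the undershoot
    a gamma density with mode at ``undershoot_delay_s`` scaled by
    ``undershoot_ratio``; the difference is normalized to unit peak.
    Causal: the response is exactly 0 at t = 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and (np.diff(t_grid) <= 0).any():
        raise ValueError("t_grid must be strictly increasing")
    if t_grid.size and t_grid[0] < 0:
        raise ValueError("t_grid must be non-negative")
    raw = _hrf_raw(t_grid, hrf)
    return raw / _hrf_peak(hrf)


def _hrf_raw(t: np.ndarray, hrf: HrfParams) -> np.ndarray:
    s = hrf.dispersion_s  # gamma mode = (shape - 1) * scale = delay
    a1 = hrf.peak_delay_s / s + 1.0
    a2 = hrf.undershoot_delay_s / s + 1.0
    return (stats.gamma.pdf(t, a1, scale=s)
            - hrf.undershoot_ratio * stats.gamma.pdf(t, a2, scale=s))


def _hrf_peak(hrf: HrfParams) -> float:
    dense = np.arange(0.0, 2.0 * hrf.undershoot_delay_s, 1e-3)
    return float(_hrf_raw(dense, hrf).max())


def _boxcar(events: EventSchedule, n_samples: int, fs: float, lag_s: float = 0.0) -> np.ndarray:
    box = np.zeros(n_samples)
    for onset, dur in events.blocks:
        lo = int(np.ceil((onset + lag_s) * fs - 1e-9))
        hi = int(np.ceil((onset + lag_s + dur) * fs - 1e-9))
        box[max(lo, 0):min(hi, n_samples)] = 1.0
    return box


def _drift_trace(n: int, fs: float, drift: DriftParams, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    if drift.amplitude <= 0:
        return out
    for _ in range(drift.n_sinusoids):
        amp = rng.uniform(0, drift.amplitude)
        freq = rng.uniform(0.002, drift.max_freq_hz)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.sin(2 * np.pi * freq * t + phase)
    slope = rng.uniform(-drift.amplitude, drift.amplitude) / t[-1] if n > 1 else 0.0
    return out + slope * t


def generate_recording(spec: SimulationSpec) -> tuple[Recording, EventSchedule, np.ndarray]:
    """Simulate one session; returns (recording, schedule, true amplitudes).

    Fully reproducible from ``spec.seed``: the same spec yields bit-identical
    output.  The noiseless oxy signal of channel c is
    ``amplitude_c * (boxcar (*) HRF)``, rescaled so an isolated task block
    peaks at exactly ``amplitude_c``; deoxy is ``deoxy_ratio`` times the
    (lagged) response.  Drift and Gaussian noise are drawn independently per
    channel and chromophore.
    """
    rng = np.random.default_rng(spec.seed)
    events = spec.schedule()
    fs = spec.fs_hz
    n = int(round(events.total_duration_s * fs))
    amps = spec.resolved_amplitudes()

    kernel_t = np.arange(0.0, 2.5 * spec.hrf.undershoot_delay_s, 1.0 / fs)
    h = hemodynamic_response(kernel_t, spec.hrf)
    # single isolated block sets the peak-normalization of the block response
    block_box = np.zeros(int((spec.task_s + 3 * spec.hrf.undershoot_delay_s) * fs))
    block_box[: int(round(spec.task_s * fs))] = 1.0
    peak = np.convolve(block_box, h).max()

    resp_oxy = np.convolve(_boxcar(events, n, fs), h)[:n] / peak
    resp_deoxy = np.convolve(_boxcar(events, n, fs, spec.deoxy_lag_s), h)[:n] / peak

    oxy = np.empty((n, spec.n_channels))
    deoxy = np.empty((n, spec.n_channels))
    for c in range(spec.n_channels):
        oxy[:, c] = (amps[c] * resp_oxy
                     + _drift_trace(n, fs, spec.drift, rng)
                     + rng.normal(0, spec.noise_sd, n))
        deoxy[:, c] = (spec.deoxy_ratio * amps[c] * resp_deoxy
                       + _drift_trace(n, fs, spec.drift, rng)
                       + rng.normal(0, spec.noise_sd, n))

    ids = [f"ch{c + 1}" for c in range(spec.n_channels)]
    return Recording(fs, ids, oxy, deoxy), events, amps


def enumerate_probe_channels(rows: int = 4, cols: int = 4) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Enumerate measurement channels of one rows x cols optode patch.

    Emitters and detectors alternate in a checkerboard, so every
    grid-adjacent optode pair is an emitter-detector pair, i.e. one
    measurement channel.  Returns (emitter_pos, detector_pos) tuples.
    """
    channels = []
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < rows and c2 < cols:
                    a, b = (r, c), (r2, c2)
                    if (r + c) % 2 == 1:  # emitter listed first
                        a, b = b, a
                    channels.append((a, b))
    return channels


def probe_channel_count(rows: int = 4, cols: int = 4, n_patches: int = 2) -> int:
    """Total measurement channels across identical patches (default 2x 4x4)."""
    return n_patches * len(enumerate_probe_channels(rows, cols))
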