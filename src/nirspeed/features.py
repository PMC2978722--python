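"""Feature-space construction for per-timepoint decoding.

Each sample becomes one classification instance.  A feature space is built
per channel and per chromophore combination from the filtered signal:

* ``amplitude`` — the current sample plus ``y`` lagged samples of history,
  giving ``y + 1`` columns per series.
* ``gradient1`` / ``gradient2`` — the current amplitude plus ``y`` columns of
  first/second-order finite differences at lags ``0..y-1`` (dimension-matched
  to the amplitude space; a linear classifier can represent either, since
  gradients are differences of adjacent amplitude columns).

Chromophore combinations: ``oxy``, ``deoxy``, ``both`` (doubles the columns),
``total`` (oxy + deoxy), and ``cbsi`` (correlation-based signal improvement —
the anti-correlation-weighted difference that suppresses common-mode noise).

Rows whose history window reaches before the start of the recording are
flagged invalid rather than zero-padded and are excluded from training and
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "gradient",
    "cbsi_correct",
    "total_hb",
    "assemble_features",
]

SIGNAL_COMBOS = ("oxy", "deoxy", "both", "total", "cbsi")
REPRESENTATIONS = ("amplitude", "gradient1", "gradient2")


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of a feature space.

    ``history_s`` is converted to a lag count y = round(history_s * fs); the
    per-series column count is always y + 1.
    """

    channels: tuple[str, ...]
    history_s: float = 0.0
    representation: str = "amplitude"
    signals: str = "oxy"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FeatureSpec needs at least one channel")
        if self.history_s < 0:
            raise ValueError("history_s must be >= 0")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.signals not in SIGNAL_COMBOS:
            raise ValueError(f"signals must be one of {SIGNAL_COMBOS}")
        object.__setattr__(self, "channels", tuple(self.channels))

    def n_lags(self, fs_hz: float) -> int:
        return int(round(self.history_s * fs_hz))

    @property
    def n_series_per_channel(self) -> int:
        return 2 if self.signals == "both" else 1

    def n_columns(self, fs_hz: float) -> int:
        return (self.n_lags(fs_hz) + 1) * self.n_series_per_channel * len(self.channels)


@dataclass
class FeatureMatrix:
    """Realized design matrix with a per-row validity mask."""

    X: np.ndarray
    valid: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match X columns")
        if self.X.shape[0] != self.valid.shape[0]:
            raise ValueError("valid mask length must match X rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def gradient(x: np.ndarray, order: int = 1) -> np.ndarray:
    """Backward finite difference: order 1 is x(t) - x(t-1), order 2 the
    gradient of the gradient, i.e. x(t) - 2x(t-1) + x(t-2).

    The first ``order`` outputs have no complete stencil and are returned as
    NaN (flagged invalid downstream).
    """
    x = np.asarray(x, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if x.shape[0] < order + 1:
        raise ValueError(f"series of length {x.shape[0]} too short for order {order}")
    out = np.full_like(x, np.nan)
    if order == 1:
        out[1:] = x[1:] - x[:-1]
    else:
        out[2:] = x[2:] - 2 * x[1:-1] + x[:-2]
    return out


def cbsi_correct(oxy: np.ndarray, deoxy: np.ndarray,
                 fit_slice: slice | None = None) -> np.ndarray:
    """Correlation-based signal improvement: (oxy - alpha * deoxy) / 2 with
    alpha = sd(oxy) / sd(deoxy).

    Exploits the physiological anti-correlation of the two chromophores:
    common-mode (e.g. motion) components, which move both signals the same
    way, cancel.  ``fit_slice`` restricts the alpha estimate (e.g. to the
    training portion) to avoid test-set leakage; the correction itself is
    applied to the whole series.
    """
    oxy = np.asarray(oxy, dtype=float)
    deoxy = np.asarray(deoxy, dtype=float)
    if oxy.shape != deoxy.shape:
        raise ValueError("oxy and deoxy must have equal length")
    if oxy.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    fit = fit_slice if fit_slice is not None else slice(None)
    sd_d = float(np.std(deoxy[fit]))
    if sd_d == 0:
        raise ValueError("deoxy is constant over the fit range; CBSI alpha undefined")
    alpha = float(np.std(oxy[fit])) / sd_d
    return (oxy - alpha * deoxy) / 2.0


def total_hb(oxy: np.ndarray, deoxy: np.ndarray) -> np.ndarray:
    """Total hemoglobin: elementwise oxy + deoxy."""
    oxy = np.asarray(oxy, dtype=float)
    deoxy = np.asarray(deoxy, dtype=float)
    if oxy.shape != deoxy.shape:
        raise ValueError("oxy and deoxy must have equal length")
    return oxy + deoxy


def _series_for(rec: Recording, channel: str, signals: str,
                train_end: int | None) -> list[tuple[str, np.ndarray]]:
    c = rec.channel_index(channel)
    oxy, deoxy = rec.oxy[:, c], rec.deoxy[:, c]
    if signals == "oxy":
        return [("oxy", oxy)]
    if signals == "deoxy":
        return [("deoxy", deoxy)]
    if signals == "both":
        return [("oxy", oxy), ("deoxy", deoxy)]
    if signals == "total":
        return [("total", total_hb(oxy, deoxy))]
    fit = slice(0, train_end) if train_end is not None else None
    return [("cbsi", cbsi_correct(oxy, deoxy, fit))]


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    if lag == 0:
        return x
    out = np.full_like(x, np.nan)
    out[lag:] = x[:-lag]
    return out


def assemble_features(rec: Recording, spec: FeatureSpec,
                      train_end: int | None = None) -> FeatureMatrix:
    """Build the n_samples x m design matrix for a feature spec.

    Columns are ordered channel-major, then series, then lag 0..y.  For the
    gradient representations the lag-0 column is the raw amplitude and the
    remaining y columns are gradients at lags 0..y-1.  Features at row t
    only ever reference samples at or before t (causal), so the matrix can
    be computed incrementally in deployment.

    ``train_end`` (sample index) bounds the CBSI alpha estimate to the
    training portion.
    """
    unknown = [ch for ch in spec.channels if ch not in rec.channel_ids]
    if unknown:
        raise KeyError(f"unknown channels: {unknown}")
    y = spec.n_lags(rec.sampling_rate_hz)
    if y >= rec.n_samples:
        raise ValueError(f"history of {y} samples >= recording length {rec.n_samples}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    for ch in spec.channels:
        for sig_name, series in _series_for(rec, ch, spec.signals, train_end):
            if spec.representation == "amplitude":
                for lag in range(y + 1):
                    cols.append(_lagged(series, lag))
                    names.append(f"{ch}/{sig_name}/amp{lag}")
            else:
                order = 1 if spec.representation == "gradient1" else 2
                cols.append(series)
                names.append(f"{ch}/{sig_name}/amp0")
                grad = gradient(series, order) if y > 0 else None
                for lag in range(y):
                    cols.append(_lagged(grad, lag))
                    names.append(f"{ch}/{sig_name}/d{order}lag{lag}")

    X = np.column_stack(cols)
    valid = ~np.isnan(X).any(axis=1)
    return FeatureMatrix(X, valid, names)
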