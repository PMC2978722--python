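"""Causal exponential-moving-average (EMA) band-pass filtering.

The filter computes a short-span EMA ``S`` (tracks the signal, removes
high-frequency instrument noise) and a long-span EMA ``L`` (tracks slow
drift) and returns ``g = S - L``.  Both recursions are seeded with the first
sample, so ``g(0) = 0`` and there is no startup transient.  The output at
time ``t`` depends only on samples ``0..t`` — the filter is usable sample by
sample in a real-time decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .io import Recording

__all__ = ["EmaParams", "ema_ma", "ema_filter", "filter_recording"]

_LAMBDA_RULES = ("standard", "reciprocal")


@dataclass(frozen=True)
class EmaParams:
    """Spans (in samples) of the long- and short-term moving averages.

    ``lambda_rule`` maps a span ``alpha`` to the recursion weight:
    ``standard`` uses the conventional EMA weight 2/(alpha+1) (an
    alpha-sample window), ``reciprocal`` uses 1/alpha.
    """

    alpha_long: float = 100.0
    alpha_short: float = 20.0
    lambda_rule: str = "standard"

    def __post_init__(self) -> None:
        if self.alpha_long <= 1 or self.alpha_short <= 1:
            raise ValueError("EMA spans must exceed 1 sample")
        if self.alpha_short >= self.alpha_long:
            raise ValueError("alpha_short must be smaller than alpha_long")
        if self.lambda_rule not in _LAMBDA_RULES:
            raise ValueError(f"lambda_rule must be one of {_LAMBDA_RULES}")

    def short_window_s(self, fs_hz: float) -> float:
        """Duration of the short-term averaging window at sampling rate fs."""
        return self.alpha_short / fs_hz

    def long_window_s(self, fs_hz: float) -> float:
        return self.alpha_long / fs_hz


def _lambda(alpha: float, lambda_rule: str) -> float:
    if alpha <= 1:
        raise ValueError(f"EMA span must exceed 1 sample, got {alpha}")
    if lambda_rule == "standard":
        return 2.0 / (alpha + 1.0)
    if lambda_rule == "reciprocal":
        return 1.0 / alpha
    raise ValueError(f"lambda_rule must be one of {_LAMBDA_RULES}")


def ema_ma(x: np.ndarray, alpha: float, lambda_rule: str = "standard") -> np.ndarray:
    """Exponential moving average M(t) = lam*x(t) + (1-lam)*M(t-1), M(0)=x(0).

    Accepts a 1-D series or a time-major 2-D array (filtered per column).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 1:
        raise ValueError("series must have at least one sample")
    lam = _lambda(alpha, lambda_rule)
    # IIR form: y[t] - (1-lam) y[t-1] = lam x[t]; initial condition y[-1] = x[0]
    zi = (1.0 - lam) * x[:1]  # shape (1,) or (1, n_channels)
    out, _ = lfilter([lam], [1.0, -(1.0 - lam)], x, axis=0, zi=zi)
    return out


def ema_filter(x: np.ndarray, params: EmaParams = EmaParams()) -> np.ndarray:
    """Band-pass by EMA difference: g = S(alpha_short) - L(alpha_long)."""
    s = ema_ma(x, params.alpha_short, params.lambda_rule)
    l = ema_ma(x, params.alpha_long, params.lambda_rule)
    return s - l


def filter_recording(rec: Recording, params: EmaParams = EmaParams()) -> Recording:
    """Apply the EMA filter independently to every channel and chromophore."""
    return replace(
        rec,
        oxy=ema_filter(rec.oxy, params),
        deoxy=ema_filter(rec.deoxy, params),
        channel_ids=list(rec.channel_ids),
    )
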