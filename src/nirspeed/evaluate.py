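"""Accuracy and detection-latency metrics, plus the sweep experiments.

The figure of merit of a real-time hemodynamic decoder is not only how many
samples it labels correctly but how quickly it reflects a change of
behavioral state:

* **onset delay** — time from a task block's onset to the first sample the
  classifier labels active, searched forward within that trial;
* **offset delay** — time from the block's offset to the first sample
  labeled inactive.

Trials where no qualifying sample occurs before the next block are censored
and excluded from the means (with the censor count reported).  Sweeps vary
one axis of the feature space at a time — history length, gradient order,
chromophore combination, channel count — holding everything else fixed, and
``run_full_pipeline`` assembles the four-condition comparison (baseline,
+history, +deoxy, +channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .decode import label_timepoints, predict, split_trials, train_classifier
from .features import SIGNAL_COMBOS, FeatureSpec, assemble_features
from .io import EventSchedule, Recording
from .preprocess import filter_recording
from .ranking import rank_channels

__all__ = [
    "DelayResult",
    "ConditionResult",
    "SweepResult",
    "accuracy",
    "onset_offset_delays",
    "evaluate_feature_space",
    "sweep_history",
    "sweep_signals",
    "sweep_channels",
    "run_full_pipeline",
    "cohort_report",
]


def accuracy(pred: np.ndarray, truth: np.ndarray,
             valid_mask: np.ndarray | None = None) -> float:
    """Fraction of valid samples where pred == truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if valid_mask is None:
        valid_mask = np.ones(pred.shape, dtype=bool)
    n = int(valid_mask.sum())
    if n == 0:
        raise ValueError("no valid samples to score")
    return float((pred[valid_mask] == truth[valid_mask]).sum() / n)


@dataclass
class DelayResult:
    """Per-trial onset/offset delays (seconds; NaN = censored) with summary
    statistics over the uncensored trials (SE uses the n-1 denominator)."""

    onset_delays_s: np.ndarray
    offset_delays_s: np.ndarray

    @property
    def onset_censored(self) -> np.ndarray:
        return np.isnan(self.onset_delays_s)

    @property
    def offset_censored(self) -> np.ndarray:
        return np.isnan(self.offset_delays_s)

    @property
    def censor_count(self) -> int:
        return int(self.onset_censored.sum() + self.offset_censored.sum())

    @property
    def mean_onset_s(self) -> float:
        return _nan_stat(self.onset_delays_s, np.mean)

    @property
    def mean_offset_s(self) -> float:
        return _nan_stat(self.offset_delays_s, np.mean)

    @property
    def se_onset_s(self) -> float:
        return _nan_se(self.onset_delays_s)

    @property
    def se_offset_s(self) -> float:
        return _nan_se(self.offset_delays_s)


def _nan_stat(x: np.ndarray, f) -> float:
    x = x[~np.isnan(x)]
    return float(f(x)) if x.size else float("nan")


def _nan_se(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def onset_offset_delays(pred: np.ndarray, events: EventSchedule, fs: float,
                        t0_s: float = 0.0) -> DelayResult:
    """Detection latencies of a per-sample prediction over test blocks.

    For block b the onset delay is the time of the first +1 prediction in
    [onset_b, next_onset_b), minus onset_b; the offset delay uses the first
    -1 in [offset_b, next_onset_b).  next_onset is the following block's
    onset or the end of the prediction.  A trial with no qualifying sample
    is censored (NaN).
    """
    pred = np.asarray(pred)
    n = pred.shape[0]
    end_time = t0_s + n / fs
    onsets, offsets = [], []
    for b, (onset, dur) in enumerate(events.blocks):
        next_onset = events.blocks[b + 1][0] if b + 1 < events.n_blocks else end_time
        if onset + dur > end_time + 1e-9:
            raise ValueError(f"block ({onset}, {dur}) outside prediction range")
        onsets.append(_first_hit(pred, +1, onset, next_onset, fs, t0_s))
        offsets.append(_first_hit(pred, -1, onset + dur, next_onset, fs, t0_s))
    return DelayResult(np.array(onsets), np.array(offsets))


def _first_hit(pred: np.ndarray, target: int, start_s: float, end_s: float,
               fs: float, t0_s: float) -> float:
    lo = int(np.ceil((start_s - t0_s) * fs - 1e-9))
    hi = min(int(np.ceil((end_s - t0_s) * fs - 1e-9)), pred.shape[0])
    hits = np.nonzero(pred[lo:hi] == target)[0]
    if hits.size == 0:
        return float("nan")
    return float((lo + hits[0]) / fs + t0_s - start_s)


@dataclass
class ConditionResult:
    """Outcome of one feature-space condition on the test half."""

    spec: FeatureSpec
    accuracy: float
    delays: DelayResult
    model: object = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mean_onset_delay_s": self.delays.mean_onset_s,
            "mean_offset_delay_s": self.delays.mean_offset_s,
            "se_onset_delay_s": self.delays.se_onset_s,
            "se_offset_delay_s": self.delays.se_offset_s,
            "censor_count": self.delays.censor_count,
        }


def evaluate_feature_space(rec: Recording, events: EventSchedule,
                           cfg: PipelineConfig, spec: FeatureSpec,
                           prefiltered: bool = False) -> ConditionResult:
    """Train on the first half of trials, score accuracy and delays on the
    second half, for one feature spec.

    ``prefiltered=True`` skips the EMA stage (the recording is already
    filtered); otherwise filtering is applied here.
    """
    filt = rec if prefiltered else filter_recording(rec, cfg.ema)
    fs = filt.sampling_rate_hz
    n = filt.n_samples
    split = split_trials(events, n, fs)
    labels = label_timepoints(events, n, fs, filt.t0_s)
    fm = assemble_features(filt, spec, train_end=split.train_range[1])

    idx = np.arange(n)
    in_train = (idx >= split.train_range[0]) & (idx < split.train_range[1])
    in_test = (idx >= split.test_range[0]) & (idx < split.test_range[1])

    model = train_classifier(fm, labels, cfg.svm_c, row_mask=in_train,
                             feature_spec=spec)
    pred = predict(model, fm)
    acc = accuracy(pred, labels, in_test & fm.valid)
    test_events = events.subset(split.test_blocks)
    delays = onset_offset_delays(pred, test_events, fs, filt.t0_s)
    return ConditionResult(spec, acc, delays, model)


@dataclass
class SweepResult:
    """Metrics along one axis of the feature space, plus the accuracy-
    maximizing value (first value on ties)."""

    axis_name: str
    values: list
    accuracies: list[float]
    mean_onset_s: list[float]
    mean_offset_s: list[float]
    results: list[ConditionResult] = field(repr=False, default_factory=list)

    @property
    def optimum(self):
        return self.values[int(np.argmax(self.accuracies))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.axis_name: self.values,
            "accuracy": self.accuracies,
            "mean_onset_delay_s": self.mean_onset_s,
            "mean_offset_delay_s": self.mean_offset_s,
        })


def _best_channel(filt: Recording, train_events: EventSchedule,
                  cfg: PipelineConfig) -> list[str]:
    ranking = rank_channels(filt, train_events, cfg.cnr_windows,
                            cfg.rank_chromophore, cfg.cnr_mode)
    return [ch for ch, _ in ranking]


def _prepare(rec: Recording, events: EventSchedule, cfg: PipelineConfig):
    filt = filter_recording(rec, cfg.ema)
    split = split_trials(events, filt.n_samples, filt.sampling_rate_hz)
    train_events = events.subset(split.train_blocks)
    ranked = _best_channel(filt, train_events, cfg)
    return filt, split, ranked


def sweep_history(rec: Recording, events: EventSchedule, cfg: PipelineConfig,
                  history_values_s: list[float], signals: str = "oxy",
                  representation: str = "amplitude") -> SweepResult:
    """Vary the history length on the best-CNR channel, all else fixed."""
    filt, _, ranked = _prepare(rec, events, cfg)
    results = []
    for h in history_values_s:
        spec = FeatureSpec(channels=(ranked[0],), history_s=h,
                           representation=representation, signals=signals)
        results.append(evaluate_feature_space(filt, events, cfg, spec, prefiltered=True))
    return _collect("history_s", list(history_values_s), results)


def sweep_signals(rec: Recording, events: EventSchedule, cfg: PipelineConfig,
                  history_s: float | None = None) -> SweepResult:
    """Compare the five chromophore combinations on the best-CNR channel.

    Delays are reported as NaN for combinations whose accuracy falls below
    ``cfg.delay_accuracy_floor`` (an unreliable decoder's latency is not
    meaningful).
    """
    if history_s is None:
        history_s = cfg.history_s
    filt, _, ranked = _prepare(rec, events, cfg)
    results = []
    for sig in SIGNAL_COMBOS:
        spec = FeatureSpec(channels=(ranked[0],), history_s=history_s, signals=sig)
        results.append(evaluate_feature_space(filt, events, cfg, spec, prefiltered=True))
    sweep = _collect("signals", list(SIGNAL_COMBOS), results)
    for i, acc in enumerate(sweep.accuracies):
        if acc < cfg.delay_accuracy_floor:
            sweep.mean_onset_s[i] = float("nan")
            sweep.mean_offset_s[i] = float("nan")
    return sweep


def sweep_channels(rec: Recording, events: EventSchedule, cfg: PipelineConfig,
                   max_channels: int | None = None, history_s: float | None = None,
                   signals: str = "both") -> SweepResult:
    """Add channels one by one in decreasing training-half CNR order."""
    if max_channels is None:
        max_channels = min(cfg.max_channels, rec.n_channels)
    if max_channels > rec.n_channels:
        raise ValueError(f"max_channels {max_channels} exceeds {rec.n_channels} channels")
    if history_s is None:
        history_s = cfg.history_s
    filt, _, ranked = _prepare(rec, events, cfg)
    results = []
    for k in range(1, max_channels + 1):
        spec = FeatureSpec(channels=tuple(ranked[:k]), history_s=history_s,
                           signals=signals)
        results.append(evaluate_feature_space(filt, events, cfg, spec, prefiltered=True))
    return _collect("n_channels", list(range(1, max_channels + 1)), results)


def _collect(axis: str, values: list, results: list[ConditionResult]) -> SweepResult:
    return SweepResult(
        axis_name=axis,
        values=values,
        accuracies=[r.accuracy for r in results],
        mean_onset_s=[r.delays.mean_onset_s for r in results],
        mean_offset_s=[r.delays.mean_offset_s for r in results],
        results=results,
    )


CONDITION_NAMES = ("baseline", "history", "oxy_deoxy", "multichannel")


def run_full_pipeline(rec: Recording, events: EventSchedule,
                      cfg: PipelineConfig) -> dict:
    """Four-condition comparison on one recording.

    baseline: amplitude of the best-CNR channel's oxy signal only (a
    single-threshold decoder); history: + ``cfg.history_s`` of amplitude
    history; oxy_deoxy: + the deoxy signal; multichannel: + additional
    channels in decreasing CNR order, keeping the accuracy-maximizing count
    (selected on the test half — an optimistic, replication-faithful
    choice).
    """
    filt, _, ranked = _prepare(rec, events, cfg)
    best = ranked[0]
    conditions: dict[str, ConditionResult] = {}
    conditions["baseline"] = evaluate_feature_space(
        filt, events, cfg,
        FeatureSpec(channels=(best,), history_s=0.0, signals="oxy"), prefiltered=True)
    conditions["history"] = evaluate_feature_space(
        filt, events, cfg,
        FeatureSpec(channels=(best,), history_s=cfg.history_s, signals="oxy"),
        prefiltered=True)
    conditions["oxy_deoxy"] = evaluate_feature_space(
        filt, events, cfg,
        FeatureSpec(channels=(best,), history_s=cfg.history_s, signals="both"),
        prefiltered=True)
    chan_sweep = sweep_channels(rec, events, cfg)
    k = chan_sweep.optimum
    conditions["multichannel"] = chan_sweep.results[k - 1]

    return {
        "conditions": {name: conditions[name].summary() for name in CONDITION_NAMES},
        "channel_ranking": ranked,
        "n_channels_selected": int(k),
    }


def cohort_report(cohort: list[tuple[Recording, EventSchedule]],
                  cfg: PipelineConfig) -> dict:
    """Run the full pipeline on every recording and aggregate.

    Aggregate means are the plain mean of per-recording values (NaN-aware
    for delays, since a condition may be fully censored on one recording).
    """
    per_recording = [run_full_pipeline(rec, ev, cfg) for rec, ev in cohort]
    aggregate = {}
    for name in CONDITION_NAMES:
        agg = {}
        for metric in ("accuracy", "mean_onset_delay_s", "mean_offset_delay_s"):
            vals = np.array([r["conditions"][name][metric] for r in per_recording])
            agg[metric] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
        aggregate[name] = agg
    return {"per_recording": per_recording, "aggregate": aggregate,
            "n_recordings": len(cohort)}
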