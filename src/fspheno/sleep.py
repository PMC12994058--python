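"""Sleep-architecture metrics from hypnograms and a rule-based epoch scorer.

A hypnogram is a sequence of vigilance states — WAKE, slow-wave sleep (SWS)
and REM (paradoxical) sleep — in fixed 5-s epochs over a 24-h recording.
From it we derive, per state: percentage of time, episode number, mean
episode duration, and the sleep-onset latency defined as the start of the
first episode lasting at least 25 s (5 epochs).  At baseline the origin is
lights-on; fourteen days after stress the origin is the moment the cue
reminder is placed in the recording box (both coincide with epoch 0 of the
recording).

An episode is a maximal run of identical epochs; no smoothing or merging of
brief interruptions is applied by default (a merge-gap option exists but
defaults off), so every metric is exactly auditable from the raw sequence.

The epoch classifier is a deliberately simple decision rule over per-epoch
EMG power and EEG band powers, mirroring the spectral signatures of the
three states: wake has high, variable EMG; SWS has low EMG and dominant
delta (1-4 Hz); REM has muscle atonia and a theta-dominated (5-9 Hz) EEG,
detected here by the theta/delta ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import Direction, Rule, ThresholdSet, VariableSpec, assign_score, build_thresholds

__all__ = [
    "STATES",
    "Hypnogram",
    "SleepMetrics",
    "ClassifierConfig",
    "episodes",
    "percent_time",
    "sleep_onset_latency",
    "sleep_metrics",
    "classify_epochs",
    "sleep_radar_scores",
    "cohort_sleep_metrics",
]

STATES = ("WAKE", "SWS", "REM")
SLEEP_STATES = ("SWS", "REM")


@dataclass
class Hypnogram:
    """Vigilance-state sequence in fixed epochs.

    ``origin`` records what epoch 0 means for latency measurements:
    ``lights_on`` for baseline recordings, ``cue_exposure`` for day-14
    recordings started right after the cue reminder was introduced.
    """

    states: np.ndarray
    epoch_seconds: float = 5.0
    origin: str = "lights_on"

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="U4")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance states: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration_hours(self) -> float:
        return len(self) * self.epoch_seconds / 3600.0


def episodes(
    hypnogram: Hypnogram, state: str, merge_gap_epochs: int = 0
) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` as (start_epoch, length_epochs), in order.

    With ``merge_gap_epochs`` > 0, runs separated by at most that many
    non-state epochs are merged into one episode (off by default).
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    x = hypnogram.states == state
    if x.size == 0:
        return []
    diff = np.diff(x.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if x[0]:
        starts.insert(0, 0)
    if x[-1]:
        ends.append(x.size)
    runs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    if merge_gap_epochs > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, ln in runs[1:]:
            ps, pl = merged[-1]
            if s - (ps + pl) <= merge_gap_epochs:
                merged[-1] = (ps, s + ln - ps)
            else:
                merged.append((s, ln))
        runs = merged
    return runs


def percent_time(hypnogram: Hypnogram, state: str) -> float:
    """Percentage of recording time spent in ``state``."""
    n = len(hypnogram)
    if n == 0:
        raise ValueError("empty hypnogram")
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    return 100.0 * int(np.count_nonzero(hypnogram.states == state)) / n


def sleep_onset_latency(
    hypnogram: Hypnogram, state: str, min_seconds: float = 25.0
) -> float | None:
    """Minutes from the recording origin to the first >= ``min_seconds`` episode.

    Returns ``None`` when no qualifying episode exists (excluded from group
    statistics rather than imputed).
    """
    min_epochs = min_seconds / hypnogram.epoch_seconds
    if abs(min_epochs - round(min_epochs)) > 1e-9:
        raise ValueError("min_seconds must be a multiple of epoch_seconds")
    min_epochs = int(round(min_epochs))
    for start, length in episodes(hypnogram, state):
        if length >= min_epochs:
            return start * hypnogram.epoch_seconds / 60.0
    return None


@dataclass
class SleepMetrics:
    """Per-state architecture metrics for one recording."""

    percent_time: dict[str, float]
    episode_count: dict[str, int]
    mean_episode_duration: dict[str, float]  # seconds; NaN when no episode
    onset_latency: dict[str, float | None]   # minutes; None when never entered

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for st in STATES:
            row[f"{st}_percent"] = self.percent_time[st]
            row[f"{st}_episodes"] = self.episode_count[st]
            row[f"{st}_mean_duration_s"] = self.mean_episode_duration[st]
            lat = self.onset_latency[st]
            row[f"{st}_latency_min"] = float("nan") if lat is None else lat
        return row


def sleep_metrics(hypnogram: Hypnogram, min_latency_seconds: float = 25.0) -> SleepMetrics:
    """All architecture metrics for one hypnogram."""
    pct, cnt, dur, lat = {}, {}, {}, {}
    for st in STATES:
        runs = episodes(hypnogram, st)
        pct[st] = percent_time(hypnogram, st)
        cnt[st] = len(runs)
        total_epochs = sum(ln for _, ln in runs)
        dur[st] = (
            total_epochs * hypnogram.epoch_seconds / len(runs) if runs else float("nan")
        )
        lat[st] = sleep_onset_latency(hypnogram, st, min_latency_seconds)
    return SleepMetrics(pct, cnt, dur, lat)


@dataclass
class ClassifierConfig:
    """Thresholds for the rule-based epoch scorer.

    ``emg_threshold`` separates wake (above) from sleep; ``theta_delta_threshold``
    separates REM (above) from SWS among sleep epochs.  ``from_quantiles``
    derives both per recording from the feature distributions instead of
    using fixed values, assuming rough prior state fractions.
    """

    emg_threshold: float = 3.0
    theta_delta_threshold: float = 1.5

    @classmethod
    def from_quantiles(
        cls,
        features: pd.DataFrame,
        wake_fraction: float = 0.45,
        rem_fraction: float = 0.08,
    ) -> "ClassifierConfig":
        emg_thr = float(np.quantile(features["emg"], 1.0 - wake_fraction))
        sleep = features[features["emg"] <= emg_thr]
        ratio = sleep["theta"] / sleep["delta"]
        rem_among_sleep = min(0.99, rem_fraction / max(1e-9, 1.0 - wake_fraction))
        ratio_thr = float(np.quantile(ratio, 1.0 - rem_among_sleep))
        return cls(emg_threshold=emg_thr, theta_delta_threshold=ratio_thr)


def classify_epochs(
    features: pd.DataFrame, config: ClassifierConfig | None = None
) -> np.ndarray:
    """Score each epoch as WAKE / SWS / REM from its spectral features.

    ``features`` must have columns ``emg``, ``delta``, ``theta`` (one row
    per epoch).  Decision rule: high EMG -> WAKE; else theta/delta above the
    REM threshold -> REM; else SWS.
    """
    config = config or ClassifierConfig()
    for col in ("emg", "delta", "theta"):
        if col not in features.columns:
            raise ValueError(f"missing feature column {col!r}")
    emg = features["emg"].to_numpy(dtype=float)
    delta = features["delta"].to_numpy(dtype=float)
    theta = features["theta"].to_numpy(dtype=float)
    out = np.full(len(features), "SWS", dtype="U4")
    wake = emg > config.emg_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)
    out[~wake & (ratio > config.theta_delta_threshold)] = "REM"
    out[wake] = "WAKE"
    return out


# -- sleep radar scores --------------------------------------------------

#: Adverse direction per sleep variable: longer latency, fewer episodes,
#: less time in state and shorter episodes all read as impaired sleep.
_SLEEP_VARIABLE_DIRECTIONS = {
    "latency_min": Direction.HIGHER_IS_WORSE,
    "episodes": Direction.LOWER_IS_WORSE,
    "percent": Direction.LOWER_IS_WORSE,
    "mean_duration_s": Direction.LOWER_IS_WORSE,
}


def _metric_value(m: SleepMetrics, state: str, var: str) -> float:
    if var == "latency_min":
        lat = m.onset_latency[state]
        return float("nan") if lat is None else float(lat)
    if var == "episodes":
        return float(m.episode_count[state])
    if var == "percent":
        return float(m.percent_time[state])
    if var == "mean_duration_s":
        return float(m.mean_episode_duration[state])
    raise KeyError(var)


def sleep_radar_scores(
    metrics: SleepMetrics,
    control_metrics: Sequence[SleepMetrics],
    states: Sequence[str] = SLEEP_STATES,
) -> dict[str, float]:
    """Entry and continuity scores (0-6) per sleep state.

    Each of latency, episode count, percent time and mean episode duration
    is scored 0-3 against the control distribution with the bidirectional
    percentile rule; sleep *entry* = latency + episode-number scores, sleep
    *continuity* = percent-time + mean-duration scores.
    """
    if len(control_metrics) < 4:
        raise ValueError("sleep radar scores need at least 4 control animals")
    comp: dict[tuple[str, str], float | None] = {}
    for state in states:
        for var, direction in _SLEEP_VARIABLE_DIRECTIONS.items():
            ref = np.array(
                [_metric_value(cm, state, var) for cm in control_metrics], dtype=float
            )
            ref = ref[np.isfinite(ref)]
            spec = VariableSpec(f"{state}_{var}", "sleep", 14, Rule.BIDIRECTIONAL, direction)
            ts = build_thresholds(spec, ref)
            comp[(state, var)] = assign_score(_metric_value(metrics, state, var), ts)

    def combine(state: str, a: str, b: str) -> float:
        sa, sb = comp[(state, a)], comp[(state, b)]
        if sa is None or sb is None:
            return float("nan")
        return float(sa + sb)

    out: dict[str, float] = {}
    for state in states:
        out[f"{state}_entry"] = combine(state, "latency_min", "episodes")
        out[f"{state}_continuity"] = combine(state, "percent", "mean_duration_s")
    return out


def cohort_sleep_metrics(
    hypnograms: dict[str, Hypnogram], min_latency_seconds: float = 25.0
) -> pd.DataFrame:
    """SleepMetrics table for a cohort keyed by animal id."""
    rows = []
    for animal_id, hyp in hypnograms.items():
        row = {"animal_id": animal_id}
        row.update(sleep_metrics(hyp, min_latency_seconds).as_row())
        rows.append(row)
    return pd.DataFrame.from_records(rows)
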