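"""Percentile-threshold behavioral scoring.

Each behavioral variable is converted into a four-point severity score
(0 = adapted ... 3 = severely altered) using data-driven thresholds taken
from the empirical distribution of a reference dataset — in most cases the
unshocked (No-FS) control group.  Three threshold rules are used:

``FS_TAIL``
    For variables where control values are nearly null and unusable as a
    graded reference (freezing / escaping in the novelty tests): score 0 up
    to the control 95th percentile, then 1/2/3 at the 75th and 95th
    percentiles of the shocked (FS) dataset.
``BIDIRECTIONAL``
    For variables with a protective ("risk-taking") and an adverse
    (anxiety-like) direction (elevated-plus-maze open-arm time and
    velocity): 0 inside the control interquartile range, graded scores on
    the adverse tail at the control 5th/25th (or 75th/95th) percentiles,
    and a capped score of 1 on the protective tail beyond the 95th (or
    below the 5th).
``STARTLE_RATIO``
    Habituation ratios from the air-puff startle session, with fixed
    hyperarousal gates (amplitude ratio >= 0.95, latency ratio <= 1.05) and
    further bins from control distribution statistics.

A fourth rule, ``CONTROL_PERCENTILE``, grades one-sided deviations above
control percentile cuts and is reused by the cellular-activation scores.

The composite severity score is the sum of eight variable scores from four
tests (two variables per test); radar "domain" scores sum two related
variable scores each (range 0-6).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Rule",
    "Direction",
    "VariableSpec",
    "ThresholdSet",
    "StartleSession",
    "COMPOSITE_VARIABLES",
    "INTRUSION_VARIABLES",
    "RADAR_DOMAINS",
    "compute_percentile",
    "build_thresholds",
    "assign_score",
    "startle_habituation_ratios",
    "composite_score",
    "radar_domain_scores",
    "variable_dispersion_ranking",
    "score_cohort",
]


class Rule(str, Enum):
    CONTROL_PERCENTILE = "CONTROL_PERCENTILE"
    FS_TAIL = "FS_TAIL"
    BIDIRECTIONAL = "BIDIRECTIONAL"
    STARTLE_RATIO = "STARTLE_RATIO"


class Direction(str, Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    LOWER_IS_WORSE = "lower_is_worse"
    TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class VariableSpec:
    """One scored behavioral variable: where it comes from and how to bin it."""

    name: str
    test: str
    day: int
    rule: Rule
    direction: Direction

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.test, self.day, self.name)


@dataclass
class ThresholdSet:
    """Ordered cut values for one variable plus the provenance of each cut.

    ``cuts`` is keyed by a semantic name (e.g. ``"fs_p75"``); ``provenance``
    records, for every cut, which dataset and which statistic produced it so
    that the whole threshold table can be audited and replayed.
    """

    variable: VariableSpec
    cuts: dict[str, float]
    provenance: dict[str, str]

    def audit_rows(self) -> list[dict]:
        return [
            {
                "variable": self.variable.name,
                "test": self.variable.test,
                "day": self.variable.day,
                "rule": self.variable.rule.value,
                "cut": name,
                "value": value,
                "provenance": self.provenance.get(name, ""),
            }
            for name, value in self.cuts.items()
        ]


@dataclass
class StartleSession:
    """A 40-trial air-puff startle session for one animal.

    Trials with movement in the pre-stimulus window are flagged and excluded
    from the habituation-ratio computation.
    """

    amplitude: np.ndarray
    latency_ms: np.ndarray
    prestim_movement: np.ndarray

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.latency_ms = np.asarray(self.latency_ms, dtype=float)
        self.prestim_movement = np.asarray(self.prestim_movement, dtype=bool)
        n = len(self.amplitude)
        if len(self.latency_ms) != n or len(self.prestim_movement) != n:
            raise ValueError("trial series must have equal length")


def compute_percentile(values: Sequence[float], p: float) -> float:
    """Linear-interpolation percentile of ``values`` (inclusive endpoints).

    ``p`` is a percent in [0, 100]; p=0 returns the minimum, p=100 the
    maximum, p=50 the sample median.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("compute_percentile requires at least one finite value")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    return float(np.percentile(arr, p, method="linear"))


STARTLE_AMPLITUDE_GATE = 0.95  # ratio >= gate marks impaired amplitude habituation
STARTLE_LATENCY_GATE = 1.05    # ratio <= gate marks shortened response latency

_MIN_REFERENCE_N = 4


def _check_reference(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < _MIN_REFERENCE_N:
        raise ValueError(
            f"undersampled reference: need >= {_MIN_REFERENCE_N} {label} values, got {arr.size}"
        )
    return arr


def build_thresholds(
    variable: VariableSpec,
    control_values: Sequence[float],
    fs_values: Sequence[float] | None = None,
) -> ThresholdSet:
    """Derive the 0|1|2|3 cut values for one variable from reference data.

    ``control_values`` is the No-FS reference distribution; ``fs_values``
    (required for the FS_TAIL rule) is the pooled foot-shocked dataset.
    """
    rule = variable.rule
    if rule is Rule.FS_TAIL:
        ctrl = _check_reference(control_values, "control")
        if fs_values is None or len(np.atleast_1d(fs_values)) == 0:
            raise ValueError("FS_TAIL rule requires a non-empty FS dataset")
        fs = np.asarray(fs_values, dtype=float)
        fs = fs[np.isfinite(fs)]
        c0 = compute_percentile(ctrl, 95)
        c1 = compute_percentile(fs, 75)
        c2 = compute_percentile(fs, 95)
        # enforce monotone severity if the FS cuts undershoot the control tail
        c1 = max(c0, c1)
        c2 = max(c1, c2)
        return ThresholdSet(
            variable,
            cuts={"nofs_p95": c0, "fs_p75": c1, "fs_p95": c2},
            provenance={
                "nofs_p95": "95th percentile of No-FS dataset",
                "fs_p75": "75th percentile of FS dataset",
                "fs_p95": "95th percentile of FS dataset",
            },
        )
    if rule is Rule.BIDIRECTIONAL:
        ctrl = _check_reference(control_values, "control")
        cuts = {
            "min": float(ctrl.min()),
            "p5": compute_percentile(ctrl, 5),
            "p25": compute_percentile(ctrl, 25),
            "p75": compute_percentile(ctrl, 75),
            "p95": compute_percentile(ctrl, 95),
            "max": float(ctrl.max()),
        }
        prov = {
            "min": "minimum of No-FS dataset",
            "p5": "5th percentile of No-FS dataset",
            "p25": "25th percentile of No-FS dataset",
            "p75": "75th percentile of No-FS dataset",
            "p95": "95th percentile of No-FS dataset",
            "max": "maximum of No-FS dataset",
        }
        return ThresholdSet(variable, cuts=cuts, provenance=prov)
    if rule is Rule.STARTLE_RATIO:
        ctrl = _check_reference(control_values, "control")
        med = compute_percentile(ctrl, 50)
        if variable.direction is Direction.HIGHER_IS_WORSE:  # amplitude ratio
            c1 = max(STARTLE_AMPLITUDE_GATE, med)
            c2 = max(c1, compute_percentile(ctrl, 75))
            cuts = {"gate": STARTLE_AMPLITUDE_GATE, "c1": c1, "c2": c2}
            prov = {
                "gate": "fixed hyperarousal gate (amplitude ratio >= 0.95)",
                "c1": "No-FS median (floored at the 0.95 gate)",
                "c2": "No-FS 75th percentile (floored at c1)",
            }
        else:  # latency-to-peak ratio, lower is worse
            c1 = min(STARTLE_LATENCY_GATE, med)
            c2 = min(c1, compute_percentile(ctrl, 25))
            cuts = {"gate": STARTLE_LATENCY_GATE, "c1": c1, "c2": c2}
            prov = {
                "gate": "fixed hyperarousal gate (latency ratio <= 1.05)",
                "c1": "No-FS median (capped at the 1.05 gate)",
                "c2": "No-FS 25th percentile (capped at c1)",
            }
        return ThresholdSet(variable, cuts=cuts, provenance=prov)
    if rule is Rule.CONTROL_PERCENTILE:
        ctrl = _check_reference(control_values, "control")
        c0 = compute_percentile(ctrl, 50)
        c1 = max(c0, compute_percentile(ctrl, 75))
        c2 = max(c1, float(ctrl.max()))
        return ThresholdSet(
            variable,
            cuts={"median": c0, "p75": c1, "max": c2},
            provenance={
                "median": "median of No-FS dataset",
                "p75": "75th percentile of No-FS dataset",
                "max": "maximum of No-FS dataset",
            },
        )
    raise ValueError(f"unknown rule {rule!r}")


def assign_score(value: float, thresholds: ThresholdSet) -> int | None:
    """Map one measured value to its 0-3 severity score.

    Returns ``None`` for non-finite values (propagated as a missing score).
    Values exactly on a cut take the lower-severity score, except the fixed
    startle gates, which are inclusive on the hyperarousal side.
    """
    if value is None or not math.isfinite(value):
        return None
    v = float(value)
    rule = thresholds.variable.rule
    cuts = thresholds.cuts
    if rule is Rule.FS_TAIL:
        if v <= cuts["nofs_p95"]:
            return 0
        if v <= cuts["fs_p75"]:
            return 1
        if v <= cuts["fs_p95"]:
            return 2
        return 3
    if rule is Rule.CONTROL_PERCENTILE:
        if v <= cuts["median"]:
            return 0
        if v <= cuts["p75"]:
            return 1
        if v <= cuts["max"]:
            return 2
        return 3
    if rule is Rule.BIDIRECTIONAL:
        return _assign_bidirectional(v, cuts, thresholds.variable.direction)
    if rule is Rule.STARTLE_RATIO:
        if thresholds.variable.direction is Direction.HIGHER_IS_WORSE:
            if v < cuts["gate"]:
                return 0
            if v <= cuts["c1"]:
                return 1
            if v <= cuts["c2"]:
                return 2
            return 3
        else:
            if v > cuts["gate"]:
                return 0
            if v >= cuts["c1"]:
                return 1
            if v >= cuts["c2"]:
                return 2
            return 3
    raise ValueError(f"unknown rule {rule!r}")


def _assign_bidirectional(v: float, cuts: Mapping[str, float], direction: Direction) -> int:
    p5, p25, p75, p95 = cuts["p5"], cuts["p25"], cuts["p75"], cuts["p95"]
    lo, hi = cuts["min"], cuts["max"]
    if p25 <= v <= p75:
        return 0

    def low_tail(adverse: bool) -> int:
        # v < p25
        if v >= p5:
            return 1 if adverse else 0
        if not adverse:
            return 1  # protective deviation capped at 1
        return 2 if v >= lo else 3

    def high_tail(adverse: bool) -> int:
        # v > p75
        if v <= p95:
            return 1 if adverse else 0
        if not adverse:
            return 1
        return 2 if v <= hi else 3

    if direction is Direction.LOWER_IS_WORSE:
        return low_tail(True) if v < p25 else high_tail(False)
    if direction is Direction.HIGHER_IS_WORSE:
        return high_tail(True) if v > p75 else low_tail(False)
    # two-sided: both tails adverse
    return low_tail(True) if v < p25 else high_tail(True)


def startle_habituation_ratios(
    session: StartleSession, window: int = 5, min_window: int = 3
) -> tuple[float, float]:
    """Habituation ratios: median(last window) / median(first window).

    Computed separately for maximum response amplitude and latency-to-peak,
    on unflagged trials only.  The windows shrink down to ``min_window``
    valid trials when exclusions leave fewer than ``window``; below that the
    result is missing (NaN).  A zero first-window median yields NaN with a
    warning rather than an infinite ratio.
    """
    valid = ~session.prestim_movement
    idx = np.flatnonzero(valid)
    if idx.size < 2 * min_window:
        return (float("nan"), float("nan"))
    k = min(window, idx.size // 2)
    first, last = idx[:k], idx[-k:]

    def ratio(series: np.ndarray) -> float:
        denom = float(np.median(series[first]))
        numer = float(np.median(series[last]))
        if denom == 0.0:
            warnings.warn("first-window median is zero; habituation ratio undefined")
            return float("nan")
        return numer / denom

    return (ratio(session.amplitude), ratio(session.latency_ms))


# -- variable registry ---------------------------------------------------

#: The eight composite variables: two per test across four tests.
COMPOSITE_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("freezing_pct", "new_context", 16, Rule.FS_TAIL, Direction.HIGHER_IS_WORSE),
    VariableSpec("escaping_pct", "new_context", 16, Rule.FS_TAIL, Direction.HIGHER_IS_WORSE),
    VariableSpec("freezing_pct", "new_object", 16, Rule.FS_TAIL, Direction.HIGHER_IS_WORSE),
    VariableSpec("escaping_pct", "new_object", 16, Rule.FS_TAIL, Direction.HIGHER_IS_WORSE),
    VariableSpec("open_arm_time_pct", "epm", 18, Rule.BIDIRECTIONAL, Direction.LOWER_IS_WORSE),
    VariableSpec("open_arm_velocity", "epm", 18, Rule.BIDIRECTIONAL, Direction.LOWER_IS_WORSE),
    VariableSpec("amplitude_ratio", "startle", 23, Rule.STARTLE_RATIO, Direction.HIGHER_IS_WORSE),
    VariableSpec("latency_to_peak_ratio", "startle", 23, Rule.STARTLE_RATIO, Direction.LOWER_IS_WORSE),
)

#: Cue-reminder (D14) conditioned responses; scored with the FS_TAIL rule and
#: combined into the "intrusion" radar domain (not part of the composite).
INTRUSION_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("freezing_pct", "cue_reminder", 14, Rule.FS_TAIL, Direction.HIGHER_IS_WORSE),
    VariableSpec("escaping_pct", "cue_reminder", 14, Rule.FS_TAIL, Direction.HIGHER_IS_WORSE),
)

#: Radar domains: each is the sum of two variable scores (range 0-6).
RADAR_DOMAINS: dict[str, tuple[tuple[str, int, str], tuple[str, int, str]]] = {
    "intrusion": (("cue_reminder", 14, "freezing_pct"), ("cue_reminder", 14, "escaping_pct")),
    "avoidance": (("epm", 18, "open_arm_time_pct"), ("epm", 18, "open_arm_velocity")),
    "altered_reactivity": (("new_context", 16, "freezing_pct"), ("new_context", 16, "escaping_pct")),
    "altered_arousal": (("startle", 23, "amplitude_ratio"), ("startle", 23, "latency_to_peak_ratio")),
}


def composite_score(scores: Mapping[tuple[str, int, str], int | None]) -> float:
    """Sum the eight composite variable scores (0-24).

    Any missing component voids the composite (returns NaN); the animal is
    then excluded from classification rather than imputed.
    """
    total = 0
    for spec in COMPOSITE_VARIABLES:
        s = scores.get(spec.key)
        if s is None or (isinstance(s, float) and not math.isfinite(s)):
            return float("nan")
        total += int(s)
    return float(total)


def radar_domain_scores(
    scores: Mapping[tuple[str, int, str], int | None],
) -> dict[str, float]:
    """Combine variable scores into the four 0-6 symptom-domain scores."""
    out: dict[str, float] = {}
    for domain, (a, b) in RADAR_DOMAINS.items():
        sa, sb = scores.get(a), scores.get(b)
        if sa is None or sb is None:
            out[domain] = float("nan")
        else:
            out[domain] = float(int(sa) + int(sb))
    return out


def variable_dispersion_ranking(
    table: pd.DataFrame, group_col: str = "group", control_label: str = "NoFS"
) -> pd.DataFrame:
    """Rank variables by descending sample SD within the FS group.

    Part of the data-driven variable selection: high-dispersion variables
    discriminate individuals best.  Returns a DataFrame sorted by SD with a
    stable order for ties (constant variables rank last).
    """
    fs = table[table[group_col] != control_label]
    sd = (
        fs.groupby(["test", "day", "variable"], sort=True)["value"]
        .std(ddof=1)
        .fillna(0.0)
        .reset_index(name="sd")
    )
    sd = sd.sort_values("sd", ascending=False, kind="stable").reset_index(drop=True)
    sd["rank"] = np.arange(1, len(sd) + 1)
    return sd


def score_cohort(
    table: pd.DataFrame,
    control_label: str = "NoFS",
    extra_variables: Sequence[VariableSpec] = INTRUSION_VARIABLES,
) -> tuple[pd.DataFrame, list[ThresholdSet]]:
    """Score a full behavioral cohort from its long-format measurement table.

    Thresholds are derived from the supplied cohort itself (No-FS rows are
    the control reference; all other rows the FS dataset), then every animal
    — control or shocked — is scored against them.

    Returns ``(scorecard, thresholds)`` where ``scorecard`` has one row per
    animal with per-variable scores, the composite (NaN when any component
    is missing) and the four radar domain scores.
    """
    required = {"animal_id", "group", "test", "day", "variable", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"behavior table missing columns: {sorted(missing_cols)}")

    wide = table.pivot_table(
        index=["animal_id", "group"],
        columns=["test", "day", "variable"],
        values="value",
        aggfunc="first",
    )
    is_control = wide.index.get_level_values("group") == control_label

    specs = tuple(COMPOSITE_VARIABLES) + tuple(extra_variables)
    thresholds: list[ThresholdSet] = []
    score_cols: dict[tuple[str, int, str], list] = {}
    for spec in specs:
        if spec.key not in wide.columns:
            raise ValueError(f"variable {spec.key} absent from behavior table")
        col = wide[spec.key]
        ctrl_values = col[is_control].dropna().to_numpy()
        fs_values = col[~is_control].dropna().to_numpy()
        ts = build_thresholds(spec, ctrl_values, fs_values)
        thresholds.append(ts)
        score_cols[spec.key] = [assign_score(v, ts) for v in col.to_numpy()]

    records = []
    for i, (animal_id, group) in enumerate(wide.index):
        scores = {key: vals[i] for key, vals in score_cols.items()}
        rec = {"animal_id": animal_id, "group": group}
        for spec in specs:
            s = scores[spec.key]
            rec[f"score:{spec.test}/{spec.name}"] = np.nan if s is None else s
        rec["composite"] = composite_score(scores)
        rec.update(radar_domain_scores(scores))
        records.append(rec)
    scorecard = pd.DataFrame.from_records(records)
    return scorecard, thresholds


def thresholds_audit_table(thresholds: Sequence[ThresholdSet]) -> pd.DataFrame:
    """Flatten ThresholdSets into an auditable cut-by-cut table."""
    rows: list[dict] = []
    for ts in thresholds:
        rows.extend(ts.audit_rows())
    return pd.DataFrame.from_records(rows)
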