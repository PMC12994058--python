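"""Two-step phenotype classification of foot-shocked animals.

Step 1 splits shocked (FS) animals into resilient and susceptible using the
composite behavioral severity score: the cut-off is the *maximum composite
score observed in the unshocked control group*, and an FS animal is
susceptible iff its composite is strictly above that cut-off.

Step 2 splits susceptible animals by their dominant defensive strategy
during the day-28 full-context re-exposure: an animal that attempted to
escape at least once is an escaper (FS-Esc); otherwise it is a freezer
(FS-Frz).  The control 95th percentile of D28 freezing is recorded as a QC
annotation (susceptible animals with neither high freezing nor any escape
attempt are flagged), but the escape-attempt criterion alone decides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import compute_percentile

__all__ = [
    "ClassificationRule",
    "derive_cutoff",
    "classify_step1",
    "classify_step2",
    "classify_cohort",
    "phenotype_summary",
]

FINAL_LABELS = ("NoFS", "FS-Res", "FS-Frz", "FS-Esc")


@dataclass
class ClassificationRule:
    """Parameters of the two-step rule, derived from the control group."""

    composite_cutoff: float
    escape_rule_min_attempts: int = 1
    freezing_reference: float | None = None  # control 95th pct of D28 freezing (QC only)


def derive_cutoff(control_composites: Sequence[float]) -> float:
    """Susceptibility cut-off: the maximal control composite score."""
    arr = np.asarray(control_composites, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("derive_cutoff requires at least one control composite")
    return float(arr.max())


def classify_step1(composite: float, cutoff: float) -> str | None:
    """Susceptible iff composite strictly exceeds the control maximum.

    A composite exactly at the cut-off is resilient: the cut-off is itself a
    control score and controls are by definition not susceptible.  Missing
    composites return ``None`` (unclassified).
    """
    if composite is None or not math.isfinite(composite):
        return None
    return "Susceptible" if composite > cutoff else "Resilient"


def classify_step2(
    d28_freezing_pct: float,
    escape_attempts: int,
    rule: ClassificationRule,
) -> tuple[str, bool]:
    """Freezer/escaper split for a susceptible animal.

    Returns ``(label, qc_flag)``: label is ``"Esc"`` iff the animal made at
    least ``rule.escape_rule_min_attempts`` escape attempts, else ``"Frz"``.
    The QC flag marks freezers whose D28 freezing did not exceed the control
    95th percentile (neither defensive behavior dominated).
    """
    if escape_attempts < 0:
        raise ValueError("escape attempt count cannot be negative")
    if escape_attempts >= rule.escape_rule_min_attempts:
        return "Esc", False
    qc = False
    if rule.freezing_reference is not None and math.isfinite(d28_freezing_pct):
        qc = d28_freezing_pct <= rule.freezing_reference
    return "Frz", qc


def classify_cohort(
    scorecard: pd.DataFrame,
    behavior: pd.DataFrame,
    control_label: str = "NoFS",
    d28_test: str = "full_context",
    d28_day: int = 28,
) -> tuple[pd.DataFrame, ClassificationRule]:
    """Run both classification steps over a scored cohort.

    ``scorecard`` is the output of :func:`fspheno.scoring.score_cohort`;
    ``behavior`` supplies the day-28 full-context freezing percentage and
    escape-attempt counts.  Controls are labelled NoFS unconditionally.

    Returns a label table (animal_id, group, step1, step2, final, qc_flag)
    and the derived :class:`ClassificationRule`.
    """
    is_control = scorecard["group"] == control_label
    cutoff = derive_cutoff(scorecard.loc[is_control, "composite"])

    d28 = behavior[(behavior["test"] == d28_test) & (behavior["day"] == d28_day)]
    freezing = d28[d28["variable"] == "freezing_pct"].set_index("animal_id")["value"]
    attempts = d28[d28["variable"] == "escape_attempts"].set_index("animal_id")["value"]
    ctrl_ids = set(scorecard.loc[is_control, "animal_id"])
    ctrl_freeze = freezing[freezing.index.isin(ctrl_ids)].to_numpy()
    freeze_ref = compute_percentile(ctrl_freeze, 95) if len(ctrl_freeze) >= 1 else None
    rule = ClassificationRule(composite_cutoff=cutoff, freezing_reference=freeze_ref)

    records = []
    for _, row in scorecard.iterrows():
        animal, group = row["animal_id"], row["group"]
        if group == control_label:
            records.append(
                {"animal_id": animal, "group": group, "step1": "Resilient",
                 "step2": "NA", "final": "NoFS", "qc_flag": False}
            )
            continue
        step1 = classify_step1(row["composite"], cutoff)
        if step1 is None:
            records.append(
                {"animal_id": animal, "group": group, "step1": "unclassified",
                 "step2": "NA", "final": "unclassified", "qc_flag": True}
            )
            continue
        if step1 == "Resilient":
            records.append(
                {"animal_id": animal, "group": group, "step1": step1,
                 "step2": "NA", "final": "FS-Res", "qc_flag": False}
            )
            continue
        frz = float(freezing.get(animal, np.nan))
        att = int(attempts.get(animal, 0))
        step2, qc = classify_step2(frz, att, rule)
        records.append(
            {"animal_id": animal, "group": group, "step1": step1,
             "step2": step2, "final": f"FS-{step2}", "qc_flag": qc}
        )
    return pd.DataFrame.from_records(records), rule


def phenotype_summary(labels: pd.DataFrame | Sequence[str]) -> pd.DataFrame:
    """Counts and percentages per final phenotype label.

    Percentages are relative to the foot-shocked total (NoFS excluded from
    the denominator) and rounded to the nearest 0.5 percentage point.  A
    ``Susceptible`` row aggregates FS-Frz + FS-Esc.
    """
    if isinstance(labels, pd.DataFrame):
        finals = labels["final"].tolist()
    else:
        finals = list(labels)
    counts = {lab: finals.count(lab) for lab in FINAL_LABELS}
    fs_total = counts["FS-Res"] + counts["FS-Frz"] + counts["FS-Esc"]

    def pct(k: int) -> float:
        if fs_total == 0:
            return float("nan")
        return round(100.0 * k / fs_total * 2.0) / 2.0

    rows = [
        {"label": "NoFS", "count": counts["NoFS"], "pct_of_fs": float("nan")},
        {"label": "Susceptible", "count": counts["FS-Frz"] + counts["FS-Esc"],
         "pct_of_fs": pct(counts["FS-Frz"] + counts["FS-Esc"])},
        {"label": "FS-Res", "count": counts["FS-Res"], "pct_of_fs": pct(counts["FS-Res"])},
        {"label": "FS-Frz", "count": counts["FS-Frz"], "pct_of_fs": pct(counts["FS-Frz"])},
        {"label": "FS-Esc", "count": counts["FS-Esc"], "pct_of_fs": pct(counts["FS-Esc"])},
    ]
    return pd.DataFrame.from_records(rows)
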