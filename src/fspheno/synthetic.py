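"""Synthetic multi-level cohort generator.

Emulates the statistical structure of a foot-shock (FS) phenotyping study
so every downstream analysis stage is testable without animal data: a
four-archetype cohort (unshocked NoFS controls, resilient Res, freezer Frz
and escaper Esc), 24-h hypnograms from a three-state Markov chain at 5-s
resolution, per-epoch EMG/EEG band-power features with state-conditional
signatures, and two-channel fluorescence scenes with known spot ground
truth for the nucleus-counting workflow.

The default archetype parameters encode the qualitative effect directions
of the emulated study design: freezers show high novelty freezing and low
open-arm exploration; escapers show high escaping, at least one day-28
escape attempt and no startle habituation; resilient animals are
control-like on non-conditioned tests but show strong cue-conditioned
freezing and a selective post-stress REM-sleep increase.  The exact values
are package constants, documented here, not claims about any dataset.

Determinism: every generator draws from a substream seeded with the global
seed plus a fixed counter tuple ``(seed, archetype_index, animal_index,
purpose)``, so identical configurations reproduce byte-identical outputs
and individual animals can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sleep import STATES, Hypnogram

__all__ = [
    "Dist",
    "ArchetypeSpec",
    "CohortConfig",
    "FeatureParams",
    "transition_matrix",
    "stationary_distribution",
    "default_archetypes",
    "generate_cohort",
    "generate_hypnogram",
    "generate_epoch_features",
    "generate_cfos_image",
    "sample_region_densities",
]

GROUPS = ("NoFS", "Res", "Frz", "Esc")

# substream purpose counters
_BEHAVIOR, _HYPNO_BASE, _HYPNO_D14, _FEATURES, _IMAGING = range(5)


@dataclass(frozen=True)
class Dist:
    """One variable's sampling distribution for one archetype.

    Families:
      * ``truncnorm`` — normal(loc, scale) truncated to [0, 100]; used for
        percentage-of-session-time variables.
      * ``lognorm`` — log-normal with median ``loc`` and log-SD ``scale``;
        used for velocities, distances and habituation ratios.
      * ``escape_count`` — zero-inflated count: 0 with probability
        1 - ``loc``, else 1 + Poisson(``scale``); used for escape attempts.
    """

    family: str
    loc: float
    scale: float

    def __post_init__(self):
        if self.family not in ("truncnorm", "lognorm", "escape_count"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.family == "truncnorm" and not 0.0 <= self.loc <= 100.0:
            raise ValueError("percentage location must be in [0, 100]")
        if self.family == "escape_count" and not 0.0 <= self.loc <= 1.0:
            raise ValueError("escape_count loc is a probability")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "truncnorm":
            if self.scale == 0:
                return np.full(size, self.loc) if size else self.loc
            a = (0.0 - self.loc) / self.scale
            b = (100.0 - self.loc) / self.scale
            return sps.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale,
                                     size=size, random_state=rng)
        if self.family == "lognorm":
            z = rng.standard_normal(size)
            return self.loc * np.exp(self.scale * z)
        # escape_count
        n = size or 1
        nonzero = rng.random(n) < self.loc
        counts = np.where(nonzero, 1 + rng.poisson(self.scale, n), 0)
        return counts if size else int(counts[0])

    def mean(self) -> float:
        """Exact mean of the family (oracle for large-sample checks)."""
        if self.family == "truncnorm":
            if self.scale == 0:
                return self.loc
            a = (0.0 - self.loc) / self.scale
            b = (100.0 - self.loc) / self.scale
            return float(sps.truncnorm.mean(a, b, loc=self.loc, scale=self.scale))
        if self.family == "lognorm":
            return self.loc * math.exp(self.scale**2 / 2.0)
        return self.loc * (1.0 + self.scale)

    def std(self) -> float:
        if self.family == "truncnorm":
            if self.scale == 0:
                return 0.0
            a = (0.0 - self.loc) / self.scale
            b = (100.0 - self.loc) / self.scale
            return float(sps.truncnorm.std(a, b, loc=self.loc, scale=self.scale))
        if self.family == "lognorm":
            s2 = self.scale**2
            return self.loc * math.exp(s2 / 2.0) * math.sqrt(math.exp(s2) - 1.0)
        # var of zero-inflated 1+Poisson mixture
        p, lam = self.loc, self.scale
        m = p * (1.0 + lam)
        second = p * ((1.0 + lam) ** 2 + lam)
        return math.sqrt(max(0.0, second - m**2))


def transition_matrix(
    fractions: Sequence[float],
    sws_bout_s: float = 100.0,
    rem_bout_s: float = 60.0,
    rem_exit_to_wake: float = 0.7,
    epoch_seconds: float = 5.0,
) -> np.ndarray:
    """Build a WAKE/SWS/REM transition matrix with a given stationary law.

    ``fractions`` are the target long-run (WAKE, SWS, REM) time fractions;
    bout lengths set the mean dwell times of the sleep states.  REM is
    enterable only from SWS (standard rodent sleep-stage grammar), so the
    WAKE row always has zero mass on REM.  The construction solves the
    stationary flow-balance equations, hence the returned chain's
    stationary distribution equals ``fractions`` exactly.
    """
    pi = np.asarray(fractions, dtype=float)
    if pi.shape != (3,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 positive numbers summing to 1")
    ls = sws_bout_s / epoch_seconds
    lr = rem_bout_s / epoch_seconds
    d = rem_exit_to_wake / lr
    e = (1.0 - rem_exit_to_wake) / lr
    c = pi[2] / (pi[1] * lr)
    b = 1.0 / ls - c
    if b < 0:
        raise ValueError("SWS bout too long for the requested REM fraction")
    a = (pi[1] * b + pi[2] * d) / pi[0]
    if a >= 1.0:
        raise ValueError("infeasible targets: WAKE exit probability >= 1")
    return np.array([
        [1.0 - a, a, 0.0],
        [b, 1.0 - b - c, c],
        [d, e, 1.0 - d - e],
    ])


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary law of a 3-state chain via left-eigenvector analysis."""
    w, v = np.linalg.eig(np.asarray(matrix, dtype=float).T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    return pi / pi.sum()


@dataclass
class FeatureParams:
    """State-conditional per-epoch feature means and noise.

    Wake epochs have high EMG power; SWS has low EMG and dominant delta
    (1-4 Hz) with spindle (10-14 Hz) activity; REM has the lowest EMG and a
    theta-dominated (5-9 Hz) EEG.  Values are in arbitrary power units.
    """

    means: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "WAKE": {"emg": 10.0, "delta": 2.0, "theta": 3.0, "spindle": 1.0},
        "SWS": {"emg": 1.0, "delta": 8.0, "theta": 2.0, "spindle": 3.0},
        "REM": {"emg": 0.4, "delta": 2.0, "theta": 8.0, "spindle": 1.0},
    })
    noise_sd: float = 0.6

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ArchetypeSpec:
    """All generator parameters for one phenotype archetype."""

    name: str
    n: int
    behavior: Mapping[tuple[str, int, str], Dist]
    sleep: Mapping[str, np.ndarray]  # condition ("baseline" | "D14") -> 3x3 matrix
    features: FeatureParams = field(default_factory=FeatureParams)
    imaging: Mapping[str, float] = field(default_factory=dict)  # region -> spots/mm^2

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("animal count must be non-negative")
        for cond, mat in self.sleep.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (3, 3) or np.any(mat < 0):
                raise ValueError(f"{cond}: transition matrix must be 3x3 non-negative")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{cond}: transition matrix rows must sum to 1")
            if mat[0, 2] > 0:
                raise ValueError(f"{cond}: direct WAKE->REM transitions are forbidden")


@dataclass
class CohortConfig:
    archetypes: Sequence[ArchetypeSpec]
    seed: int = 0
    epoch_seconds: float = 5.0
    recording_hours: float = 24.0

    def __post_init__(self):
        if self.epoch_seconds <= 0 or self.recording_hours <= 0:
            raise ValueError("epoch_seconds and recording_hours must be positive")


# -- default archetype parameters ---------------------------------------

def _behavior_table() -> dict[tuple[str, int, str], dict[str, Dist]]:
    tn, ln, ec = (
        lambda loc, sc: Dist("truncnorm", loc, sc),
        lambda loc, sc: Dist("lognorm", loc, sc),
        lambda p, lam: Dist("escape_count", p, lam),
    )
    return {
        # pre-stress open field: no group difference (no pre-existing marker)
        ("open_field", -5, "center_time_pct"): dict(
            NoFS=tn(20, 6), Res=tn(20, 6), Frz=tn(20, 6), Esc=tn(20, 6)),
        ("open_field", -5, "distance_m"): dict(
            NoFS=ln(25, 0.2), Res=ln(25, 0.2), Frz=ln(25, 0.2), Esc=ln(25, 0.2)),
        # shock day: all FS animals freeze (successful fear induction)
        ("fs_exposure", 0, "freezing_pct"): dict(
            NoFS=tn(2, 2), Res=tn(50, 12), Frz=tn(40, 12), Esc=tn(35, 12)),
        ("fs_exposure", 0, "escaping_pct"): dict(
            NoFS=tn(0.5, 0.5), Res=tn(1, 1), Frz=tn(1, 1), Esc=tn(8, 4)),
        ("partial_context", 5, "freezing_pct"): dict(
            NoFS=tn(3, 2), Res=tn(30, 10), Frz=tn(60, 12), Esc=tn(15, 8)),
        ("partial_context", 5, "escaping_pct"): dict(
            NoFS=tn(0.5, 0.5), Res=tn(1, 1), Frz=tn(1, 1), Esc=tn(10, 5)),
        # D14 cue reminder: strong conditioned freezing in all FS groups,
        # resilient included (cue-specific defensive response)
        ("cue_reminder", 14, "freezing_pct"): dict(
            NoFS=tn(5, 3), Res=tn(55, 12), Frz=tn(65, 12), Esc=tn(45, 12)),
        ("cue_reminder", 14, "escaping_pct"): dict(
            NoFS=tn(0.5, 0.5), Res=tn(1, 1), Frz=tn(1, 1), Esc=tn(20, 8)),
        # D16 novelty: freezers generalize freezing, escapers escape
        ("new_context", 16, "freezing_pct"): dict(
            NoFS=tn(2, 2), Res=tn(4, 3), Frz=tn(55, 12), Esc=tn(8, 5)),
        ("new_context", 16, "escaping_pct"): dict(
            NoFS=tn(1, 1), Res=tn(1, 1), Frz=tn(1, 1), Esc=tn(45, 10)),
        ("new_object", 16, "freezing_pct"): dict(
            NoFS=tn(2, 2), Res=tn(5, 3), Frz=tn(60, 12), Esc=tn(6, 4)),
        ("new_object", 16, "escaping_pct"): dict(
            NoFS=tn(1, 1), Res=tn(1.5, 1.5), Frz=tn(2, 2), Esc=tn(50, 10)),
        ("partial_context", 17, "freezing_pct"): dict(
            NoFS=tn(3, 2), Res=tn(20, 8), Frz=tn(55, 12), Esc=tn(10, 6)),
        ("partial_context", 17, "escaping_pct"): dict(
            NoFS=tn(0.5, 0.5), Res=tn(8, 4), Frz=tn(1, 1), Esc=tn(30, 8)),
        # D18 elevated-plus maze: freezers avoid and slow down in open arms
        ("epm", 18, "open_arm_time_pct"): dict(
            NoFS=tn(25, 8), Res=tn(22, 8), Frz=tn(5, 3), Esc=tn(18, 7)),
        ("epm", 18, "open_arm_velocity"): dict(
            NoFS=ln(6, 0.25), Res=ln(5.5, 0.25), Frz=ln(2.5, 0.3), Esc=ln(5, 0.3)),
        # D23 startle habituation ratios: escapers fail to habituate in
        # amplitude; freezers shorten their response latency; resilient
        # animals lengthen it
        ("startle", 23, "amplitude_ratio"): dict(
            NoFS=ln(0.75, 0.12), Res=ln(0.80, 0.12), Frz=ln(0.70, 0.15), Esc=ln(1.15, 0.12)),
        ("startle", 23, "latency_to_peak_ratio"): dict(
            NoFS=ln(1.00, 0.08), Res=ln(1.25, 0.10), Frz=ln(0.85, 0.08), Esc=ln(0.95, 0.10)),
        # D28 full-context re-exposure: the step-2 discriminators
        ("full_context", 28, "freezing_pct"): dict(
            NoFS=tn(5, 3), Res=tn(60, 12), Frz=tn(70, 10), Esc=tn(15, 8)),
        ("full_context", 28, "escaping_pct"): dict(
            NoFS=tn(0.3, 0.3), Res=tn(0.5, 0.5), Frz=tn(0.5, 0.5), Esc=tn(30, 10)),
        ("full_context", 28, "escape_attempts"): dict(
            NoFS=ec(0.0, 0.0), Res=ec(0.02, 1.0), Frz=ec(0.02, 1.0), Esc=ec(1.0, 2.0)),
    }


#: Long-run (WAKE, SWS, REM) fractions per archetype and condition.  At
#: baseline the later-resilient animals have slightly *less* REM than the
#: later-susceptible ones; fourteen days post-stress the ordering reverses,
#: with a REM increase specific to the resilient archetype.
_SLEEP_FRACTIONS = {
    "NoFS": {"baseline": (0.45, 0.47, 0.08), "D14": (0.45, 0.47, 0.08)},
    "Res": {"baseline": (0.44, 0.50, 0.06), "D14": (0.42, 0.47, 0.11)},
    "Frz": {"baseline": (0.455, 0.45, 0.095), "D14": (0.47, 0.46, 0.07)},
    "Esc": {"baseline": (0.455, 0.45, 0.095), "D14": (0.475, 0.46, 0.065)},
}

#: c-Fos+ spot densities per mm^2 per region: amygdala hyperactivation in
#: both susceptible archetypes (LA, CeL), reduced anterior dPAG in freezers,
#: reduced posterior dPAG in escapers, ventral PAG recruitment in resilient
#: (anterior) and all shocked groups (posterior).
_IMAGING_DENSITIES = {
    "NoFS": dict(BA=120, LA=100, CeL=90, CeM=90, dPAG_anterior=150,
                 dPAG_posterior=150, vPAG_anterior=100, vPAG_posterior=100),
    "Res": dict(BA=110, LA=90, CeL=100, CeM=110, dPAG_anterior=160,
                dPAG_posterior=160, vPAG_anterior=160, vPAG_posterior=150),
    "Frz": dict(BA=170, LA=180, CeL=170, CeM=140, dPAG_anterior=90,
                dPAG_posterior=140, vPAG_anterior=120, vPAG_posterior=150),
    "Esc": dict(BA=175, LA=185, CeL=175, CeM=140, dPAG_anterior=140,
                dPAG_posterior=90, vPAG_anterior=120, vPAG_posterior=150),
}

#: Study-sized cohort: 16 unshocked controls and 31 shocked animals.
DEFAULT_GROUP_SIZES = {"NoFS": 16, "Res": 11, "Frz": 13, "Esc": 7}


def default_archetypes(
    n_per_group: int | Mapping[str, int] | None = None,
) -> list[ArchetypeSpec]:
    """The packaged worked-example archetypes.

    ``n_per_group`` overrides the study-sized group counts, either with one
    integer for all groups or a mapping per group name.
    """
    if n_per_group is None:
        sizes = dict(DEFAULT_GROUP_SIZES)
    elif isinstance(n_per_group, int):
        sizes = {g: n_per_group for g in GROUPS}
    else:
        sizes = dict(n_per_group)
    behavior = _behavior_table()
    out = []
    for g in GROUPS:
        out.append(ArchetypeSpec(
            name=g,
            n=sizes.get(g, 0),
            behavior={key: dists[g] for key, dists in behavior.items()},
            sleep={cond: transition_matrix(frac)
                   for cond, frac in _SLEEP_FRACTIONS[g].items()},
            imaging=dict(_IMAGING_DENSITIES[g]),
        ))
    return out


# -- generators ----------------------------------------------------------

def _substream(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(c) & 0x7FFFFFFF for c in counters])


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample the full behavioral table for a cohort.

    Returns a long-format table with one row per animal x test x day x
    variable, columns ``animal_id, group, test, day, variable, value``.
    """
    rows = []
    for ai, spec in enumerate(config.archetypes):
        for j in range(spec.n):
            rng = _substream(config.seed, ai, j, _BEHAVIOR)
            animal_id = f"{spec.name}-{j:03d}"
            for (test, day, variable), dist in spec.behavior.items():
                value = dist.sample(rng)
                rows.append((animal_id, spec.name, test, day, variable, float(value)))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "test", "day", "variable", "value"]
    )


def generate_hypnogram(
    spec: ArchetypeSpec,
    condition: str,
    seed: int,
    animal_index: int = 0,
    epoch_seconds: float = 5.0,
    recording_hours: float = 24.0,
) -> Hypnogram:
    """Simulate one recording from the archetype's Markov chain.

    ``condition`` is ``"baseline"`` or ``"D14"``; the chain starts awake
    (lights-on / cue placement) and runs for ``recording_hours``.
    """
    if condition not in spec.sleep:
        raise ValueError(f"no transition matrix for condition {condition!r}")
    mat = np.asarray(spec.sleep[condition], dtype=float)
    n_epochs = int(round(recording_hours * 3600.0 / epoch_seconds))
    purpose = _HYPNO_BASE if condition == "baseline" else _HYPNO_D14
    ai = GROUPS.index(spec.name) if spec.name in GROUPS else 0
    rng = _substream(seed, ai, animal_index, purpose)
    cum = np.cumsum(mat, axis=1)
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.int8)
    s = 0  # start awake
    for t in range(n_epochs):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        states[t] = s
    origin = "lights_on" if condition == "baseline" else "cue_exposure"
    return Hypnogram(np.array(STATES)[states], epoch_seconds=epoch_seconds, origin=origin)


def generate_epoch_features(
    hypnogram: Hypnogram,
    spec: ArchetypeSpec,
    seed: int,
    animal_index: int = 0,
) -> pd.DataFrame:
    """Per-epoch EMG and EEG band-power features with retained ground truth.

    Each epoch's features are drawn from the state-conditional normal
    distributions in ``spec.features`` (floored at a small positive value
    so band-power ratios stay defined); the true state is kept in the
    ``state`` column.
    """
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    fp = spec.features
    ai = GROUPS.index(spec.name) if spec.name in GROUPS else 0
    rng = _substream(seed, ai, animal_index, _FEATURES)
    n = len(hypnogram)
    cols = {"epoch_index": np.arange(n), "state": hypnogram.states}
    for feat in ("emg", "delta", "theta", "spindle"):
        mean = np.array([fp.means[st][feat] for st in hypnogram.states])
        vals = mean + (fp.noise_sd * rng.standard_normal(n) if fp.noise_sd > 0 else 0.0)
        cols[feat] = np.maximum(vals, 1e-3)
    return pd.DataFrame(cols)


def generate_cfos_image(
    width_px: int,
    height_px: int,
    spots: Sequence[tuple[float, float, float]],
    cfos_positive: Sequence[bool] | None = None,
    background: float = 10.0,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a two-channel (nuclear, c-Fos) image with known ground truth.

    ``spots`` is a list of (row, col, radius_px) centers; every spot is a
    Gaussian intensity profile (sigma = radius/2) in the nuclear channel,
    and the subset flagged in ``cfos_positive`` (default: all) also appears
    in the c-Fos channel.  Overlapping spots are allowed — they are the
    watershed test case.  Returns ``(image[2, H, W], ground_truth)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    spots = list(spots)
    if cfos_positive is None:
        cfos_positive = [True] * len(spots)
    if len(cfos_positive) != len(spots):
        raise ValueError("cfos_positive must match the spot list length")
    for r, c, rad in spots:
        if not (0 <= r < height_px and 0 <= c < width_px):
            raise ValueError(f"spot center ({r}, {c}) outside image bounds")
        if rad <= 0:
            raise ValueError("spot radius must be positive")
    rng = np.random.default_rng([int(seed), _IMAGING])
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    nuclear = np.full((height_px, width_px), float(background))
    cfos = np.full((height_px, width_px), float(background))
    for (r, c, rad), pos in zip(spots, cfos_positive):
        sigma = rad / 2.0
        profile = amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
        nuclear += profile
        if pos:
            cfos += profile
    if noise_sd > 0:
        nuclear += noise_sd * rng.standard_normal(nuclear.shape)
        cfos += noise_sd * rng.standard_normal(cfos.shape)
    truth = pd.DataFrame(
        [(r, c, rad, bool(p)) for (r, c, rad), p in zip(spots, cfos_positive)],
        columns=["row", "col", "radius_px", "cfos_positive"],
    )
    return np.stack([nuclear, cfos]), truth


def sample_region_densities(
    spec: ArchetypeSpec,
    seed: int,
    animal_index: int = 0,
    n_slices: int = 3,
    slice_cv: float = 0.15,
) -> pd.DataFrame:
    """Per-slice c-Fos+ densities for one animal across all regions.

    Slice densities vary log-normally around the archetype's regional
    density with coefficient of variation ``slice_cv``.
    """
    ai = GROUPS.index(spec.name) if spec.name in GROUPS else 0
    rng = _substream(seed, ai, animal_index, _IMAGING)
    rows = []
    for region, density in spec.imaging.items():
        for s in range(n_slices):
            val = density * math.exp(slice_cv * rng.standard_normal())
            rows.append({"animal_id": f"{spec.name}-{animal_index:03d}",
                         "region": region, "slice": s, "density_per_mm2": val})
    return pd.DataFrame.from_records(rows)
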