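"""Nonparametric statistics layer.

Group-level inference follows the study's conventions: intergroup
differences are assessed with Kruskal-Wallis ANOVA (tie-corrected H)
followed by Dunn's rank post hoc comparisons when the omnibus test is
significant; within-subject contrasts use Friedman or paired Wilcoxon
tests; habituation ratios are compared to the theoretical value 1 with a
one-sample signed-rank test; and cross-domain associations use Spearman
rank correlations.  The significance threshold is p < 0.05, with the
(0.05, 0.07] band annotated as a trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "TREND_BAND",
    "TestResult",
    "CorrelationResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "friedman",
    "one_sample_vs_theoretical",
    "spearman",
    "build_report",
]

ALPHA = 0.05
TREND_BAND = (0.05, 0.07)


def significance_marker(p: float) -> str:
    if not math.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    if TREND_BAND[0] < p <= TREND_BAND[1]:
        return "trend"
    return "ns"


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int | None
    n: int
    p_value: float
    posthoc: pd.DataFrame | None = None

    @property
    def marker(self) -> str:
        return significance_marker(self.p_value)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int

    @property
    def marker(self) -> str:
        return significance_marker(self.p_value)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    posthoc: bool = True,
    holm: bool = False,
) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups.

    Dunn's pairwise rank comparisons (unadjusted by default; Holm-adjusted
    with ``holm=True``) are attached only when the omnibus p < 0.05.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("kruskal_wallis needs >= 2 groups with >= 2 values each")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]
    n_total = sum(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("Kruskal-Wallis", 0.0, len(arrays) - 1, n_total, 1.0)
    h, p = sps.kruskal(*arrays)
    result = TestResult("Kruskal-Wallis", float(h), len(arrays) - 1, n_total, float(p))
    if posthoc and p < ALPHA:
        result.posthoc = dunn_posthoc(arrays, labels, holm=holm)
    return result


def dunn_posthoc(
    groups: Sequence[np.ndarray], labels: Sequence[str], holm: bool = False
) -> pd.DataFrame:
    """Dunn's z-test pairwise comparisons on the pooled midranks.

    Uses the tie-corrected variance N(N+1)/12 - sum(t^3-t)/(12(N-1)).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"comparison": f"{labels[i]} vs {labels[j]}", "z": z, "p": p})
    out = pd.DataFrame.from_records(rows)
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    out["marker"] = [significance_marker(p) for p in out["p"]]
    return out


def friedman(repeated: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None,
             posthoc: bool = True) -> TestResult:
    """Friedman rank test for a complete animals x timepoints matrix.

    Uses the tie-robust chi-square form (ranking within subjects with
    midranks); post hoc paired Wilcoxon signed-rank comparisons are
    attached when the omnibus p < 0.05.  Missing cells are an error: the
    analysis is complete-case.
    """
    mat = np.asarray(repeated, dtype=float)
    if isinstance(repeated, pd.DataFrame) and labels is None:
        labels = [str(c) for c in repeated.columns]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("friedman needs an n x k matrix with k >= 2 timepoints")
    if not np.all(np.isfinite(mat)):
        raise ValueError("friedman requires a complete matrix (no missing cells)")
    n, k = mat.shape
    labels = list(labels) if labels is not None else [f"t{j}" for j in range(k)]
    r = np.apply_along_axis(sps.rankdata, 1, mat)
    col_sums = r.sum(axis=0)
    # tie-robust form: chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / sum_ij (r_ij - (k+1)/2)^2
    num = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    den = float(np.sum((r - (k + 1) / 2.0) ** 2))
    chi2 = (k - 1) * num / den if den > 0 else 0.0
    p = float(sps.chi2.sf(chi2, k - 1)) if den > 0 else 1.0
    result = TestResult("Friedman", chi2, k - 1, n, p)
    if posthoc and p < ALPHA:
        rows = []
        for i, j in combinations(range(k), 2):
            sub = one_sample_vs_theoretical(mat[:, i] - mat[:, j], 0.0)
            rows.append({"comparison": f"{labels[i]} vs {labels[j]}", "p": sub.p_value,
                         "marker": significance_marker(sub.p_value)})
        result.posthoc = pd.DataFrame.from_records(rows)
    return result


def one_sample_vs_theoretical(values: Sequence[float], theoretical: float = 1.0) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of ``values`` against a constant.

    Exact null distribution for small samples (no ties in the nonzero
    absolute differences); normal approximation with continuity correction
    otherwise.  All values equal to the constant give statistic 0, p = 1.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    diffs = arr - theoretical
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        return TestResult("Wilcoxon signed-rank", 0.0, None, arr.size, 1.0)
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "approx" if (nz.size > 25 or has_ties) else "exact"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return TestResult("Wilcoxon signed-rank", float(res.statistic), None, arr.size,
                      float(res.pvalue))


def spearman(
    x: Sequence[float], y: Sequence[float], pair: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties; two-sided p.

    Pairs with any non-finite member are dropped; a constant vector yields
    rho = NaN (undefined) with p = NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    if xa.size < 3:
        raise ValueError("spearman needs >= 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(pair, float("nan"), float("nan"), xa.size)
    rho, p = sps.spearmanr(xa, ya)
    return CorrelationResult(pair, float(rho), float(p), xa.size)


# -- report bundle -------------------------------------------------------

def _group_summary(df: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    """Median and IQR per phenotype group for the given columns."""
    rows = []
    for group, sub in df.groupby("final", sort=True):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append({
                "group": group, "variable": col, "n": vals.size,
                "median": float(np.median(vals)),
                "iqr_low": float(np.percentile(vals, 25)),
                "iqr_high": float(np.percentile(vals, 75)),
            })
    return pd.DataFrame.from_records(rows)


def build_report(
    scorecard: pd.DataFrame,
    labels: pd.DataFrame,
    sleep: pd.DataFrame | None = None,
    cfos: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> dict:
    """Assemble the summary report over all available pipeline outputs.

    Always includes the behavioral section (phenotype counts, composite and
    radar-domain summaries with Kruskal-Wallis tests across the four
    phenotypes); the sleep section adds D14 architecture summaries and the
    REM%-vs-composite Spearman correlation when a sleep table (indexed by
    animal_id, with a ``REM_percent`` column) is supplied; the c-Fos
    section summarises regional densities.  Deterministic for fixed inputs.
    """
    from .phenotype import phenotype_summary

    merged = scorecard.merge(labels[["animal_id", "final"]], on="animal_id")
    domain_cols = ["composite", "intrusion", "avoidance", "altered_reactivity", "altered_arousal"]
    domain_cols = [c for c in domain_cols if c in merged.columns]
    report: dict = {
        "phenotype_summary": phenotype_summary(labels),
        "behavior_summary": _group_summary(merged, domain_cols),
        "tests": {},
        "correlations": {},
        "radar": {},
        "manifest": dict(manifest or {}),
    }
    grouped = {g: sub for g, sub in merged.groupby("final") if g != "unclassified"}
    order = [g for g in ("NoFS", "FS-Res", "FS-Frz", "FS-Esc") if g in grouped]
    for col in domain_cols:
        samples = [grouped[g][col].dropna().to_numpy() for g in order]
        if len(samples) >= 2 and all(s.size >= 2 for s in samples):
            report["tests"][col] = kruskal_wallis(samples, labels=order)
    radar_cols = [c for c in domain_cols if c != "composite"]
    if radar_cols:
        report["radar"]["behavior"] = (
            merged.groupby("final", sort=True)[radar_cols].median().reset_index()
        )

    if sleep is not None and len(sleep):
        sl = sleep.merge(labels[["animal_id", "final"]], on="animal_id")
        sl = sl.merge(scorecard[["animal_id", "composite"]], on="animal_id")
        metric_cols = [c for c in sl.columns if c.endswith(("_percent", "_episodes",
                                                           "_mean_duration_s", "_latency_min"))]
        report["sleep_summary"] = _group_summary(sl, metric_cols)
        if "REM_percent" in sl.columns:
            ok = sl[["REM_percent", "composite"]].dropna()
            if len(ok) >= 3:
                report["correlations"]["REM_percent_vs_composite"] = spearman(
                    ok["REM_percent"], ok["composite"],
                    pair=("REM_percent", "composite"),
                )
        sleep_groups = {g: sub for g, sub in sl.groupby("final")}
        s_order = [g for g in ("NoFS", "FS-Res", "FS-Frz", "FS-Esc") if g in sleep_groups]
        for col in metric_cols:
            samples = [sleep_groups[g][col].dropna().to_numpy() for g in s_order]
            if len(samples) >= 2 and all(s.size >= 2 for s in samples):
                report["tests"][f"sleep:{col}"] = kruskal_wallis(samples, labels=s_order)

    if cfos is not None and len(cfos):
        cf = cfos.merge(labels[["animal_id", "final"]], on="animal_id")
        region_cols = [c for c in cf.columns if c not in ("animal_id", "final")]
        report["cfos_summary"] = _group_summary(cf, region_cols)
        report["radar"]["cfos"] = (
            cf.groupby("final", sort=True)[region_cols].median().reset_index()
        )
    return report
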