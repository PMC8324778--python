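"""Nonparametric cohort comparisons and summary tables.

Two-group comparisons use the two-sided Mann-Whitney U test (exact null
distribution for small samples, normal approximation with tie and
continuity correction otherwise); multi-group comparisons use
Kruskal-Wallis with tie correction; correlations are Spearman rank
correlations (exact permutation p for small n). Summaries render the
usual case-control table: mean +/- SD per group with a control-vs-patient
p-value and a severity p-value per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupSummary",
    "compare_two_groups",
    "compare_multi_groups",
    "correlate",
    "summarize_cohort",
    "EXACT_MW_MAX_N",
    "EXACT_SPEARMAN_MAX_N",
]

#: combined-sample threshold below which the Mann-Whitney null is enumerated
EXACT_MW_MAX_N = 12
#: sample-size threshold below which the Spearman p is an exact permutation p
EXACT_SPEARMAN_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a over b via midranks (tie-aware)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return ra - a.size * (a.size + 1) / 2.0


def compare_two_groups(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the p-value comes from exhaustive enumeration of
    the permutation null (tie-safe); larger samples use the normal
    approximation with continuity and tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.unique(np.concatenate([a, b])).size == 1:
        return TestResult(_mw_u(a, b), 1.0, "mann-whitney/degenerate", degenerate=True)
    if a.size + b.size <= EXACT_MW_MAX_N:
        res = sps.permutation_test(
            (a, b), lambda x, y: _mw_u(np.asarray(x), np.asarray(y)),
            permutation_type="independent", alternative="two-sided",
            n_resamples=np.inf,
        )
        return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                          "mann-whitney/exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "mann-whitney/asymptotic")


def compare_multi_groups(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square reference."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if np.unique(np.concatenate(arrays)).size == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis/degenerate", degenerate=True)
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal-wallis")


def correlate(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with tie-aware ranking.

    p via exact permutation for n <= 10, t-approximation otherwise; a
    constant input leaves the coefficient undefined (NaN, flagged).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 4:
        raise ValueError("need n >= 4")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return TestResult(math.nan, math.nan, "spearman/degenerate", degenerate=True)

    def rho(xx, yy):
        return sps.spearmanr(xx, yy).statistic

    if xa.size <= EXACT_SPEARMAN_MAX_N:
        res = sps.permutation_test(
            (xa, ya), rho, permutation_type="pairings",
            alternative="two-sided", n_resamples=np.inf,
        )
        return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                          "spearman/exact")
    res = sps.spearmanr(xa, ya)
    return TestResult(float(res.statistic), float(res.pvalue), "spearman/t-approx")


@dataclass
class GroupSummary:
    """Mean +/- SD per group and parameter, with comparison p-values."""

    table: pd.DataFrame
    counts: dict[str, int]
    p_control_vs_patients: dict[str, float]
    p_severity: dict[str, float]
    methods: dict[str, str]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path)
        return path

    def to_text(self) -> str:
        lines = [self.table.to_string(float_format=lambda v: f"{v:.3g}")]
        lines.append("")
        lines.append("group sizes: " + ", ".join(f"{g}={n}" for g, n in self.counts.items()))
        return "\n".join(lines) + "\n"


PATIENT_GROUPS = ("mild", "moderate", "severe")


def summarize_cohort(
    results: pd.DataFrame,
    group_col: str = "group",
    value_cols: Sequence[str] | None = None,
    control_label: str = "control",
) -> GroupSummary:
    """Case-control summary table from per-sample results.

    One row per parameter; per-group ``mean`` and ``sd`` columns, a
    control-vs-pooled-patients Mann-Whitney p-value and an
    across-severities Kruskal-Wallis p-value (when those groups exist
    with enough samples). Missing values are excluded per parameter with
    counts reported.
    """
    if group_col not in results.columns:
        raise ValueError(f"no {group_col!r} column in results")
    if value_cols is None:
        value_cols = [c for c in results.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(results[c])]
    if not value_cols:
        raise ValueError("no numeric parameter columns to summarise")

    groups_present = [g for g in (control_label, *PATIENT_GROUPS)
                      if g in set(results[group_col])]
    counts = {g: int((results[group_col] == g).sum()) for g in groups_present}
    rows, p_two, p_sev, methods = [], {}, {}, {}
    for col in value_cols:
        row: dict[str, float] = {}
        for g in groups_present:
            vals = results.loc[results[group_col] == g, col].dropna()
            row[f"{g}_n"] = len(vals)
            row[f"{g}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
        ctrl = results.loc[results[group_col] == control_label, col].dropna()
        pats = results.loc[results[group_col].isin(PATIENT_GROUPS), col].dropna()
        if len(ctrl) >= 3 and len(pats) >= 3:
            res = compare_two_groups(ctrl, pats)
            row["p_control_vs_patients"] = res.p_value
            p_two[col] = res.p_value
            methods[col] = res.method
        sev = [results.loc[results[group_col] == g, col].dropna()
               for g in PATIENT_GROUPS if g in groups_present]
        sev = [s for s in sev if len(s) >= 2]
        if len(sev) >= 2:
            res = compare_multi_groups(sev)
            row["p_severity"] = res.p_value
            p_sev[col] = res.p_value
        rows.append(row)
    table = pd.DataFrame(rows, index=list(value_cols))
    table.index.name = "parameter"
    return GroupSummary(table, counts, p_two, p_sev, methods)
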