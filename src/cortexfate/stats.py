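"""Group-comparison statistics: Welch tests, ANOVA, one-sample t, BH FDR,
and replicate-averaged time-course comparisons.

All tests are two-sided. Welch tests do not assume equal variances and use
the Welch-Satterthwaite degrees of freedom. Multiple testing within a
family is corrected with the Benjamini-Hochberg step-up procedure.
Time-course comparisons first average replicate samples of the same
differentiation, pool samples into named dpi windows, and then run per-gene
Welch tests between groups with FDR correction across genes within each
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import SampleMetadata
from .normalize import ExpressionMatrix


@dataclass
class TestResult:
    comparison: str
    statistic: float
    df: float | tuple[float, float]
    p_raw: float
    n: tuple[int, ...]
    effect: float
    p_adjusted: float | None = None


@dataclass
class TimepointPooling:
    """Named dpi windows, e.g. {"~17.5": (17, 18), "~35": (30, 39)}."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"~17.5": (17.0, 18.0), "~35": (30.0, 39.0)}
    )

    def __post_init__(self) -> None:
        spans = sorted(self.windows.values())
        for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
            if lo1 > hi1:
                raise ValueError("window bounds out of order")
            if lo2 <= hi1:
                raise ValueError("pooling windows overlap")

    def window_of(self, dpi: float) -> str | None:
        for name, (lo, hi) in self.windows.items():
            if lo <= dpi <= hi:
                return name
        return None


def welch_test(a: Sequence[float], b: Sequence[float],
               comparison: str = "") -> TestResult:
    """Unpaired two-sided Welch's t test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    effect = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        if effect == 0:
            warnings.warn("both groups constant and equal; p = 1 by convention",
                          stacklevel=2)
            return TestResult(comparison, 0.0, float(len(a) + len(b) - 2),
                              1.0, (len(a), len(b)), 0.0)
        warnings.warn("both groups constant with different means; p = 0 limit",
                      stacklevel=2)
        return TestResult(comparison, float(np.sign(effect)) * np.inf,
                          float(len(a) + len(b) - 2), 0.0,
                          (len(a), len(b)), effect)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(comparison, float(res.statistic), float(res.df),
                      float(res.pvalue), (len(a), len(b)), effect)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def one_way_anova(groups: Sequence[Sequence[float]],
                  comparison: str = "") -> TestResult:
    """One-way fixed-effects ANOVA from explicit sums of squares."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >=2 groups, each with n >= 1")
    N = sum(len(g) for g in gs)
    k = len(gs)
    if N <= k:
        raise ValueError("total n must exceed number of groups")
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    df = (k - 1, N - k)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(comparison, 0.0, df, 1.0,
                              tuple(len(g) for g in gs), 0.0)
        warnings.warn("zero within-group variance with unequal means; p = 0 limit",
                      stacklevel=2)
        return TestResult(comparison, np.inf, df, 0.0,
                          tuple(len(g) for g in gs), float(ss_between))
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(F, df[0], df[1]))
    return TestResult(comparison, float(F), df, p,
                      tuple(len(g) for g in gs), float(ss_between / (k - 1)))


def one_sample_t(values: Sequence[float], mu: float = 0.0,
                 comparison: str = "") -> TestResult:
    """Two-sided one-sample Student's t test against ``mu``."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    if v.var(ddof=1) == 0:
        raise ValueError("zero variance; one-sample t undefined")
    res = sps.ttest_1samp(v, mu)
    return TestResult(comparison, float(res.statistic), float(len(v) - 1),
                      float(res.pvalue), (len(v),), float(v.mean() - mu))


def average_replicates(
    expr: ExpressionMatrix, meta: SampleMetadata,
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Average samples of the same differentiation (uin); rows indexed by uin."""
    sub = expr.values.loc[list(sample_ids)]
    uin = meta.table.loc[sub.index, "uin"]
    return sub.groupby(uin.to_numpy()).mean()


def pool_and_compare_timecourse(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    grouping: Mapping[str, str],
    pooling: TimepointPooling | None = None,
) -> pd.DataFrame:
    """Per-gene Welch tests between two groups within each pooled time point.

    ``grouping`` maps line -> group name (exactly two groups). Within each
    window, replicate samples of the same differentiation are averaged
    first; genes are FDR-corrected within the window. Windows where either
    group has fewer than 2 differentiations are skipped with a warning, as
    are samples whose dpi falls in no window.
    """
    pooling = pooling or TimepointPooling()
    meta.require_samples(expr.sample_ids)
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise ValueError("grouping must define exactly 2 groups")

    info = meta.table.loc[expr.sample_ids]
    rows = []
    for name in pooling.windows:
        in_win = info["dpi"].map(lambda d: pooling.window_of(d) == name)
        win_ids = list(info.index[in_win])
        if not win_ids:
            warnings.warn(f"window {name}: no samples", stacklevel=2)
            continue
        by_group: dict[str, pd.DataFrame] = {}
        for g in groups:
            ids = [s for s in win_ids if grouping.get(info.loc[s, "line"]) == g]
            by_group[g] = average_replicates(expr, meta, ids) if ids else \
                pd.DataFrame(columns=expr.values.columns)
        if any(len(by_group[g]) < 2 for g in groups):
            warnings.warn(
                f"window {name}: fewer than 2 differentiations in a group; "
                "tests skipped", stacklevel=2,
            )
            continue
        res = []
        for gene in expr.values.columns:
            r = welch_test(by_group[groups[0]][gene], by_group[groups[1]][gene],
                           comparison=f"{name}:{gene}")
            res.append((gene, r))
        padj = fdr_adjust([r.p_raw for _, r in res])
        for (gene, r), pa in zip(res, padj):
            rows.append({
                "window": name, "gene": gene, "t": r.statistic, "df": r.df,
                "p_raw": r.p_raw, "p_adjusted": float(pa),
                "effect": r.effect, "n1": r.n[0], "n2": r.n[1],
            })
    dropped = [s for s in expr.sample_ids
               if pooling.window_of(info.loc[s, "dpi"]) is None]
    if dropped:
        warnings.warn(
            f"{len(dropped)} samples outside all pooling windows excluded",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
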