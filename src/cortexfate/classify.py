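"""Threshold-based regional-outcome classification and line-bias statistics.

Five outcome classes are called from four marker genes on log2 expression,
in a fixed decision order (caudal calls take precedence):

1. FOXG1 < foxg1_verylow AND DLX5 < dlx5_verylow  -> highly_caudalized
2. FOXG1 < foxg1_low     AND DLX5 < dlx5_low      -> partially_caudalized
3. NKX2-1 >= nkx21_high  AND PAX6 < pax6_low      -> highly_ventralized
4. NKX2-1 >= nkx21_high  AND PAX6 >= pax6_low     -> partially_ventralized
5. otherwise                                      -> dorsalized

Thresholds can come from config or be re-derived from paired early/late
data (``fit_thresholds``), choosing midpoint cutoffs that maximize
agreement with late-stage outcomes. Per-line outcome frequencies are
summarized with a Newcombe hybrid Wilson 95% interval for the difference
between a line's dorsal frequency and the overall dorsal frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import SampleMetadata
from .normalize import ExpressionMatrix

OUTCOME_LABELS = (
    "dorsalized",
    "partially_ventralized",
    "highly_ventralized",
    "partially_caudalized",
    "highly_caudalized",
)

MARKER_GENES = ("FOXG1", "DLX5", "NKX2-1", "PAX6")

#: late-stage cluster -> outcome label used when fitting thresholds
LATE_CLUSTER_OUTCOME = {
    "LC1": "highly_ventralized",
    "LC2": "dorsalized",
    "LC3": "partially_caudalized",
}


@dataclass
class ThresholdSet:
    """Fitted or configured log2 cutoffs driving the 5-class decision tree."""

    foxg1_low: float
    dlx5_low: float
    nkx21_high: float
    pax6_low: float
    foxg1_verylow: float = float("-inf")
    dlx5_verylow: float = float("-inf")
    provenance: str = "config"

    def __post_init__(self) -> None:
        if self.foxg1_verylow > self.foxg1_low or self.dlx5_verylow > self.dlx5_low:
            raise ValueError("verylow cutoffs must not exceed low cutoffs")
        for name in ("foxg1_low", "dlx5_low", "nkx21_high", "pax6_low"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def classify(expr: ExpressionMatrix, th: ThresholdSet) -> pd.Series:
    """Assign one outcome label per sample from the marker decision tree."""
    if expr.scale != "log2":
        raise ValueError("classification is defined on log2 expression")
    for g in MARKER_GENES:
        if g not in expr.values.columns:
            raise KeyError(f"marker gene {g!r} missing from expression matrix")
    f = expr.values["FOXG1"].to_numpy()
    d = expr.values["DLX5"].to_numpy()
    n = expr.values["NKX2-1"].to_numpy()
    p = expr.values["PAX6"].to_numpy()

    labels = np.full(len(f), "dorsalized", dtype=object)
    ventral = n >= th.nkx21_high
    labels[ventral & (p >= th.pax6_low)] = "partially_ventralized"
    labels[ventral & (p < th.pax6_low)] = "highly_ventralized"
    caudal = (f < th.foxg1_low) & (d < th.dlx5_low)
    labels[caudal] = "partially_caudalized"
    labels[(f < th.foxg1_verylow) & (d < th.dlx5_verylow)] = "highly_caudalized"
    return pd.Series(labels, index=expr.values.index, name="outcome")


# ---------------------------------------------------------------------------
# threshold fitting
# ---------------------------------------------------------------------------

def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values, plus outside sentinels."""
    v = np.unique(values)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


def _margins(cuts: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.abs(values[:, None] - cuts[None, :]).min(axis=0)


def _pick_best(agree: np.ndarray, cx: np.ndarray, cy: np.ndarray,
               mx: np.ndarray, my: np.ndarray) -> tuple[float, float]:
    """Maximize agreement; ties broken by larger minimum margin to the
    training values, then by the lexicographically smallest (cx, cy)."""
    margin = np.minimum(mx[:, None], my[None, :])
    best = None
    for i in range(len(cx)):
        for j in range(len(cy)):
            key = (agree[i, j], margin[i, j], -cx[i], -cy[j])
            if best is None or key > best[0]:
                best = (key, cx[i], cy[j])
    return float(best[1]), float(best[2])


def _fit_caudal(x: np.ndarray, y: np.ndarray,
                is_caudal: np.ndarray) -> tuple[float, float]:
    """Joint (FOXG1, DLX5) cutoffs: caudal iff both below."""
    cx, cy = _candidate_cutoffs(x), _candidate_cutoffs(y)
    A = x[:, None] < cx[None, :]          # samples x candidates
    B = y[:, None] < cy[None, :]
    t = is_caudal.astype(float)
    # agree(cx,cy) = sum_s [ (A&B)==t ] = sum(1-t) + sum_s A*B*(2t-1)
    hits = float((1 - t).sum()) + (A * (2 * t - 1)[:, None]).T @ B
    return _pick_best(hits, cx, cy, _margins(cx, x), _margins(cy, y))


def _fit_ventral(n: np.ndarray, p: np.ndarray,
                 target: np.ndarray) -> tuple[float, float]:
    """Joint (NKX2-1, PAX6) cutoffs maximizing strict 3-class agreement
    among {highly_ventralized, partially_ventralized, dorsalized}."""
    cn, cp = _candidate_cutoffs(n), _candidate_cutoffs(p)
    N = n[:, None] >= cn[None, :]
    Plow = p[:, None] < cp[None, :]
    t_hv = (target == "highly_ventralized").astype(float)
    t_pv = (target == "partially_ventralized").astype(float)
    t_d = (target == "dorsalized").astype(float)
    agree = (
        (N * t_hv[:, None]).T @ Plow
        + (N * t_pv[:, None]).T @ (1.0 - Plow)
        + (((1.0 - N) * t_d[:, None]).sum(axis=0))[:, None]
    )
    return _pick_best(agree, cn, cp, _margins(cn, n), _margins(cp, p))


def fit_thresholds(
    early: ExpressionMatrix,
    late_labels: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    verylow_offset: float = 2.0,
) -> ThresholdSet:
    """Derive marker cutoffs from paired early samples and late outcomes.

    ``late_labels`` maps each pair's late id to a late cluster ("LC1"-"LC3")
    or directly to an outcome label. Caudal cutoffs (FOXG1, DLX5) are fitted
    first, jointly separating partially/highly caudalized outcomes from the
    rest; ventral cutoffs (NKX2-1, PAX6) are then fitted on the remaining
    samples. A predicted partially_ventralized counts as agreeing with a
    dorsalized late outcome (early partially-ventral differentiations do not
    separate from dorsalized ones at the late stage). Verylow cutoffs are
    fitted only when highly-caudalized training examples exist; otherwise
    they fall ``verylow_offset`` log2 units below the low cutoffs.

    Non-separable training data yields the best-agreement thresholds with a
    warning listing the misclassified pairs.
    """
    if expr_missing := [g for g in MARKER_GENES if g not in early.values.columns]:
        raise KeyError(f"marker genes absent from early matrix: {expr_missing}")
    early_ids = [p[0] for p in pairs]
    outcomes = np.array([
        LATE_CLUSTER_OUTCOME.get(late_labels[p[1]], late_labels[p[1]])
        for p in pairs
    ])
    unknown = set(outcomes) - set(OUTCOME_LABELS)
    if unknown:
        raise ValueError(f"unknown late outcomes {sorted(unknown)}")

    M = early.values.loc[early_ids, list(MARKER_GENES)]
    fox = M["FOXG1"].to_numpy()
    dlx = M["DLX5"].to_numpy()
    nkx = M["NKX2-1"].to_numpy()
    pax = M["PAX6"].to_numpy()

    is_caudal = np.isin(outcomes, ["partially_caudalized", "highly_caudalized"])
    foxg1_low, dlx5_low = _fit_caudal(fox, dlx, is_caudal)

    pred_caudal = (fox < foxg1_low) & (dlx < dlx5_low)
    rest = ~pred_caudal
    nkx21_high, pax6_low = _fit_ventral(nkx[rest], pax[rest], outcomes[rest])

    if np.any(outcomes == "highly_caudalized") and pred_caudal.any():
        caud = pred_caudal
        is_hc = outcomes[caud] == "highly_caudalized"
        foxg1_vl, dlx5_vl = _fit_caudal(fox[caud], dlx[caud], is_hc)
        foxg1_vl = min(foxg1_vl, foxg1_low)
        dlx5_vl = min(dlx5_vl, dlx5_low)
    else:
        foxg1_vl = foxg1_low - verylow_offset
        dlx5_vl = dlx5_low - verylow_offset

    th = ThresholdSet(
        foxg1_low=foxg1_low, dlx5_low=dlx5_low,
        nkx21_high=nkx21_high, pax6_low=pax6_low,
        foxg1_verylow=foxg1_vl, dlx5_verylow=dlx5_vl,
        provenance="fitted",
    )
    pred = classify(
        ExpressionMatrix(values=M, scale="log2"), th
    ).to_numpy()
    mismatch = ~_labels_agree(pred, outcomes)
    if mismatch.any():
        bad = [pairs[i] for i in np.flatnonzero(mismatch)]
        warnings.warn(
            f"training data not separable; misclassified pairs: {bad}",
            stacklevel=2,
        )
    return th


def _labels_agree(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    ok = pred == truth
    # early partially-ventralized maps to dorsal-like late outcome
    ok |= (pred == "partially_ventralized") & (truth == "dorsalized")
    return ok


def training_agreement(
    early: ExpressionMatrix, late_labels: Mapping[str, str],
    pairs: Sequence[tuple[str, str]], th: ThresholdSet,
) -> float:
    """Fraction of training pairs whose early call agrees with the late label."""
    early_ids = [p[0] for p in pairs]
    outcomes = np.array([
        LATE_CLUSTER_OUTCOME.get(late_labels[p[1]], late_labels[p[1]])
        for p in pairs
    ])
    sub = ExpressionMatrix(
        values=early.values.loc[early_ids, list(MARKER_GENES)], scale="log2"
    )
    pred = classify(sub, th).to_numpy()
    return float(np.mean(_labels_agree(pred, outcomes)))


# ---------------------------------------------------------------------------
# line / genotype summaries
# ---------------------------------------------------------------------------

def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def line_bias_interval(
    line_dorsal: tuple[int, int], overall_dorsal: tuple[int, int],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Newcombe hybrid score interval for p_line - p_overall.

    Wilson intervals (l1,u1), (l2,u2) for the two proportions are combined as
    (d - sqrt((p1-l1)^2 + (u2-p2)^2), d + sqrt((u1-p1)^2 + (p2-l2)^2)) with
    d = p1 - p2. The caller supplies the overall counts; use
    :func:`line_frequencies` for the convention that the overall excludes
    the line under test (making the two proportions independent).
    """
    k1, n1 = line_dorsal
    k2, n2 = overall_dorsal
    if n1 < 1:
        raise ValueError("line has no differentiations")
    if n2 < 1:
        raise ValueError("overall comparison group is empty")
    p1, p2 = k1 / n1, k2 / n2
    l1, u1 = wilson_interval(k1, n1, alpha)
    l2, u2 = wilson_interval(k2, n2, alpha)
    d = p1 - p2
    lo = d - float(np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2))
    hi = d + float(np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2))
    return lo, hi


def line_frequencies(
    labels: pd.Series, meta: SampleMetadata, min_n: int = 2,
) -> pd.DataFrame:
    """Per-line outcome counts/frequencies with dorsal-bias Wilson intervals.

    Lines with fewer than ``min_n`` differentiations are excluded. The
    overall dorsal frequency is computed over all included differentiations;
    each line's bias interval compares it to the overall *excluding* that
    line's own differentiations.
    """
    meta.require_samples(labels.index)
    lines = meta.table.loc[labels.index, "line"]
    df = pd.DataFrame({"line": lines, "outcome": labels})
    sizes = df.groupby("line").size()
    keep = sizes[sizes >= min_n].index
    df = df[df["line"].isin(keep)]
    if df.empty:
        raise ValueError(f"no line has >= {min_n} differentiations")

    total_n = len(df)
    total_dorsal = int((df["outcome"] == "dorsalized").sum())

    rows = []
    for line, grp in df.groupby("line", sort=True):
        n = len(grp)
        counts = {f"n_{lab}": int((grp["outcome"] == lab).sum())
                  for lab in OUTCOME_LABELS}
        freqs = {f"freq_{lab}": counts[f"n_{lab}"] / n for lab in OUTCOME_LABELS}
        k = counts["n_dorsalized"]
        k_rest = total_dorsal - k
        n_rest = total_n - n
        if n_rest == 0:
            # only one line included: no comparison group, bias undefined
            warnings.warn(f"line {line}: no other differentiations to "
                          "compare against; bias interval undefined",
                          stacklevel=2)
            lo = hi = diff = float("nan")
            flag = False
        else:
            lo, hi = line_bias_interval((k, n), (k_rest, n_rest))
            diff = k / n - k_rest / n_rest
            flag = bool(lo > 0 or hi < 0)
        rows.append({
            "line": line, "n_differentiations": n, **counts, **freqs,
            "dorsal_diff": diff,
            "wilson_lo": lo, "wilson_hi": hi,
            "biased_flag": flag,
        })
    out = pd.DataFrame(rows).set_index("line")
    out.attrs["overall_dorsal_freq"] = total_dorsal / total_n
    out.attrs["n_total"] = total_n
    return out


def genotype_frequencies(
    line_table: pd.DataFrame, genotype_map: Mapping[str, str],
    min_lines: int = 3,
) -> pd.DataFrame:
    """Equal-line-weight outcome frequencies per genotype.

    Each line contributes its frequency vector once, regardless of how many
    differentiations it has; genotypes with fewer than ``min_lines`` lines
    are excluded. Also reports the "partly cortical" rate
    (dorsalized + partially_ventralized).
    """
    missing = set(line_table.index) - set(genotype_map)
    if missing:
        raise KeyError(f"lines without genotype: {sorted(missing)}")
    freq_cols = [f"freq_{lab}" for lab in OUTCOME_LABELS]
    tbl = line_table[freq_cols].copy()
    tbl["genotype"] = [genotype_map[l] for l in line_table.index]
    counts = tbl.groupby("genotype").size()
    keep = counts[counts >= min_lines].index
    out = tbl[tbl["genotype"].isin(keep)].groupby("genotype")[freq_cols].mean()
    out["n_lines"] = counts[out.index]
    out["freq_partly_cortical"] = (
        out["freq_dorsalized"] + out["freq_partially_ventralized"]
    )
    return out
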