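"""nCounter-style normalization, QC, expression filtering and codeset merging.

The normalization chain mirrors the standard nSolver workflow for targeted
expression panels:

1. per-sample background = geometric mean of the negative control probes,
   subtracted from every other probe and clamped at zero;
2. a positive-control normalization factor — the dataset geometric mean of
   per-sample positive-probe geometric means divided by the sample's own —
   multiplied into every probe;
3. a housekeeping normalization factor computed the same way on the
   housekeeping probes after step 2;
4. samples whose positive or housekeeping factor falls outside
   [0.25, 4] are flagged as outliers, removed, and the surviving samples are
   re-normalized once from scratch.

The returned matrix contains endogenous genes only, on a linear scale, with
per-sample QC (background, both factors, outlier flag and reason).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, FormatError


@dataclass
class NormalizationConfig:
    """Tunable constants of the normalization chain (defaults are the study's)."""

    factor_max: float = 4.0
    factor_min: float = 0.25
    expression_floor: float = 30.0   # "expressed" = above this in >= 1 sample
    log_floor: float = 1.0           # linear counts clamped here before log2
    reference_rule: str = "dataset_geomean"

    def __post_init__(self) -> None:
        if not (self.factor_min < 1.0 < self.factor_max):
            raise ValueError("need factor_min < 1 < factor_max")
        if self.expression_floor <= 0:
            raise ValueError("expression_floor must be positive")
        if self.reference_rule != "dataset_geomean":
            raise ValueError(f"unknown reference rule {self.reference_rule!r}")


@dataclass
class ExpressionMatrix:
    """Normalized expression, samples x genes, linear or log2 scale."""

    values: pd.DataFrame
    scale: str = "linear"             # {"linear", "log2"}
    qc: pd.DataFrame | None = None    # per-sample: background, pos_factor,
                                      # hk_factor, outlier_flag, reason

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


def geometric_mean(values: Sequence[float] | np.ndarray) -> float:
    """exp(mean(log(values))) for strictly positive values.

    Raises on empty input; non-positive entries raise — callers decide how
    zeros are prepared (background uses a zeros-to-1 rule, control factors
    treat a zero geometric mean as a QC failure).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty input")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _background_geomean(values: np.ndarray) -> float:
    # All-zero negative probes are legal (background 0); otherwise zeros are
    # replaced by 1 so the log is defined while keeping "low" low.
    if np.all(values == 0):
        return 0.0
    return geometric_mean(np.where(values == 0, 1.0, values))


def _control_geomean(values: np.ndarray) -> float:
    # Geometric mean of background-subtracted control counts; any zero pulls
    # the mean to 0, which flags the sample as invalid upstream.
    if (values <= 0).any():
        return 0.0
    return geometric_mean(values)


def _normalize_pass(cm: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One full background/positive/housekeeping pass; no outlier handling."""
    neg = cm.probes_of_class("negative")
    pos = cm.probes_of_class("positive")
    hk = cm.probes_of_class("housekeeping")
    endo = cm.probes_of_class("endogenous")
    counts = cm.counts.astype(float)

    background = counts[neg].apply(
        lambda row: _background_geomean(row.to_numpy()), axis=1
    ) if neg else pd.Series(0.0, index=counts.index)

    # background subtraction, clamped at 0 (applies to all non-negative probes)
    work = counts[pos + hk + endo].sub(background, axis=0).clip(lower=0.0)

    pos_gm = work[pos].apply(lambda r: _control_geomean(r.to_numpy()), axis=1)
    valid = pos_gm > 0
    pos_factor = pd.Series(np.nan, index=counts.index)
    if valid.any():
        ref_pos = geometric_mean(pos_gm[valid].to_numpy())
        pos_factor[valid] = ref_pos / pos_gm[valid]
    work = work.mul(pos_factor, axis=0)

    hk_gm = work[hk].apply(
        lambda r: _control_geomean(r.to_numpy()) if np.isfinite(r).all() else 0.0,
        axis=1,
    )
    hk_valid = valid & (hk_gm > 0)
    hk_factor = pd.Series(np.nan, index=counts.index)
    if hk_valid.any():
        ref_hk = geometric_mean(hk_gm[hk_valid].to_numpy())
        hk_factor[hk_valid] = ref_hk / hk_gm[hk_valid]
    work = work.mul(hk_factor, axis=0)

    qc = pd.DataFrame(
        {
            "background": background,
            "pos_factor": pos_factor,
            "hk_factor": hk_factor,
        }
    )
    return work[endo], qc


def normalize_dataset(
    raw: CountMatrix, cfg: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Run the full normalization chain with one outlier-removal pass.

    Samples with a positive-control or housekeeping factor outside
    ``[cfg.factor_min, cfg.factor_max]``, or whose control geometric mean is
    zero after background subtraction, are flagged and removed; the
    surviving samples are re-normalized from scratch (a single pass, per the
    described two-step workflow). QC rows are kept for removed samples.
    """
    cfg = cfg or NormalizationConfig()
    for cls in ("negative", "positive", "housekeeping"):
        if not raw.probes_of_class(cls):
            raise FormatError(f"normalization requires >=1 {cls} probe")
    if len(raw.sample_ids) < 2:
        raise FormatError("normalization requires >=2 samples")

    values, qc = _normalize_pass(raw)
    reasons = pd.Series("", index=qc.index)
    invalid = qc["pos_factor"].isna() | qc["hk_factor"].isna()
    reasons[invalid] = "control geometric mean zero after background subtraction"
    out_of_range = ~invalid & (
        (qc["pos_factor"] < cfg.factor_min) | (qc["pos_factor"] > cfg.factor_max)
        | (qc["hk_factor"] < cfg.factor_min) | (qc["hk_factor"] > cfg.factor_max)
    )
    reasons[out_of_range] = "normalization factor outside [%g, %g]" % (
        cfg.factor_min, cfg.factor_max
    )
    outliers = invalid | out_of_range

    if outliers.any():
        keep = [s for s in raw.sample_ids if not outliers[s]]
        if len(keep) < 2:
            raise FormatError("fewer than 2 samples survive outlier removal")
        for s, why in reasons[outliers].items():
            warnings.warn(f"sample {s} removed: {why}", stacklevel=2)
        sub = CountMatrix(
            counts=raw.counts.loc[keep].copy(),
            probe_class=raw.probe_class.copy(),
            codeset_id=raw.codeset_id,
        )
        values, qc_kept = _normalize_pass(sub)
        # a sample can only go invalid in the re-pass if controls degenerate
        still_bad = qc_kept["pos_factor"].isna() | qc_kept["hk_factor"].isna()
        if still_bad.any():
            bad = list(qc_kept.index[still_bad])
            for s in bad:
                warnings.warn(
                    f"sample {s} removed in re-normalization: control geometric "
                    "mean zero", stacklevel=2,
                )
                reasons[s] = "control geometric mean zero in re-normalization"
                outliers[s] = True
            values = values.drop(index=bad)
            qc_kept = qc_kept.drop(index=bad)
        qc.loc[qc_kept.index, qc_kept.columns] = qc_kept

    qc["outlier_flag"] = outliers
    qc["reason"] = reasons
    values = values.loc[[s for s in raw.sample_ids if not outliers[s]]]
    return ExpressionMatrix(values=values, scale="linear", qc=qc)


def filter_expressed(
    expr: ExpressionMatrix, floor: float = 30.0
) -> ExpressionMatrix:
    """Keep genes whose expression exceeds ``floor`` in at least one sample.

    Strictly above: a gene peaking exactly at the floor is dropped. Defined
    on normalized linear counts only.
    """
    if expr.scale != "linear":
        raise ValueError("expression filter is defined on linear-scale counts")
    keep = expr.values.columns[(expr.values > floor).any(axis=0)]
    return ExpressionMatrix(values=expr.values[keep].copy(), scale="linear",
                            qc=expr.qc)


def log2_transform(expr: ExpressionMatrix, log_floor: float = 1.0) -> ExpressionMatrix:
    """log2 with a floor: values below ``log_floor`` are clamped before the log."""
    if expr.scale != "linear":
        raise ValueError("input is already log-scale")
    vals = np.log2(expr.values.clip(lower=log_floor))
    return ExpressionMatrix(values=vals, scale="log2", qc=expr.qc)


def merge_codesets(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    bridge: Sequence[tuple[str, str]],
    eps: float = 0.5,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Merge two codesets via bridge samples profiled on both.

    For each shared gene the scale factor is the geometric mean over bridge
    pairs of the a/b expression ratio; every ``b`` sample is rescaled by it.
    ``eps`` is added to both sides of a ratio only when one side is zero, so
    the merge is exact whenever ``b`` is an exact per-gene rescaling of ``a``
    on positive bridge values. Bridge duplicates keep their ``a`` version.

    Returns the merged matrix (shared genes, union of samples) and a
    per-gene factor report.
    """
    if a.scale != "linear" or b.scale != "linear":
        raise ValueError("merge operates on linear-scale expression")
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise FormatError("no shared genes between codesets")
    if len(bridge) < 2:
        raise FormatError("need >=2 bridge pairs")
    for sa, sb in bridge:
        if sa not in a.values.index:
            raise FormatError(f"bridge sample {sa!r} missing from first codeset")
        if sb not in b.values.index:
            raise FormatError(f"bridge sample {sb!r} missing from second codeset")

    av = a.values.loc[[sa for sa, _ in bridge], shared].to_numpy(dtype=float)
    bv = b.values.loc[[sb for _, sb in bridge], shared].to_numpy(dtype=float)
    zero = (av <= 0) | (bv <= 0)
    num = np.where(zero, av + eps, av)
    den = np.where(zero, bv + eps, bv)
    factors = np.exp(np.mean(np.log(num / den), axis=0))
    report = pd.DataFrame({"gene": shared, "factor": factors}).set_index("gene")

    b_scaled = b.values[shared].mul(report["factor"], axis=1)
    bridge_b = {sb for _, sb in bridge}
    b_keep = [s for s in b.values.index if s not in bridge_b]
    merged = pd.concat([a.values[shared], b_scaled.loc[b_keep]])
    if merged.index.duplicated().any():
        raise FormatError("sample ids collide between codesets")
    return ExpressionMatrix(values=merged, scale="linear"), report
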