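"""Axis-of-variation analysis: PCA, Pearson-distance clustering, correlations.

PCA is performed on log2 expression, gene-centered with no unit-variance
scaling, with a deterministic sign convention (the largest-magnitude entry
of each loading column is positive). Sample clustering uses 1 - Pearson
correlation as the distance with complete linkage. Early-to-late analyses
correlate late-stage marker expression with early-stage expression across
paired differentiations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .normalize import ExpressionMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame             # samples x components
    loadings: pd.DataFrame           # genes x components
    variance_explained: np.ndarray   # fraction per component
    loading_z: pd.DataFrame          # per-component z-scored loadings


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: dict[int, np.ndarray]    # k -> 1-based labels, largest cluster = 1
    linkage_matrix: np.ndarray


def run_pca(expr: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """Gene-centered PCA of a log2 expression matrix via SVD."""
    if expr.scale != "log2":
        raise ValueError("PCA is defined on log2-scale expression")
    X = expr.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs >=3 samples and >=2 genes")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p) if n_components is None else min(n_components, min(n - 1, p))
    loadings = Vt[:k].T
    # sign convention: largest-magnitude entry of each loading column positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    var = s**2
    comp = [f"PC{i+1}" for i in range(k)]
    load_df = pd.DataFrame(loadings, index=expr.values.columns, columns=comp)
    z = (load_df - load_df.mean()) / load_df.std(ddof=1)
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.values.index, columns=comp),
        loadings=load_df,
        variance_explained=var[:k] / var.sum(),
        loading_z=z,
    )


def top_contributors(
    pca: PCAResult, component: str | int = "PC1", z_threshold: float = 2.0
) -> pd.Series:
    """Genes with |z-scored loading| above ``z_threshold`` on one component.

    Returns the signed z scores (for plotting), sorted by |z| descending.
    """
    comp = f"PC{component}" if isinstance(component, int) else component
    if comp not in pca.loading_z.columns:
        raise KeyError(f"no component {comp!r}")
    z = pca.loading_z[comp]
    hits = z[np.abs(z) > z_threshold]
    return hits.reindex(hits.abs().sort_values(ascending=False).index)


def pearson_distance_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Condensed 1 - Pearson distance between samples over genes."""
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = expr.values.index[sd == 0][0]
        raise ValueError(
            f"sample {bad!r} has zero variance across genes; "
            "correlation distance undefined"
        )
    return pdist(X, metric="correlation")


def _renumber_by_size(raw_labels: np.ndarray) -> np.ndarray:
    """Relabel clusters so the largest is 1; ties broken by first sample."""
    order = sorted(
        set(raw_labels),
        key=lambda c: (-(raw_labels == c).sum(), int(np.argmax(raw_labels == c))),
    )
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw_labels])


def hier_cluster(
    expr: ExpressionMatrix, k_values: Sequence[int] = (2, 3, 4, 5),
    method: str = "complete",
) -> ClusterAssignment:
    """Agglomerative clustering on 1 - Pearson distances, cut at each k."""
    if len(expr.sample_ids) < max(k_values):
        raise ValueError("more clusters requested than samples")
    d = pearson_distance_matrix(expr)
    Z = linkage(d, method=method)
    labels = {
        int(k): _renumber_by_size(fcluster(Z, t=k, criterion="maxclust"))
        for k in k_values
    }
    return ClusterAssignment(sample_ids=expr.sample_ids, labels=labels,
                             linkage_matrix=Z)


def correlate_early_late(
    early: ExpressionMatrix,
    late: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    late_markers: Sequence[str],
    r_filter: float | None = None,
) -> pd.DataFrame:
    """Correlate late-stage marker expression with early-stage expression.

    For each (late marker, early gene) cell: Pearson r across paired
    differentiations. With ``r_filter`` set (e.g. 0.75), early genes are kept
    only if |r| exceeds it for at least one marker.
    """
    if len(pairs) < 3:
        raise ValueError("need >=3 early/late pairs")
    e_ids = [p[0] for p in pairs]
    l_ids = [p[1] for p in pairs]
    missing = [m for m in late_markers if m not in late.values.columns]
    if missing:
        raise KeyError(f"late markers absent: {missing}")
    E = early.values.loc[e_ids]                       # pairs x early genes
    L = late.values.loc[l_ids, list(late_markers)]    # pairs x markers
    Ec = E - E.mean()
    Lc = L - L.mean()
    denom = np.outer(E.std(ddof=1), L.std(ddof=1)) * (len(pairs) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec.to_numpy().T @ Lc.to_numpy()) / denom
    table = pd.DataFrame(r, index=E.columns, columns=late_markers)
    if r_filter is not None:
        table = table[(table.abs() > r_filter).any(axis=1)]
    return table


def correlation_of_correlations(
    early: ExpressionMatrix,
    late: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
) -> tuple[float, pd.DataFrame]:
    """Compare cross-time gene-pair correlations with within-early ones.

    For every ordered gene pair (g, h), g != h, over genes shared between
    the matrices: the cross-time correlation r(late g, early h) across
    paired differentiations is paired with the within-early correlation
    r(g, h) across the full early dataset; returns the Pearson correlation
    of the two collections plus the underlying vectors.
    """
    shared = [g for g in early.gene_ids if g in set(late.gene_ids)]
    if len(shared) < 10:
        raise ValueError("need >=10 shared genes")
    e_ids = [p[0] for p in pairs]
    l_ids = [p[1] for p in pairs]
    E = early.values.loc[e_ids, shared].to_numpy(dtype=float)
    L = late.values.loc[l_ids, shared].to_numpy(dtype=float)
    if (E.std(axis=0) == 0).any() or (L.std(axis=0) == 0).any() or \
       (early.values[shared].std(ddof=0).to_numpy() == 0).any():
        raise ValueError("degenerate (constant) gene encountered")
    cross = np.corrcoef(L.T, E.T)[: len(shared), len(shared):]
    within = np.corrcoef(early.values[shared].to_numpy(dtype=float).T)
    off = ~np.eye(len(shared), dtype=bool)
    vec = pd.DataFrame({"cross_time_r": cross[off], "within_early_r": within[off]})
    r = float(np.corrcoef(vec["cross_time_r"], vec["within_early_r"])[0, 1])
    return r, vec
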