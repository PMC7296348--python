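"""Atlas-based regional mapping: selective-gene discovery and mapping scores.

Because most panel genes are correlated across brain regions, region-
selective genes are found by regressing one region's log energies on
another's across genes and flagging genes with large positive standardized
residuals in *every* pairwise comparison. Regions left without selective
genes are pruned (all at once) and the procedure repeats on the remainder.
Each differentiation is then scored against each region by Spearman
correlation over the union of selective genes, and scores are z-normalized
per differentiation across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import RegionalProfileSet
from .normalize import ExpressionMatrix


@dataclass
class SelectiveGeneSets:
    """Per-region selective genes plus the regions pruned along the way."""

    genes_by_region: dict[str, list[str]]
    pruned_regions: list[str]
    residual_threshold: float
    min_residual: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for region, genes in self.genes_by_region.items():
            if not genes:
                raise ValueError(f"retained region {region!r} has no selective genes")
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} selective for both {seen[g]!r} and {region!r}"
                    )
                seen[g] = region

    @property
    def all_genes(self) -> list[str]:
        return [g for genes in self.genes_by_region.values() for g in genes]


def standardized_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Internally studentized residuals of the OLS fit y ~ 1 + x.

    r_i / (s * sqrt(1 - h_i)) with s^2 = SSE/(n-2) and h_i the leverage of
    the simple regression. Raw residual units would be scale-dependent.
    """
    n = len(y)
    if n < 3:
        raise ValueError("need >=3 points for studentized residuals")
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0:
        raise ValueError("degenerate regressor (constant energies)")
    beta = np.sum((x - xbar) * (y - y.mean())) / sxx
    alpha = y.mean() - beta * xbar
    resid = y - (alpha + beta * x)
    s2 = np.sum(resid**2) / (n - 2)
    if s2 == 0:  # perfect fit (e.g. duplicated regions): nothing stands out
        return np.zeros(n)
    h = 1.0 / n + (x - xbar) ** 2 / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        out = resid / np.sqrt(s2 * (1.0 - h))
    return out


def select_region_specific_genes(
    profiles: RegionalProfileSet, threshold: float = 2.0, prune: bool = True,
) -> SelectiveGeneSets:
    """Identify genes selectively expressed in each region, with pruning.

    Energies are log2(energy + 1) transformed. A gene is selective for
    region A iff its standardized residual exceeds ``threshold`` in the
    regression of A on B for every other retained region B. Regions ending
    with zero selective genes are removed together and the analysis repeats
    until every retained region has at least one, or fewer than two regions
    remain (an error). With ``prune=False`` a single round is run and
    regions without selective genes are merely listed as pruned, without
    repeating the analysis.
    """
    E = np.log2(profiles.energy.to_numpy(dtype=float) + 1.0)
    regions = list(profiles.region_ids)
    genes = np.array(profiles.genes)
    if len(regions) < 2:
        raise ValueError("need >=2 regions")
    if len(genes) < 5:
        raise ValueError("need >=5 genes")
    idx = {r: i for i, r in enumerate(regions)}

    retained = list(regions)
    pruned: list[str] = []
    while True:
        if len(retained) < 2:
            raise ValueError(
                f"fewer than 2 regions remain after pruning {pruned}"
            )
        sel: dict[str, list[str]] = {}
        min_resid: dict[str, float] = {}
        for a in retained:
            mask = np.full(len(genes), np.inf)
            for b in retained:
                if b == a:
                    continue
                r = standardized_residuals(E[idx[a]], E[idx[b]])
                mask = np.minimum(mask, r)
            hit = mask > threshold
            sel[a] = list(genes[hit])
            for g, m in zip(genes[hit], mask[hit]):
                min_resid[g] = float(m)
        empty = [r for r in retained if not sel[r]]
        if not empty or not prune:
            return SelectiveGeneSets(
                genes_by_region={r: sel[r] for r in retained if sel[r]},
                pruned_regions=pruned + empty,
                residual_threshold=threshold,
                min_residual=pd.Series(min_resid, dtype=float),
            )
        pruned.extend(empty)
        retained = [r for r in retained if r not in empty]


@dataclass
class MappingScoreTable:
    """Per sample x region: raw Spearman rho and per-sample z score."""

    rho: pd.DataFrame
    z: pd.DataFrame

    def top_region(self) -> pd.Series:
        return self.z.idxmax(axis=1)


def mapping_scores(
    expr: ExpressionMatrix,
    profiles: RegionalProfileSet,
    sel: SelectiveGeneSets,
) -> MappingScoreTable:
    """Spearman mapping score of each differentiation to each region.

    Computed over the union of selective genes present in the expression
    matrix (at least 5 required); z-normalized per sample across regions.
    A constant expression vector leaves that sample's scores missing, with
    a warning.
    """
    G = [g for g in sel.all_genes if g in expr.values.columns]
    if len(G) < 5:
        raise ValueError(
            f"only {len(G)} selective genes present in expression matrix (need >=5)"
        )
    regions = [r for r in profiles.region_ids if r in sel.genes_by_region]
    X = expr.values[G].to_numpy(dtype=float)       # samples x G
    P = profiles.energy.loc[regions, G].to_numpy(dtype=float)  # regions x G

    rho = np.full((X.shape[0], len(regions)), np.nan)
    for i in range(X.shape[0]):
        if np.all(X[i] == X[i][0]):
            warnings.warn(
                f"sample {expr.values.index[i]!r} constant over selective genes; "
                "mapping score undefined", stacklevel=2,
            )
            continue
        for j in range(len(regions)):
            rho[i, j] = spearmanr(X[i], P[j]).statistic
    rho_df = pd.DataFrame(rho, index=expr.values.index, columns=regions)
    z = rho_df.sub(rho_df.mean(axis=1), axis=0).div(rho_df.std(axis=1, ddof=0),
                                                    axis=0)
    return MappingScoreTable(rho=rho_df, z=z)
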