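"""Pre-selection of candidate predictors before Bayesian modelling.

High-dimensional marker and expression panels are first reduced to a
tractable candidate set by simple marginal screens: a two-sample
t-statistic per binary marker, a phenotype/expression Pearson correlation
per gene, an across-folds intersection of top gene lists, a bootstrap
stability profile of per-gene correlations, and supervised PCA (principal
components of the correlation-filtered expression submatrix).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

__all__ = [
    "RankedCandidates",
    "StabilityProfile",
    "ComponentScores",
    "rank_sfps_by_t",
    "rank_genes_by_correlation",
    "common_subset_selection",
    "bootstrap_correlation_stability",
    "supervised_pca",
    "top_k_from_fraction",
]


def top_k_from_fraction(n: int, fraction: float) -> int:
    """Number of candidates kept by a top-``fraction`` rule (ceiling)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return math.ceil(fraction * n)


@dataclass
class RankedCandidates:
    """Candidates ordered by decreasing marginal score (|t| or |r|)."""

    ids: list[str]
    scores: np.ndarray  # aligned with ids, non-increasing
    score_type: str  # "t_statistic" or "correlation"
    phenotype: str = "phenotype"
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.score_type not in ("t_statistic", "correlation"):
            raise ValueError(f"unknown score type {self.score_type!r}")
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.ids[:k]

    def top_fraction(self, fraction: float) -> list[str]:
        return self.top(top_k_from_fraction(len(self.ids), fraction))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "score": self.scores})


@dataclass
class StabilityProfile:
    """Bootstrap mean/sd of per-gene phenotype correlation."""

    table: pd.DataFrame  # index = gene ids, columns = ["mean", "sd"]
    n_boot: int
    subsample_size: int

    def __post_init__(self):
        if (self.table["sd"] < 0).any():
            raise ValueError("negative correlation sd")
        if (self.table["mean"].abs() > 1 + 1e-9).any():
            raise ValueError("mean correlation outside [-1, 1]")


@dataclass
class ComponentScores:
    """Principal-component scores from supervised PCA."""

    scores: pd.DataFrame  # index = line ids, columns = PC1..PCk
    loadings: pd.DataFrame  # index = gene ids, columns = PC1..PCk
    explained_variance_ratio: np.ndarray
    retained_genes: list[str]


def _ordered_ranking(ids: np.ndarray, scores: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Sort by decreasing |score|, ties broken by id order (stable)."""
    order = np.argsort(-np.abs(scores), kind="stable")
    return list(ids[order]), np.abs(scores)[order]


def rank_sfps_by_t(
    G: GenotypeMatrix, y: PhenotypeVector, welch: bool = False
) -> RankedCandidates:
    """Rank markers by the absolute two-sample t-statistic between genotypes.

    Pooled-variance t by default (``welch=True`` switches to the unequal
    variance form). Markers without at least two lines in each genotype
    group are skipped and recorded.
    """
    lines = [l for l in G.line_ids if l in set(y.line_ids)]
    if len(lines) < 4:
        raise ValueError("need at least 4 overlapping lines for a t-statistic")
    X = G.values.loc[lines].to_numpy(dtype=float)
    yy = y.values.loc[lines].to_numpy(dtype=float)
    n1 = X.sum(axis=0)
    n0 = X.shape[0] - n1
    usable = (n1 >= 2) & (n0 >= 2)
    skipped = [m for m, u in zip(G.marker_ids, usable) if not u]
    if skipped:
        logger.warning("skipping %d markers with a genotype group of <2 lines", len(skipped))
    if not usable.any():
        raise ValueError("all markers monomorphic (or nearly so); no t-statistics computable")

    Xu = X[:, usable]
    n1u, n0u = n1[usable], n0[usable]
    s1 = (Xu * yy[:, None]).sum(axis=0)
    mean1 = s1 / n1u
    mean0 = (yy.sum() - s1) / n0u
    ss1 = (Xu * yy[:, None] ** 2).sum(axis=0) - n1u * mean1**2
    ss0 = (yy**2).sum() - (Xu * yy[:, None] ** 2).sum(axis=0) - n0u * mean0**2
    if welch:
        v1 = ss1 / (n1u - 1)
        v0 = ss0 / (n0u - 1)
        se = np.sqrt(v1 / n1u + v0 / n0u)
    else:
        sp2 = (ss1 + ss0) / (n1u + n0u - 2)
        se = np.sqrt(sp2 * (1.0 / n1u + 1.0 / n0u))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean1 - mean0) / se, 0.0)
    ids, scores = _ordered_ranking(np.asarray(G.marker_ids)[usable], t)
    return RankedCandidates(ids, scores, "t_statistic", y.name, skipped=skipped)


def rank_genes_by_correlation(
    E: ExpressionMatrix, y: PhenotypeVector, top_fraction: float = 1.0
) -> RankedCandidates:
    """Rank genes by |Pearson correlation| with the phenotype.

    Keeps the top ``ceil(top_fraction * n_genes)`` genes. Zero-variance
    genes get score 0 and fall to the bottom of the ranking.
    """
    lines = [l for l in E.line_ids if l in set(y.line_ids)]
    if len(lines) < 3:
        raise ValueError("need at least 3 overlapping lines for correlations")
    X = E.values.loc[lines].to_numpy(dtype=float)
    yy = y.values.loc[lines].to_numpy(dtype=float)
    yc = yy - yy.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / denom, 0.0)
    ids, scores = _ordered_ranking(np.asarray(E.gene_ids), r)
    k = top_k_from_fraction(len(ids), top_fraction)
    return RankedCandidates(ids[:k], scores[:k], "correlation", y.name)


def common_subset_selection(
    fold_rankings: list[RankedCandidates], top_fraction: float
) -> list[str]:
    """Intersect top-``fraction`` sets across rankings; order by the first.

    The first ranking supplied acts as the ordering authority (by
    convention the all-data ranking, so that supplying it plus the k fold
    rankings reproduces the k+1-list construction). May return an empty
    list when the intersection is empty.
    """
    if len(fold_rankings) < 2:
        raise ValueError("need at least 2 rankings to intersect")
    universe = set(fold_rankings[0].ids)
    for rk in fold_rankings[1:]:
        if set(rk.ids) != universe:
            raise ValueError("rankings cover different candidate universes")
    common: set[str] | None = None
    for rk in fold_rankings:
        top = set(rk.top_fraction(top_fraction))
        common = top if common is None else common & top
    reference = fold_rankings[0]
    return [cid for cid in reference.ids if cid in common]


def bootstrap_correlation_stability(
    E: ExpressionMatrix, y: PhenotypeVector, B: int = 100, m: int | None = None, seed: int = 0
) -> StabilityProfile:
    """Bootstrap the per-gene phenotype correlation to profile its stability.

    Draws ``B`` resamples of ``m`` lines with replacement and records the
    mean and standard deviation of each gene's correlation across
    resamples. A resample with zero phenotype variance contributes 0 for
    every gene in that replicate.
    """
    lines = [l for l in E.line_ids if l in set(y.line_ids)]
    n = len(lines)
    if m is None:
        m = math.ceil(0.77 * n)
    if m > n:
        raise ValueError("subsample size m exceeds number of lines")
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    X = E.values.loc[lines].to_numpy(dtype=float)
    yy = y.values.loc[lines].to_numpy(dtype=float)
    cors = np.empty((B, X.shape[1]))
    for b in range(B):
        idx = rng.integers(0, n, size=m)
        xb, yb = X[idx], yy[idx]
        yc = yb - yb.mean()
        sy = (yc**2).sum()
        if sy == 0:
            logger.warning("bootstrap replicate %d has zero phenotype variance", b)
            cors[b] = 0.0
            continue
        xc = xb - xb.mean(axis=0)
        denom = np.sqrt((xc**2).sum(axis=0) * sy)
        with np.errstate(divide="ignore", invalid="ignore"):
            cors[b] = np.where(denom > 0, xc.T @ yc / denom, 0.0)
    table = pd.DataFrame(
        {"mean": cors.mean(axis=0), "sd": cors.std(axis=0, ddof=1)},
        index=pd.Index(E.gene_ids, name="gene"),
    )
    return StabilityProfile(table, n_boot=B, subsample_size=m)


def supervised_pca(
    E: ExpressionMatrix,
    y: PhenotypeVector,
    top_fraction: float = 0.1,
    n_components: int = 5,
    scale: bool = False,
) -> ComponentScores:
    """PCA of the expression submatrix pre-filtered by phenotype correlation.

    Genes are first ranked by |r| with the phenotype and the top fraction
    retained; components are computed on the centred (optionally scaled)
    submatrix. Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is positive.
    """
    ranking = rank_genes_by_correlation(E, y, top_fraction=top_fraction)
    genes = ranking.ids
    lines = [l for l in E.line_ids if l in set(y.line_ids)]
    X = E.values.loc[lines, genes].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank bound {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return ComponentScores(
        scores=pd.DataFrame(scores, index=pd.Index(lines, name="line"), columns=cols),
        loadings=pd.DataFrame(loadings, index=pd.Index(genes, name="gene"), columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        retained_genes=genes,
    )
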