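"""Posterior relevance of predictors and gene-set / chromosome summaries.

The per-predictor relevance is the posterior mean of indicator times
coefficient magnitude, E[I |beta|]. For binary SFP columns this is
additionally multiplied by the empirical genotype variance p(1-p) of the
column ("weighted genetic variation"); expression columns are reported
as weighted coefficients. Gene-set summaries average the weighted
genetic variation over a set's SFP members and sum the weighted
coefficients over its expression members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import DesignMatrix, PosteriorSamples

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "weighted_relevance",
    "compare_marginal_joint",
    "set_enrichment",
    "top_predictor_report",
    "read_gene_sets",
]


@dataclass
class GeneSetCollection:
    """Named predictor sets (GO-process-like or per-chromosome)."""

    sets: dict[str, tuple[str, list[str]]]  # id -> (description, member ids)
    namespace: str = "go_process"  # or "chromosome"

    def restrict_to(self, known_ids: list[str]) -> "GeneSetCollection":
        """Drop member ids not present in ``known_ids`` (with a warning count)."""
        known = set(known_ids)
        dropped = 0
        out: dict[str, tuple[str, list[str]]] = {}
        for sid, (desc, members) in self.sets.items():
            kept = [m for m in members if m in known]
            dropped += len(members) - len(kept)
            out[sid] = (desc, kept)
        if dropped:
            logger.warning("dropped %d unknown member ids from gene sets", dropped)
        return GeneSetCollection(out, self.namespace)


def weighted_relevance(
    samples: PosteriorSamples,
    X: DesignMatrix,
    marginal: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-predictor joint relevance: posterior mean of I * |beta|.

    SFP columns are scaled by the empirical genotype variance of the
    column; expression and component columns are reported unscaled as
    weighted coefficients. An optional ``marginal`` series (|t| or |r|
    scores) is merged in for marginal-vs-joint comparisons.
    """
    if list(X.column_ids) != list(samples.column_ids):
        raise ValueError("design columns do not match the fitted columns")
    rel = (samples.indicator * np.abs(samples.beta)).mean(axis=0)
    is_sfp = samples.column_types == "sfp"
    if is_sfp.any():
        geno = X.values.loc[:, np.asarray(X.column_ids)[is_sfp]].to_numpy(dtype=float)
        phat = geno.mean(axis=0)
        rel = rel.copy()
        rel[is_sfp] *= phat * (1.0 - phat)
    table = pd.DataFrame(
        {
            "marker_type": samples.column_types,
            "joint_relevance": rel,
            "inclusion_probability": samples.indicator.mean(axis=0),
        },
        index=pd.Index(samples.column_ids, name="predictor"),
    )
    if marginal is not None:
        table["marginal_score"] = marginal.reindex(table.index).abs()
    return table


def compare_marginal_joint(relevance: pd.DataFrame) -> pd.DataFrame:
    """Least-squares fit of joint relevance on marginal score per type.

    Returns slope, intercept, Pearson correlation and the slope p-value
    for each marker type with at least 3 predictors.
    """
    if "marginal_score" not in relevance.columns:
        raise ValueError("relevance table lacks marginal scores")
    rows = {}
    for mtype, sub in relevance.groupby("marker_type"):
        sub = sub.dropna(subset=["marginal_score"])
        if len(sub) < 3:
            continue
        x = sub["marginal_score"].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"zero-variance marginal scores for type {mtype!r}")
        fit = stats.linregress(x, sub["joint_relevance"].to_numpy(dtype=float))
        rows[mtype] = dict(
            slope=fit.slope, intercept=fit.intercept,
            correlation=fit.rvalue, slope_pvalue=fit.pvalue, n=len(sub),
        )
    if not rows:
        raise ValueError("no marker type has >= 3 predictors with marginal scores")
    return pd.DataFrame.from_dict(rows, orient="index")


def set_enrichment(
    relevance: pd.DataFrame,
    sets: GeneSetCollection,
    expression_aggregate: str = "sum",
    context: str = "",
) -> pd.DataFrame:
    """Summarize relevance over predictor sets.

    Per set: the mean weighted genetic variation over SFP members and the
    joint (summed by default, or mean) weighted coefficient over
    expression members. Sets with no known members are dropped.
    """
    if expression_aggregate not in ("sum", "mean"):
        raise ValueError("expression_aggregate must be 'sum' or 'mean'")
    sets = sets.restrict_to(list(relevance.index))
    rows = {}
    for sid, (desc, members) in sets.sets.items():
        if not members:
            continue
        sub = relevance.loc[members]
        sfp = sub[sub["marker_type"] == "sfp"]["joint_relevance"]
        expr = sub[sub["marker_type"] != "sfp"]["joint_relevance"]
        agg = expr.sum() if expression_aggregate == "sum" else expr.mean()
        rows[sid] = dict(
            description=desc,
            n_members=len(members),
            mean_weighted_genetic_variation=float(sfp.mean()) if len(sfp) else np.nan,
            joint_weighted_coefficient=float(agg) if len(expr) else np.nan,
            model_context=context,
        )
    if not rows:
        raise ValueError("no gene set has a known member")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "set_id"
    return out


def top_predictor_report(
    tables: dict[str, pd.DataFrame], top_n: int = 10, by: str = "joint_relevance"
) -> pd.DataFrame:
    """Union of per-measure top-n predictor lists with per-measure ranks.

    ``tables`` maps a measure/context label to a relevance table over the
    same predictor universe. A predictor appears in the report if it is in
    the top ``top_n`` of any measure; ranks under every measure are shown.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(tables) < 1:
        raise ValueError("need at least one relevance table")
    labels = list(tables)
    universe = set(tables[labels[0]].index)
    for lab in labels[1:]:
        if set(tables[lab].index) != universe:
            raise ValueError("relevance tables cover different predictor universes")
    ranks = {}
    selected: set[str] = set()
    for lab in labels:
        scores = tables[lab][by]
        rank = scores.rank(ascending=False, method="first")
        ranks[f"rank_{lab}"] = rank
        selected.update(rank.nsmallest(top_n).index)
    report = pd.DataFrame(ranks).loc[sorted(selected)]
    report.index.name = "predictor"
    order = report.min(axis=1).sort_values(kind="stable").index
    return report.loc[order]


def read_gene_sets(path, namespace: str = "go_process") -> GeneSetCollection:
    """Read a GMT-like TSV: set id, description, then tab-separated members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed gene-set line: {line[:60]!r}")
            sets[parts[0]] = (parts[1], parts[2:])
    return GeneSetCollection(sets, namespace)
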