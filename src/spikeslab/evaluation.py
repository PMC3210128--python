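"""Cross-validated prediction assessment, model-size sweeps, permutation test.

The assessment convention: the data are split into k near-equal folds
(checked for phenotype homogeneity), the whole pipeline — pre-selection
included — is re-run on each learning set, held-out lines are predicted,
and a single pooled Pearson/Spearman correlation is computed over the
concatenated held-out predictions. In-data (goodness-of-fit) correlations
are averaged over the k training fits. Significance of the pooled
out-data correlation is assessed by re-running the full pipeline on
phenotype values permuted across lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeVector
from .model import PriorConfig, SpikeSlabModel, build_design
from .preselect import (
    common_subset_selection,
    rank_genes_by_correlation,
    rank_sfps_by_t,
    supervised_pca,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "Strategy",
    "PredictionResult",
    "SweepResult",
    "make_kfold",
    "make_split",
    "correlation_metrics",
    "run_cross_validation",
    "model_size_sweep",
    "permutation_test",
]


@dataclass
class FoldAssignment:
    """Line -> fold partition (folds numbered 1..k) with diagnostics.

    ``split_sample`` marks a two-part learning/test split (fold 2 = test),
    which is allowed to be unequal; ordinary k-fold partitions must have
    fold sizes differing by at most one.
    """

    assignment: pd.Series  # index = line ids, values in 1..k
    k: int
    seed: int
    diagnostics: pd.DataFrame | None = None  # per-fold phenotype deciles
    homogeneous: bool = True
    split_sample: bool = False

    def __post_init__(self):
        sizes = self.assignment.value_counts()
        if len(sizes) != self.k:
            raise ValueError("every fold index in 1..k must be used")
        if not self.split_sample and sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes may differ by at most one")

    def fold_lines(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment == fold])

    def train_lines(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment != fold])


def make_kfold(
    y: PhenotypeVector,
    k: int = 5,
    seed: int = 0,
    max_tries: int = 100,
    decile_tolerance: float = 0.25,
) -> FoldAssignment:
    """Random near-equal k-fold partition with a phenotype homogeneity check.

    Partitions are re-drawn (up to ``max_tries``) until every fold's
    phenotype deciles deviate from the full-sample deciles by less than
    ``decile_tolerance`` times the phenotype interquartile range. If no
    draw passes, the best partition seen is returned with a warning.
    """
    n = len(y.line_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k < n and n < 2 * k:
        raise ValueError("need at least 2k lines for k-fold partitioning")
    if k > n:
        raise ValueError("k exceeds the number of lines")
    rng = np.random.default_rng(seed)
    yv = y.values.to_numpy(dtype=float)
    probs = np.linspace(0.1, 0.9, 9)
    full_dec = np.quantile(yv, probs)
    iqr = float(np.subtract(*np.quantile(yv, [0.75, 0.25])))
    tol = decile_tolerance * iqr if iqr > 0 else np.inf

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max_tries):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k + 1
        if k == n:  # leave-one-out: deciles of singletons are meaningless
            best = (0.0, folds, np.tile(yv[perm][:, None], 1))
            break
        devs = np.empty(k)
        decs = np.empty((k, len(probs)))
        for f in range(1, k + 1):
            decs[f - 1] = np.quantile(yv[folds == f], probs)
            devs[f - 1] = np.abs(decs[f - 1] - full_dec).max()
        worst = float(devs.max())
        if best is None or worst < best[0]:
            best = (worst, folds, decs)
        if worst < tol:
            break
    worst, folds, decs = best
    homogeneous = bool(worst < tol) or k == n
    if not homogeneous:
        logger.warning(
            "fold homogeneity tolerance %.4g not reached in %d tries (best %.4g); "
            "returning best partition", tol, max_tries, worst,
        )
    diagnostics = None
    if k < n:
        diagnostics = pd.DataFrame(
            decs, index=[f"fold{f}" for f in range(1, k + 1)],
            columns=[f"q{int(p * 100)}" for p in probs],
        )
    return FoldAssignment(
        pd.Series(folds, index=y.values.index, name="fold"),
        k=k, seed=seed, diagnostics=diagnostics, homogeneous=homogeneous,
    )


def make_split(y: PhenotypeVector, test_lines: list[str]) -> FoldAssignment:
    """Explicit learning/test split as a two-fold assignment (fold 2 = test).

    Mirrors the hold-out assessment mode: training happens on fold 1,
    prediction on fold 2, and ``run_cross_validation`` evaluates only the
    listed test lines. The split may be unequal.
    """
    test = set(test_lines)
    unknown = test - set(y.line_ids)
    if unknown:
        raise ValueError(f"test lines absent from phenotype: {sorted(unknown)[:5]}")
    if not test or len(test) == len(y.line_ids):
        raise ValueError("test set must be a non-empty proper subset of the lines")
    folds = pd.Series(
        [2 if l in test else 1 for l in y.line_ids],
        index=y.values.index, name="fold",
    )
    return FoldAssignment(folds, k=2, seed=0, split_sample=True)


def correlation_metrics(observed, predicted) -> tuple[float, float]:
    """Pearson and Spearman correlation between observed and predicted."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("need at least 3 observed/predicted pairs")
    # relative tolerance: a numerically-constant vector differs by ~1 ulp
    if np.std(obs) <= 1e-12 * (np.abs(obs).max() + 1.0):
        raise ValueError("observed values have zero variance")
    if np.std(pred) <= 1e-12 * (np.abs(pred).max() + 1.0):
        raise ValueError("predicted values have zero variance")
    pearson = float(stats.pearsonr(obs, pred).statistic)
    spearman = float(stats.spearmanr(obs, pred).statistic)
    return pearson, spearman


@dataclass
class Strategy:
    """One cell of the data-type x selection x model-type grid.

    ``n_sfp``/``n_gene`` are model-size budgets (0 disables that data
    type). ``gene_method`` chooses the expression-side reduction:
    marginal correlation ranking, across-folds common-subset selection, or
    supervised PCA (whose ``n_components`` scores replace gene columns).
    """

    n_sfp: int = 0
    n_gene: int = 0
    sfp_method: str = "t_statistic"
    gene_method: str = "correlation"
    gene_top_fraction: float = 0.10
    common_subset_fraction: float = 0.05
    n_components: int = 5
    priors: PriorConfig = field(default_factory=PriorConfig.non_indicator)
    standardize_expression: bool = True
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 2
    chains: int = 2

    def mcmc(self, seed: int) -> dict:
        return dict(iterations=self.iterations, burn_in=self.burn_in,
                    thin=self.thin, chains=self.chains, seed=seed)


@dataclass
class PredictionResult:
    """Observed vs predicted values with pooled and per-fold metrics."""

    phenotype: str
    frame: pd.DataFrame  # columns: observed, predicted, fold
    out_pearson: float
    out_spearman: float
    in_pearson: float
    in_spearman: float
    deviance_per_fold: list[float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in (self.out_pearson, self.out_spearman, self.in_pearson, self.in_spearman):
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError("correlation outside [-1, 1]")


def _restrict(G, E, lines):
    sub_G = GenotypeMatrix(G.values.loc[lines], map=G.map) if G is not None else None
    sub_E = ExpressionMatrix(E.values.loc[lines], gene_info=None) if E is not None else None
    return sub_G, sub_E


def _common_lines(G, E, y) -> list[str]:
    lines = list(y.line_ids)
    for src in (G, E):
        if src is not None:
            present = set(src.line_ids)
            lines = [l for l in lines if l in present]
    return lines


def run_cross_validation(
    G: GenotypeMatrix | None,
    E: ExpressionMatrix | None,
    y: PhenotypeVector,
    folds: FoldAssignment,
    strategy: Strategy,
    seed: int = 0,
) -> PredictionResult:
    """k-fold CV with pre-selection re-run on each learning set.

    Pre-selection sees the learning set only, except the common-subset
    gene selection which by construction intersects top lists from every
    learning set plus the full data; that path is flagged in the result
    metadata (``used_full_data_ranking``) because it touches each test
    fold during selection.
    """
    if strategy.n_sfp > 0 and G is None:
        raise ValueError("strategy requests SFP columns but no genotype data given")
    if strategy.n_gene > 0 and E is None:
        raise ValueError("strategy requests gene columns but no expression data given")
    if strategy.n_sfp == 0 and strategy.n_gene == 0:
        logger.info("intercept-only strategy: no predictor columns requested")

    lines = _common_lines(G, E, y)
    fold_ids = folds.assignment.loc[lines]
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=folds.k)
    metadata: dict = {"strategy": strategy, "k": folds.k}

    common_genes: list[str] | None = None
    if strategy.n_gene > 0 and strategy.gene_method == "common_subset":
        rankings = [rank_genes_by_correlation(E, y)]  # all-data list first
        learn_folds = [2] if folds.split_sample else list(range(1, folds.k + 1))
        for f in learn_folds:
            tr = [l for l in lines if fold_ids[l] != f]
            sub_G, sub_E = _restrict(G, E, tr)
            y_tr = PhenotypeVector(y.values.loc[tr], name=y.name)
            rankings.append(rank_genes_by_correlation(sub_E, y_tr))
        common_genes = common_subset_selection(rankings, strategy.common_subset_fraction)
        metadata["used_full_data_ranking"] = True
        metadata["common_subset_size"] = len(common_genes)
        logger.warning(
            "common-subset gene selection uses the all-data ranking inside CV "
            "(uses each test fold once during selection)"
        )

    rows = []
    in_p, in_s, devs = [], [], []
    # a split-sample assignment trains on fold 1 and predicts fold 2 only
    eval_folds = [2] if folds.split_sample else list(range(1, folds.k + 1))
    for f in eval_folds:
        test = [l for l in lines if fold_ids[l] == f]
        train = [l for l in lines if fold_ids[l] != f]
        y_tr = PhenotypeVector(y.values.loc[train], name=y.name)
        if float(y_tr.values.std(ddof=0)) == 0:
            raise ValueError(f"training phenotype degenerate in fold {f}")
        sub_G, sub_E = _restrict(G, E, train)

        selection: dict[str, list[str]] = {}
        components_all: pd.DataFrame | None = None
        if strategy.n_sfp > 0:
            if strategy.sfp_method != "t_statistic":
                raise ValueError(f"unknown SFP selection method {strategy.sfp_method!r}")
            selection["sfp"] = rank_sfps_by_t(sub_G, y_tr).top(strategy.n_sfp)
        if strategy.n_gene > 0:
            if strategy.gene_method == "correlation":
                ranking = rank_genes_by_correlation(sub_E, y_tr, strategy.gene_top_fraction)
                selection["expression"] = ranking.top(strategy.n_gene)
            elif strategy.gene_method == "common_subset":
                selection["expression"] = common_genes[: strategy.n_gene]
            elif strategy.gene_method == "supervised_pca":
                comp = supervised_pca(
                    sub_E, y_tr, top_fraction=strategy.gene_top_fraction,
                    n_components=strategy.n_components,
                )
                centred = E.values.loc[lines, comp.retained_genes] - \
                    sub_E.values[comp.retained_genes].mean(axis=0)
                components_all = centred.to_numpy() @ comp.loadings.to_numpy()
                components_all = pd.DataFrame(
                    components_all, index=pd.Index(lines), columns=comp.loadings.columns)
            else:
                raise ValueError(f"unknown gene selection method {strategy.gene_method!r}")

        use_E = sub_E if "expression" in selection else None
        use_G = sub_G if "sfp" in selection else None
        comps_tr = components_all.loc[train] if components_all is not None else None
        design = build_design(
            use_G, use_E, selection,
            standardize_expression=strategy.standardize_expression,
            components=comps_tr,
        )
        res = SpikeSlabModel(y_tr, design, strategy.priors).fit(**strategy.mcmc(int(fit_seeds[f - 1])))

        fitted = res.predict()
        try:
            p_in, s_in = correlation_metrics(y_tr.values.loc[design.line_ids], fitted)
        except ValueError:
            # constant fitted values (e.g. everything excluded): no fit at all
            logger.warning("fold %d: constant fitted values; in-data correlation set to 0", f)
            p_in = s_in = 0.0
        in_p.append(p_in)
        in_s.append(s_in)
        devs.append(res.deviance())

        comps_te = components_all.loc[test] if components_all is not None else None
        test_design = design.apply_to(
            G=G if use_G is not None else None,
            E=E if use_E is not None else None,
            components=comps_te, lines=test,
        )
        pred = res.predict(test_design)
        for l in test:
            rows.append((l, float(y.values[l]), float(pred[l]), f))

    frame = pd.DataFrame(rows, columns=["line", "observed", "predicted", "fold"]).set_index("line")
    out_p, out_s = correlation_metrics(frame["observed"], frame["predicted"])
    return PredictionResult(
        phenotype=y.name, frame=frame,
        out_pearson=out_p, out_spearman=out_s,
        in_pearson=float(np.mean(in_p)), in_spearman=float(np.mean(in_s)),
        deviance_per_fold=devs, metadata=metadata,
    )


@dataclass
class SweepResult:
    """Metrics over a grid of (n_sfp, n_gene) model sizes."""

    table: pd.DataFrame  # index: (n_sfp, n_gene); out/in corr + mean deviance

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate grid entries")


def model_size_sweep(
    G: GenotypeMatrix | None,
    E: ExpressionMatrix | None,
    y: PhenotypeVector,
    folds: FoldAssignment,
    grid: list[tuple[int, int]],
    strategy: Strategy,
    seed: int = 0,
) -> SweepResult:
    """Re-run CV at each (n_sfp, n_gene) grid point (cumulative top sets)."""
    rows = {}
    for n_sfp, n_gene in grid:
        st = replace(strategy, n_sfp=n_sfp, n_gene=n_gene)
        if n_sfp == 0 and n_gene == 0:
            rows[(n_sfp, n_gene)] = dict(
                out_pearson=0.0, out_spearman=0.0, in_pearson=0.0,
                in_spearman=0.0, mean_deviance=np.nan,
            )
            continue
        res = run_cross_validation(G, E, y, folds, st, seed=seed)
        rows[(n_sfp, n_gene)] = dict(
            out_pearson=res.out_pearson, out_spearman=res.out_spearman,
            in_pearson=res.in_pearson, in_spearman=res.in_spearman,
            mean_deviance=float(np.mean(res.deviance_per_fold)),
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["n_sfp", "n_gene"])
    return SweepResult(table)


def permutation_test(
    G: GenotypeMatrix | None,
    E: ExpressionMatrix | None,
    y: PhenotypeVector,
    folds: FoldAssignment,
    strategy: Strategy,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for the pooled out-data Pearson correlation.

    The null distribution re-runs the full pipeline (pre-selection
    included) on phenotype values permuted across lines. Returns
    ``(p_value, observed_statistic, null_statistics)`` with the add-one
    estimator p = (1 + #{null >= obs}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    rng = np.random.default_rng(seed)
    observed = run_cross_validation(G, E, y, folds, strategy, seed=seed).out_pearson
    null = np.empty(n_perm)
    values = y.values.to_numpy().copy()
    for b in range(n_perm):
        perm = rng.permutation(len(values))
        y_perm = PhenotypeVector(
            pd.Series(values[perm], index=y.values.index), name=y.name)
        null[b] = run_cross_validation(
            G, E, y_perm, folds, strategy, seed=int(rng.integers(0, 2**31 - 1))
        ).out_pearson
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return p, observed, null
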