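"""Spike-and-slab multilocus regression fitted by Gibbs sampling.

The model for line i is

    y_i = alpha + sum_l I_l * beta_l * x_il + e_i,    e_i ~ N(0, sigma^2)

where the latent 0/1 indicators ``I_l`` govern which predictors enter the
model (indicator-times-coefficient composition, after Kuo & Mallick). Each
predictor belongs to a marker type ("sfp", "expression" or "component")
with its own inclusion regime:

* ``fixed_prob`` — I_l ~ Bernoulli(pi) with a fixed shrinkage probability;
* ``always_in`` / ``always_out`` — degenerate indicators, reproducing
  ordinary ("non-indicator") Bayesian regression as exact special cases;
* ``uniform_prob`` — pi ~ Uniform(0, 1) shared within the type, updated
  from its conjugate Beta full conditional.

Priors: alpha ~ N(0, 1); beta_l ~ N(0, tau^2_type) with tau^2_type either
fixed or inverse-Gamma distributed; sigma^2 ~ inverse-Gamma(a0, b0).
Coefficients of excluded predictors are refreshed from their prior, which
keeps the indicator chain mixing.

Usage follows the statsmodels pattern::

    design = build_design(G, E, selection={"sfp": sfp_ids, "expression": gene_ids})
    model = SpikeSlabModel(y, design, priors=PriorConfig.default())
    res = model.fit(iterations=6000, burn_in=1000, seed=1)
    res.pip            # posterior inclusion probabilities
    res.predict(new_design)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

__all__ = [
    "MARKER_TYPES",
    "InclusionPrior",
    "PriorConfig",
    "DesignMatrix",
    "build_design",
    "SpikeSlabModel",
    "SpikeSlabResults",
    "PosteriorSamples",
    "fit_spike_slab",
    "posterior_predict",
    "compute_deviance",
]

MARKER_TYPES = ("sfp", "expression", "component")
_REGIMES = {"fixed_prob": 0, "always_in": 1, "always_out": 2, "uniform_prob": 3}


@dataclass(frozen=True)
class InclusionPrior:
    """Inclusion regime and slab-variance prior for one marker type.

    ``tau2`` fixes the coefficient (slab) variance; when ``None`` the
    variance gets an inverse-Gamma(``tau2_shape``, ``tau2_scale``)
    hyperprior updated in the Gibbs sweep.
    """

    regime: str = "fixed_prob"
    pi: float = 0.5
    tau2: float | None = None
    tau2_shape: float = 2.0
    tau2_scale: float = 1.0

    def __post_init__(self):
        if self.regime not in _REGIMES:
            raise ValueError(f"unknown inclusion regime {self.regime!r}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.tau2 is not None and self.tau2 <= 0:
            raise ValueError("fixed tau2 must be positive")
        if self.tau2_shape <= 0 or self.tau2_scale <= 0:
            raise ValueError("tau2 hyperparameters must be positive")


@dataclass(frozen=True)
class PriorConfig:
    """Per-marker-type inclusion priors plus the residual-variance prior."""

    by_type: dict[str, InclusionPrior] = field(default_factory=dict)
    sigma2_shape: float = 0.01
    sigma2_scale: float = 0.01

    def __post_init__(self):
        if self.sigma2_shape <= 0 or self.sigma2_scale <= 0:
            raise ValueError("sigma2 prior hyperparameters must be positive")
        for t in self.by_type:
            if t not in MARKER_TYPES:
                raise ValueError(f"unknown marker type {t!r}")

    @classmethod
    def default(cls, sfp_pi: float = 0.1, expression_pi: float = 0.01) -> "PriorConfig":
        """Shrinkage defaults: pi = 0.1 for markers, 0.01 for expression."""
        return cls(
            by_type={
                "sfp": InclusionPrior("fixed_prob", pi=sfp_pi),
                "expression": InclusionPrior("fixed_prob", pi=expression_pi),
                "component": InclusionPrior("always_in"),
            }
        )

    @classmethod
    def non_indicator(cls) -> "PriorConfig":
        """Degenerate indicators: every selected predictor always in."""
        return cls(by_type={t: InclusionPrior("always_in") for t in MARKER_TYPES})

    @classmethod
    def vague(cls) -> "PriorConfig":
        """Uniform(0,1) inclusion probability per marker type."""
        return cls(
            by_type={
                "sfp": InclusionPrior("uniform_prob"),
                "expression": InclusionPrior("uniform_prob"),
                "component": InclusionPrior("always_in"),
            }
        )

    def get(self, marker_type: str) -> InclusionPrior:
        return self.by_type.get(marker_type, InclusionPrior())


@dataclass
class DesignMatrix:
    """Predictor matrix with marker-type labels and standardization record.

    SFP columns stay on their 0/1 coding; expression columns are optionally
    standardized using means/sds recorded here so held-out lines can be
    transformed identically.
    """

    values: pd.DataFrame  # index = line ids, columns = predictor ids
    col_types: np.ndarray  # aligned with columns, entries in MARKER_TYPES
    center: pd.Series  # per-column offset already applied
    scale: pd.Series  # per-column divisor already applied

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("design matrix contains non-finite values")
        self.col_types = np.asarray(self.col_types, dtype=object)
        if len(self.col_types) != self.values.shape[1]:
            raise ValueError("one type label required per column")
        unknown = set(self.col_types) - set(MARKER_TYPES)
        if unknown:
            raise ValueError(f"unknown marker types {sorted(unknown)}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return np.ascontiguousarray(self.values.to_numpy(dtype=float))

    def apply_to(
        self, G: GenotypeMatrix | None = None, E: ExpressionMatrix | None = None,
        components: pd.DataFrame | None = None, lines: list[str] | None = None,
    ) -> "DesignMatrix":
        """Build a matching design for new lines, reusing the stored scaling."""
        sources: dict[str, pd.DataFrame] = {}
        if G is not None:
            sources["sfp"] = G.values
        if E is not None:
            sources["expression"] = E.values
        if components is not None:
            sources["component"] = components
        cols = {}
        for cid, ctype in zip(self.column_ids, self.col_types):
            if ctype not in sources:
                raise ValueError(f"no data source supplied for {ctype!r} column {cid!r}")
            if cid not in sources[ctype].columns:
                raise ValueError(f"column {cid!r} absent from supplied {ctype} data")
            cols[cid] = sources[ctype][cid]
        frame = pd.DataFrame(cols)
        if lines is not None:
            frame = frame.loc[lines]
        frame = (frame - self.center) / self.scale
        return DesignMatrix(frame[self.column_ids], self.col_types.copy(),
                            self.center.copy(), self.scale.copy())


def build_design(
    G: GenotypeMatrix | None = None,
    E: ExpressionMatrix | None = None,
    selection: dict[str, list[str]] | None = None,
    standardize_expression: bool = True,
    components: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Assemble the predictor matrix from selected markers and/or genes.

    ``selection`` maps marker type to an ordered id list, e.g.
    ``{"sfp": [...], "expression": [...]}``. Lines are intersected across
    all supplied sources (in the order of the first source). SFP columns
    keep their 0/1 coding; expression columns are standardized (training
    mean/sd recorded for reuse on held-out lines) when flagged.
    """
    if G is None and E is None and components is None:
        raise ValueError("at least one data source required")
    selection = dict(selection or {})
    sources: list[tuple[str, pd.DataFrame]] = []
    if G is not None:
        sources.append(("sfp", G.values))
    if E is not None:
        sources.append(("expression", E.values))
    if components is not None:
        sources.append(("component", components))
        selection.setdefault("component", list(components.columns))

    lines = list(sources[0][1].index)
    for _, frame in sources[1:]:
        present = set(frame.index)
        lines = [l for l in lines if l in present]
    if not lines:
        raise ValueError("supplied data sources share no lines")

    blocks, types = [], []
    for ctype, frame in sources:
        ids = selection.get(ctype, [])
        missing = [i for i in ids if i not in frame.columns]
        if missing:
            raise ValueError(f"selected {ctype} ids not found: {missing[:5]}")
        if not ids:
            continue
        block = frame.loc[lines, ids].astype(float)
        blocks.append(block)
        types.extend([ctype] * len(ids))
    if not blocks:
        raise ValueError("empty selection: no predictor columns")
    values = pd.concat(blocks, axis=1)
    if values.columns.has_duplicates:
        raise ValueError("duplicate column ids across data sources")

    center = pd.Series(0.0, index=values.columns)
    scale = pd.Series(1.0, index=values.columns)
    types_arr = np.asarray(types, dtype=object)
    if standardize_expression:
        expr_cols = values.columns[types_arr == "expression"]
        if len(expr_cols):
            mu = values[expr_cols].mean(axis=0)
            sd = values[expr_cols].std(axis=0, ddof=0).replace(0.0, 1.0)
            values[expr_cols] = (values[expr_cols] - mu) / sd
            center[expr_cols] = mu
            scale[expr_cols] = sd
    return DesignMatrix(values, types_arr, center, scale)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of (alpha, beta, I, pi, tau^2, sigma^2)."""

    column_ids: list[str]
    column_types: np.ndarray
    alpha: np.ndarray  # (draws,)
    beta: np.ndarray  # (draws, p)
    indicator: np.ndarray  # (draws, p) in {0, 1}
    sigma2: np.ndarray  # (draws,)
    pi: np.ndarray  # (draws, n_types); fixed regimes carry their constant
    tau2: np.ndarray  # (draws, n_types)
    type_labels: list[str]  # labels for pi/tau2 columns
    chain: np.ndarray  # (draws,) chain index
    iterations: int = 0
    burn_in: int = 0
    thin: int = 1
    seed: int | None = None

    def __post_init__(self):
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("indicator draws must be 0/1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma^2 draws must be positive")

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    @property
    def inclusion_probability(self) -> pd.Series:
        return pd.Series(self.indicator.mean(axis=0), index=self.column_ids, name="pip")

    @property
    def effective_model_size(self) -> float:
        """Posterior mean number of included predictors."""
        return float(self.indicator.sum(axis=1).mean())

    def active_coefficients(self) -> np.ndarray:
        """Per-draw I * beta (the quantity that enters predictions)."""
        return self.indicator * self.beta

    def to_frame(self) -> pd.DataFrame:
        """Flatten the draws to a plain columnar table (one row per draw)."""
        cols = {"chain": self.chain, "alpha": self.alpha, "sigma2": self.sigma2}
        for t, lab in enumerate(self.type_labels):
            cols[f"pi_{lab}"] = self.pi[:, t]
            cols[f"tau2_{lab}"] = self.tau2[:, t]
        for j, cid in enumerate(self.column_ids):
            cols[f"beta_{cid}"] = self.beta[:, j]
            cols[f"I_{cid}"] = self.indicator[:, j]
        return pd.DataFrame(cols)


def _kernel_inputs(design: DesignMatrix, priors: PriorConfig):
    labels = [t for t in MARKER_TYPES if t in set(design.col_types)]
    idx = {t: i for i, t in enumerate(labels)}
    type_idx = np.array([idx[t] for t in design.col_types], dtype=np.int64)
    regime = np.array([_REGIMES[priors.get(t).regime] for t in labels], dtype=np.int64)
    pi0 = np.array([priors.get(t).pi for t in labels])
    tau2_fixed = np.array([priors.get(t).tau2 or -1.0 for t in labels])
    t2_shape = np.array([priors.get(t).tau2_shape for t in labels])
    t2_scale = np.array([priors.get(t).tau2_scale for t in labels])
    return labels, type_idx, regime, pi0, tau2_fixed, t2_shape, t2_scale


class SpikeSlabModel:
    """Bayesian variable-selection regression of a phenotype on a design.

    Parameters
    ----------
    y : PhenotypeVector or pandas.Series
        Continuous phenotype; must cover every line of the design.
    design : DesignMatrix or pandas.DataFrame
        Predictors. A bare DataFrame is treated as expression-type columns.
    priors : PriorConfig, optional
        Inclusion regimes and variance priors (default: shrinkage priors).
    """

    def __init__(self, y, design, priors: PriorConfig | None = None):
        if isinstance(design, pd.DataFrame):
            design = DesignMatrix(
                design.astype(float),
                np.asarray(["expression"] * design.shape[1], dtype=object),
                pd.Series(0.0, index=design.columns),
                pd.Series(1.0, index=design.columns),
            )
        self.design = design
        if isinstance(y, PhenotypeVector):
            yname, yser = y.name, y.values
        else:
            yser = pd.Series(y)
            yname = yser.name or "phenotype"
        missing = [l for l in design.line_ids if l not in yser.index]
        if missing:
            raise ValueError(f"phenotype missing for lines {missing[:5]}")
        self.endog = yser.loc[design.line_ids].astype(float)
        if float(self.endog.std(ddof=0)) == 0.0:
            raise ValueError("phenotype has zero variance")
        self.endog_name = yname
        self.priors = priors if priors is not None else PriorConfig.default()

    @classmethod
    def from_data(
        cls,
        y: PhenotypeVector,
        G: GenotypeMatrix | None = None,
        E: ExpressionMatrix | None = None,
        selection: dict[str, list[str]] | None = None,
        priors: PriorConfig | None = None,
        standardize_expression: bool = True,
    ) -> "SpikeSlabModel":
        design = build_design(G, E, selection, standardize_expression)
        design = replace(design, values=design.values.loc[
            [l for l in design.line_ids if l in set(y.line_ids)]])
        return cls(y, design, priors)

    def fit(
        self,
        iterations: int = 12000,
        burn_in: int = 2000,
        thin: int = 2,
        chains: int = 2,
        seed: int | None = None,
    ) -> "SpikeSlabResults":
        """Run the Gibbs sampler and return a results object."""
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        if seed is None:
            raise ValueError("a seed is required for reproducible sampling")
        from ._sampler import run_chain

        X = self.design.matrix()
        y = self.endog.to_numpy()
        labels, type_idx, regime, pi0, tau2_fixed, t2_shape, t2_scale = _kernel_inputs(
            self.design, self.priors
        )
        chain_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=chains)
        keep = slice(burn_in, iterations, thin)
        parts = []
        for c, cs in enumerate(chain_seeds):
            draws = run_chain(
                X, y, type_idx, regime, pi0, tau2_fixed, t2_shape, t2_scale,
                self.priors.sigma2_shape, self.priors.sigma2_scale,
                iterations, int(cs),
            )
            a, b, ind, s2, pi, t2 = (d[keep] for d in draws)
            if not np.all(np.isfinite(s2)) or np.any(s2 <= 0):
                raise RuntimeError("divergent sigma^2 draws; check the data scale")
            parts.append((a, b, ind, s2, pi, t2, np.full(len(a), c)))
        cat = [np.concatenate([p[i] for p in parts]) for i in range(7)]
        samples = PosteriorSamples(
            column_ids=self.design.column_ids,
            column_types=self.design.col_types.copy(),
            alpha=cat[0], beta=cat[1], indicator=cat[2].astype(np.int8),
            sigma2=cat[3], pi=cat[4], tau2=cat[5], type_labels=labels,
            chain=cat[6].astype(int),
            iterations=iterations, burn_in=burn_in, thin=thin, seed=seed,
        )
        return SpikeSlabResults(self, samples)

    def sample_prior(self, draws: int = 5000, seed: int | None = None) -> PosteriorSamples:
        """Sample (alpha, beta, I, pi, sigma^2) from the prior alone.

        Useful for checking what a prior configuration implies a priori,
        e.g. the expected model size under a given shrinkage probability.
        """
        if seed is None:
            raise ValueError("a seed is required")
        rng = np.random.default_rng(seed)
        labels, type_idx, regime, pi0, tau2_fixed, t2_shape, t2_scale = _kernel_inputs(
            self.design, self.priors
        )
        p, T = len(self.design.column_ids), len(labels)
        pi = np.tile(pi0, (draws, 1))
        for t in range(T):
            if regime[t] == 3:
                pi[:, t] = rng.uniform(0.0, 1.0, size=draws)
            elif regime[t] == 1:
                pi[:, t] = 1.0
            elif regime[t] == 2:
                pi[:, t] = 0.0
        ind = (rng.random((draws, p)) < pi[:, type_idx]).astype(np.int8)
        tau2 = np.empty((draws, T))
        for t in range(T):
            if tau2_fixed[t] > 0:
                tau2[:, t] = tau2_fixed[t]
            else:
                tau2[:, t] = 1.0 / rng.gamma(t2_shape[t], 1.0 / t2_scale[t], size=draws)
        beta = rng.standard_normal((draws, p)) * np.sqrt(tau2[:, type_idx])
        # a shape as small as 0.01 yields gamma draws that underflow to 0;
        # clip so the (astronomically heavy-tailed) 1/gamma stays finite
        gamma_draws = rng.gamma(
            self.priors.sigma2_shape, 1.0 / self.priors.sigma2_scale, size=draws
        )
        sigma2 = 1.0 / np.clip(gamma_draws, 1e-300, None)
        return PosteriorSamples(
            column_ids=self.design.column_ids,
            column_types=self.design.col_types.copy(),
            alpha=rng.standard_normal(draws), beta=beta, indicator=ind,
            sigma2=sigma2, pi=pi, tau2=tau2, type_labels=labels,
            chain=np.zeros(draws, dtype=int), seed=seed,
        )


class SpikeSlabResults:
    """Posterior summaries, prediction and deviance for a fitted model."""

    def __init__(self, model: SpikeSlabModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    @property
    def pip(self) -> pd.Series:
        """Posterior inclusion probability per predictor."""
        return self.samples.inclusion_probability

    @property
    def params(self) -> pd.Series:
        """Posterior mean of I * beta (the effective coefficients)."""
        return pd.Series(
            self.samples.active_coefficients().mean(axis=0),
            index=self.samples.column_ids, name="mean_active_coef",
        )

    @property
    def intercept(self) -> float:
        return float(self.samples.alpha.mean())

    @property
    def sigma2_mean(self) -> float:
        return float(self.samples.sigma2.mean())

    @property
    def effective_model_size(self) -> float:
        return self.samples.effective_model_size

    def predict(self, design: DesignMatrix | None = None) -> pd.Series:
        """Posterior mean prediction; defaults to in-sample fitted values."""
        design = design if design is not None else self.model.design
        return posterior_predict(self.samples, design)

    @property
    def fittedvalues(self) -> pd.Series:
        return self.predict()

    def deviance(self, design: DesignMatrix | None = None, y: pd.Series | None = None) -> float:
        design = design if design is not None else self.model.design
        y = y if y is not None else self.model.endog
        return compute_deviance(self.samples, design, y)

    def pip_by_chain(self) -> pd.DataFrame:
        """Per-chain inclusion probabilities (a simple mixing check)."""
        out = {}
        for c in np.unique(self.samples.chain):
            mask = self.samples.chain == c
            out[f"chain{c}"] = self.samples.indicator[mask].mean(axis=0)
        return pd.DataFrame(out, index=self.samples.column_ids)

    def summary(self, top: int = 20) -> str:
        s = self.samples
        lines = [
            "Spike-and-slab regression results",
            "=" * 46,
            f"Phenotype:            {self.model.endog_name}",
            f"Lines / predictors:   {len(self.model.endog)} / {len(s.column_ids)}",
            f"Draws (chains):       {s.n_draws} ({len(np.unique(s.chain))})",
            f"Posterior mean alpha: {self.intercept: .4f}",
            f"Posterior mean sigma2:{self.sigma2_mean: .4f}",
            f"Effective model size: {self.effective_model_size: .2f}",
            f"In-sample deviance:   {self.deviance(): .2f}",
            "-" * 46,
        ]
        tab = pd.DataFrame({
            "type": s.column_types,
            "pip": self.pip,
            "mean_coef": self.params,
        }).sort_values("pip", ascending=False).head(top)
        lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def relevance(self, marginal: pd.Series | None = None) -> pd.DataFrame:
        """Relevance table (posterior mean I*|beta|, variance-weighted)."""
        from .enrichment import weighted_relevance

        return weighted_relevance(self.samples, self.model.design, marginal=marginal)


def fit_spike_slab(
    design: DesignMatrix, y, priors: PriorConfig | None = None, **mcmc
) -> SpikeSlabResults:
    """Functional wrapper: build the model and fit in one call."""
    return SpikeSlabModel(y, design, priors).fit(**mcmc)


def posterior_predict(samples: PosteriorSamples, design: DesignMatrix) -> pd.Series:
    """Posterior mean of alpha + X (I * beta) per line of ``design``."""
    if list(design.column_ids) != list(samples.column_ids):
        raise ValueError("design columns do not match the fitted columns")
    mean_active = samples.active_coefficients().mean(axis=0)
    pred = samples.alpha.mean() + design.matrix() @ mean_active
    return pd.Series(pred, index=design.line_ids, name="predicted")


def compute_deviance(samples: PosteriorSamples, design: DesignMatrix, y) -> float:
    """Posterior mean deviance -2 E[log p(y | mu(draw), sigma2(draw))]."""
    yv = pd.Series(y).loc[design.line_ids].to_numpy(dtype=float)
    if list(design.column_ids) != list(samples.column_ids):
        raise ValueError("design columns do not match the fitted columns")
    X = design.matrix()
    mu = samples.alpha[:, None] + samples.active_coefficients() @ X.T  # (draws, n)
    resid2 = (yv[None, :] - mu) ** 2
    n = len(yv)
    dev = n * np.log(2.0 * np.pi * samples.sigma2) + resid2.sum(axis=1) / samples.sigma2
    return float(dev.mean())
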