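"""Synthetic RIL genotype, expression and phenotype generation.

The generator emulates the structure of a recombinant-inbred-line (RIL)
study: binary genotypes with linkage along chromosomes, gene expression
partly driven in cis by markers, and an approximately normal phenotype
built as a sparse additive function of a few markers and a few gene
expressions plus Gaussian noise with controllable heritability.

RIL linkage uses the Haldane-Waddington selfing limit: if the per-meiosis
recombination fraction between adjacent markers is ``r``, the probability
that a fully inbred selfed line switches parental origin between them is
``R = 2r / (1 + 2r)``. Genotypes along a chromosome form a two-state
Markov chain with that switch probability; chromosomes are independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeVector,
    TruthRecord,
)

__all__ = [
    "default_genetic_map",
    "selfing_switch_probability",
    "simulate_ril_genotypes",
    "simulate_expression",
    "simulate_phenotype",
]


def selfing_switch_probability(r):
    """Effective recombination between adjacent markers in a selfed RIL.

    This is the Haldane-Waddington limit ``R = 2r / (1 + 2r)`` reached
    after many generations of selfing from an F1.
    """
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def default_genetic_map(
    n_chromosomes: int = 20, n_markers: int = 941, r: float = 0.1
) -> GeneticMap:
    """Evenly spread ``n_markers`` over chromosomes with constant adjacent r.

    Defaults mirror a mid-size plant genome: 20 chromosomes carrying 941
    markers (47-48 each) with moderate linkage (r = 0.1) between neighbours.
    """
    base, extra = divmod(n_markers, n_chromosomes)
    chroms: dict[str, tuple[list[str], np.ndarray]] = {}
    m = 0
    for c in range(n_chromosomes):
        size = base + (1 if c < extra else 0)
        markers = [f"m{m + i:04d}" for i in range(size)]
        m += size
        chroms[f"chr{c + 1:02d}"] = (markers, np.full(max(size - 1, 0), r))
    return GeneticMap(chroms)


def simulate_ril_genotypes(map: GeneticMap, n_lines: int, seed: int) -> GenotypeMatrix:
    """Draw fully inbred RIL genotypes as Markov chains along chromosomes.

    The first marker of each chromosome is Bernoulli(0.5); each subsequent
    marker switches parental origin with probability
    ``selfing_switch_probability(r)``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    for markers, r in map.chromosomes.values():
        p = len(markers)
        g = np.empty((n_lines, p), dtype=np.int8)
        g[:, 0] = rng.random(n_lines) < 0.5
        if p > 1:
            switch = rng.random((n_lines, p - 1)) < selfing_switch_probability(r)
            # cumulative XOR of switches propagates parental origin
            flips = np.cumsum(switch, axis=1) % 2
            g[:, 1:] = g[:, [0]] ^ flips.astype(np.int8)
        blocks.append(pd.DataFrame(g, columns=markers))
    values = pd.concat(blocks, axis=1)
    values.index = pd.Index([f"line{i:04d}" for i in range(n_lines)], name="line")
    return GenotypeMatrix(values, map=map)


def simulate_expression(
    G: GenotypeMatrix,
    n_genes: int,
    cis_fraction: float = 0.3,
    cis_effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate transcript abundances, a share of them cis-driven by markers.

    A ``cis_fraction`` share of genes is each tied to one marker and
    generated as ``cis_effect * genotype + Normal(0, noise_sd^2)``; the
    remaining genes are pure Gaussian noise. The marker assignment is
    recorded in ``gene_info``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not 0 <= cis_fraction <= 1:
        raise ValueError("cis_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_lines = len(G.line_ids)
    n_cis = int(round(cis_fraction * n_genes))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    values = rng.normal(0.0, noise_sd, size=(n_lines, n_genes))
    linked = np.array([None] * n_genes, dtype=object)
    if n_cis > 0:
        marker_idx = rng.integers(0, len(G.marker_ids), size=n_cis)
        cis_cols = rng.choice(n_genes, size=n_cis, replace=False)
        geno = G.values.to_numpy()
        values[:, cis_cols] += cis_effect * geno[:, marker_idx]
        linked[cis_cols] = np.asarray(G.marker_ids, dtype=object)[marker_idx]
    frame = pd.DataFrame(values, index=G.values.index, columns=gene_ids)
    info = pd.DataFrame({"linked_marker": linked}, index=pd.Index(gene_ids))
    return ExpressionMatrix(frame, gene_info=info)


def simulate_phenotype(
    G: GenotypeMatrix,
    E: ExpressionMatrix | None,
    n_qtl_markers: int,
    n_qtl_genes: int,
    h2: float,
    effect_scale: float = 1.0,
    seed: int = 0,
    name: str = "phenotype",
) -> tuple[PhenotypeVector, TruthRecord]:
    """Build a sparse additive phenotype over markers and gene expressions.

    ``y = alpha + sum_l beta_l x_l + e`` with ``e ~ Normal(0, sigma^2)``.
    Marker covariates enter as raw 0/1 codes; gene expressions are
    standardized first so both effect scales are comparable. The residual
    scale is set (and the drawn residuals rescaled to their target variance)
    so the realized genetic-variance share equals ``h2``.
    """
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lines = list(G.line_ids)
    if E is not None:
        lines = [l for l in lines if l in set(E.line_ids)]
        if not lines:
            raise ValueError("G and E share no lines")
    if n_qtl_markers > len(G.marker_ids):
        raise ValueError("n_qtl_markers exceeds available markers")
    if E is None and n_qtl_genes > 0:
        raise ValueError("gene QTL requested without expression data")
    if E is not None and n_qtl_genes > len(E.gene_ids):
        raise ValueError("n_qtl_genes exceeds available genes")

    n = len(lines)
    alpha = 0.0
    genetic = np.zeros(n)
    marker_effects: dict[str, float] = {}
    gene_effects: dict[str, float] = {}
    if h2 > 0:
        qtl_m = rng.choice(G.marker_ids, size=n_qtl_markers, replace=False)
        geno = G.values.loc[lines, qtl_m].to_numpy(dtype=float)
        # equal-magnitude effects with random sign; markers on 0/1 scale
        # carry variance ~0.25, so scale them up to match unit-sd genes
        bm = effect_scale * rng.choice((-1.0, 1.0), size=n_qtl_markers) * 2.0
        genetic = genetic + geno @ bm
        marker_effects = dict(zip(qtl_m, bm))
        if n_qtl_genes > 0:
            qtl_g = rng.choice(E.gene_ids, size=n_qtl_genes, replace=False)
            expr = E.values.loc[lines, qtl_g].to_numpy(dtype=float)
            expr = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=0)
            bg = effect_scale * rng.choice((-1.0, 1.0), size=n_qtl_genes)
            genetic = genetic + expr @ bg
            gene_effects = dict(zip(qtl_g, bg))

    var_g = float(np.var(genetic))
    if h2 == 0 or var_g == 0:
        sigma2 = 1.0
        marker_effects, gene_effects = {}, {}
        genetic = np.zeros(n)
        realized_h2 = 0.0
        resid = rng.normal(0.0, 1.0, size=n)
    else:
        sigma2 = var_g * (1.0 - h2) / h2
        resid = rng.normal(0.0, 1.0, size=n)
        resid = resid - resid.mean()
        resid *= np.sqrt(sigma2) / resid.std(ddof=0)
        realized_h2 = var_g / (var_g + float(np.var(resid)))
    y = pd.Series(alpha + genetic + resid, index=pd.Index(lines, name="line"), name=name)
    truth = TruthRecord(
        intercept=alpha,
        marker_effects=marker_effects,
        gene_effects=gene_effects,
        residual_variance=sigma2,
        heritability=realized_h2,
    )
    return PhenotypeVector(y, name=name), truth
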