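"""End-to-end pipeline: simulate or load, pre-select, fit/CV, enrich.

A :class:`RunConfig` (typically parsed from a YAML file) drives the run;
every stage's randomness is derived from one master seed, all outputs are
delimited text in one output directory, and a :class:`RunManifest` (JSON,
written atomically at the end) records the configuration snapshot, stage
timings, warnings and the output inventory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import read_gene_sets, set_enrichment
from .evaluation import Strategy, make_kfold, run_cross_validation
from .io import (
    read_genetic_map,
    read_matrix,
    read_phenotype,
    write_genetic_map,
    write_matrix,
    write_truth,
)
from .model import InclusionPrior, PriorConfig, SpikeSlabModel, build_design
from .preselect import rank_genes_by_correlation, rank_sfps_by_t
from .simulate import (
    default_genetic_map,
    simulate_expression,
    simulate_phenotype,
    simulate_ril_genotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2^31) from the master seed."""
    tag = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    output_dir: str
    seed: int
    # either simulate ...
    simulate: dict | None = None  # keys: n_lines, n_markers, n_chromosomes, r,
    #                               n_genes, cis_fraction, cis_effect, noise_sd,
    #                               n_qtl_markers, n_qtl_genes, h2
    # ... or load
    genotype_path: str | None = None
    expression_path: str | None = None
    phenotype_path: str | None = None
    map_path: str | None = None
    phenotype_name: str | None = None
    gene_sets_path: str | None = None
    # analysis settings
    strategy: dict = field(default_factory=dict)  # Strategy(**strategy)
    priors: dict = field(default_factory=dict)  # marker type -> InclusionPrior kwargs
    cv: dict = field(default_factory=dict)  # k, decile_tolerance, max_tries
    stages: list[str] = field(default_factory=lambda: ["data", "preselect", "cv", "fit"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def build_priors(self) -> PriorConfig:
        if not self.priors:
            return PriorConfig.non_indicator()
        by_type = {t: InclusionPrior(**kw) for t, kw in self.priors.items()}
        return PriorConfig(by_type=by_type)

    def build_strategy(self) -> Strategy:
        return Strategy(priors=self.build_priors(), **self.strategy)

    def validate(self) -> None:
        if self.simulate is None:
            for label, p in (
                ("phenotype", self.phenotype_path),
                ("genotype", self.genotype_path),
                ("expression", self.expression_path),
            ):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{label} file not found: {p}")
            if self.phenotype_path is None:
                raise ValueError("either 'simulate' settings or a phenotype_path is required")
        if self.gene_sets_path is not None and not Path(self.gene_sets_path).exists():
            raise FileNotFoundError(f"gene-set file not found: {self.gene_sets_path}")


@dataclass
class RunManifest:
    """Record of a completed run: config, timings, warnings, outputs."""

    config: dict
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def write(self, path) -> None:
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        os.replace(tmp, path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the configured stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)

    def _save(obj, name, writer=write_matrix):
        path = out / name
        writer(obj, path)
        manifest.outputs.append(name)

    def _stage(name):
        manifest.timings[name] = time.time()
        logger.info("stage %s", name)

    def _done(name):
        manifest.timings[name] = round(time.time() - manifest.timings[name], 3)

    try:
        _stage("data")
        G = E = None
        truth = None
        if config.simulate is not None:
            sim = dict(config.simulate)
            gmap = default_genetic_map(
                sim.get("n_chromosomes", 20), sim.get("n_markers", 941), sim.get("r", 0.1)
            )
            G = simulate_ril_genotypes(
                gmap, sim.get("n_lines", 260), seed=stage_seed(config.seed, "genotypes")
            )
            E = simulate_expression(
                G, sim.get("n_genes", 2000),
                cis_fraction=sim.get("cis_fraction", 0.3),
                cis_effect=sim.get("cis_effect", 1.0),
                noise_sd=sim.get("noise_sd", 1.0),
                seed=stage_seed(config.seed, "expression"),
            )
            y, truth = simulate_phenotype(
                G, E,
                n_qtl_markers=sim.get("n_qtl_markers", 5),
                n_qtl_genes=sim.get("n_qtl_genes", 3),
                h2=sim.get("h2", 0.5),
                seed=stage_seed(config.seed, "phenotype"),
                name=config.phenotype_name or "phenotype",
            )
            _save(G, "genotypes.tsv")
            _save(E, "expression.tsv")
            _save(y, "phenotype.tsv")
            _save(gmap, "genetic_map.tsv", writer=write_genetic_map)
            _save(truth, "truth.tsv", writer=write_truth)
        else:
            gmap = read_genetic_map(config.map_path) if config.map_path else None
            if config.genotype_path:
                G = read_matrix(config.genotype_path, "genotype", map=gmap)
            if config.expression_path:
                E = read_matrix(config.expression_path, "expression")
            y = read_phenotype(config.phenotype_path, config.phenotype_name)
        _done("data")

        strategy = config.build_strategy()
        use_G = G if strategy.n_sfp > 0 else None
        use_E = E if strategy.n_gene > 0 else None

        selection: dict[str, list[str]] = {}
        if "preselect" in config.stages:
            _stage("preselect")
            if use_G is not None:
                rk = rank_sfps_by_t(use_G, y)
                _save(rk.to_frame(), "sfp_ranking.tsv",
                      writer=lambda o, p: o.to_csv(p, sep="\t", index=False))
                selection["sfp"] = rk.top(strategy.n_sfp)
            if use_E is not None:
                rk = rank_genes_by_correlation(use_E, y, strategy.gene_top_fraction)
                _save(rk.to_frame(), "gene_ranking.tsv",
                      writer=lambda o, p: o.to_csv(p, sep="\t", index=False))
                selection["expression"] = rk.top(strategy.n_gene)
            _done("preselect")

        if "cv" in config.stages:
            _stage("cv")
            folds = make_kfold(
                y, k=config.cv.get("k", 5), seed=stage_seed(config.seed, "folds"),
                max_tries=config.cv.get("max_tries", 100),
                decile_tolerance=config.cv.get("decile_tolerance", 0.25),
            )
            if not folds.homogeneous:
                manifest.warnings.append("fold homogeneity tolerance not reached")
            _save(folds.assignment, "folds.tsv")
            res = run_cross_validation(
                use_G, use_E, y, folds, strategy, seed=stage_seed(config.seed, "cv")
            )
            if res.metadata.get("used_full_data_ranking"):
                manifest.warnings.append(
                    "common-subset selection used the all-data ranking inside CV"
                )
            _save(res.frame, "cv_predictions.tsv")
            manifest.metrics.update(
                out_pearson=res.out_pearson, out_spearman=res.out_spearman,
                in_pearson=res.in_pearson, in_spearman=res.in_spearman,
                mean_deviance=float(np.mean(res.deviance_per_fold)),
            )
            _done("cv")

        if "fit" in config.stages and selection:
            _stage("fit")
            design = build_design(
                use_G, use_E, selection,
                standardize_expression=strategy.standardize_expression,
            )
            design_lines = [l for l in design.line_ids if l in set(y.line_ids)]
            design = dataclasses.replace(design, values=design.values.loc[design_lines])
            model = SpikeSlabModel(y, design, strategy.priors)
            results = model.fit(**strategy.mcmc(stage_seed(config.seed, "fit")))
            rel = results.relevance()
            _save(rel, "relevance.tsv")
            manifest.metrics["effective_model_size"] = results.effective_model_size
            manifest.metrics["in_sample_deviance"] = results.deviance()
            (out / "fit_summary.txt").write_text(results.summary() + "\n")
            manifest.outputs.append("fit_summary.txt")

            if config.gene_sets_path and "enrich" in config.stages:
                _stage("enrich")
                sets = read_gene_sets(config.gene_sets_path)
                table = set_enrichment(rel, sets, context="full-data fit")
                _save(table, "enrichment.tsv")
                _done("enrich")
            _done("fit")
    except Exception as exc:
        stage = [k for k, v in manifest.timings.items() if not isinstance(v, float) or v > 1e9]
        raise RuntimeError(f"pipeline stage {stage[-1] if stage else '?'} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest
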