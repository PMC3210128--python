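import numpy as np
import pandas as pd
import pytest

from spikeslab import (
    PriorConfig,
    SpikeSlabModel,
    build_design,
    default_genetic_map,
    rank_genes_by_correlation,
    rank_sfps_by_t,
    simulate_expression,
    simulate_phenotype,
    simulate_ril_genotypes,
)


@pytest.fixture(scope="session")
def ril_dataset():
    """Mid-size simulated dataset with known planted effects."""
    gmap = default_genetic_map(5, 60, r=0.15)
    G = simulate_ril_genotypes(gmap, 200, seed=11)
    E = simulate_expression(G, 300, cis_fraction=0.3, seed=12)
    y, truth = simulate_phenotype(G, E, n_qtl_markers=3, n_qtl_genes=2, h2=0.5, seed=13)
    return G, E, y, truth


@pytest.fixture(scope="session")
def fitted_results(ril_dataset):
    """A fitted joint-data model on pre-selected columns (shared by tests)."""
    G, E, y, truth = ril_dataset
    selection = {
        "sfp": rank_sfps_by_t(G, y).top(10),
        "expression": rank_genes_by_correlation(E, y).top(10),
    }
    design = build_design(G, E, selection)
    priors = PriorConfig.default(sfp_pi=0.1, expression_pi=0.1)
    model = SpikeSlabModel(y, design, priors)
    return model.fit(iterations=3000, burn_in=1000, thin=2, chains=2, seed=21)


@pytest.fixture()
def toy_design():
    """Hand-sized design with one sfp and one expression column."""
    lines = [f"l{i}" for i in range(6)]
    frame = pd.DataFrame(
        {"m1": [0, 0, 0, 1, 1, 1], "g1": [-1.2, 0.3, 0.8, -0.5, 1.0, -0.4]},
        index=lines, dtype=float,
    )
    from spikeslab.model import DesignMatrix

    return DesignMatrix(
        frame,
        np.array(["sfp", "expression"], dtype=object),
        pd.Series(0.0, index=frame.columns),
        pd.Series(1.0, index=frame.columns),
    )
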