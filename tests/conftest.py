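import numpy as np
import pandas as pd
import pytest

from ilmqtl.panel import MetabolitePanel
from ilmqtl.simulate import QtlEffect, SimConfig, simulate_panel


def make_panel(values_by_key, metabolites):
    """Panel from {(genotype, replicate, experiment): [values...]}."""
    idx = pd.MultiIndex.from_tuples(values_by_key.keys(),
                                    names=["genotype", "replicate", "experiment"])
    return MetabolitePanel(
        pd.DataFrame(list(values_by_key.values()), index=idx, columns=metabolites)
    )


@pytest.fixture
def tiny_panel():
    """2 genotypes x 2 replicates x 1 experiment x 3 metabolites, complete."""
    return make_panel(
        {
            ("M82", 1, 1): [1.0, 2.0, 4.0],
            ("M82", 2, 1): [1.0, 2.0, 4.0],
            ("IL01", 1, 1): [2.0, 2.0, 1.0],
            ("IL01", 2, 1): [2.0, 2.0, 1.0],
        },
        ["metA", "metB", "metC"],
    )


@pytest.fixture
def small_sim():
    """Small two-experiment simulation with two strong planted QTL."""
    cfg = SimConfig(
        n_ils=10, n_metabolites=6, n_replicates=4, n_experiments=2,
        sigma_g=0.0, sigma_env=0.2, sigma_ge=0.0, sigma_eps=0.2,
        qtl_effects=[QtlEffect(0, 0, 1.5), QtlEffect(3, 2, -1.5)],
        seed=11,
    )
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth
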