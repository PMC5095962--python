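import numpy as np
import pytest

from crossphen import qc
from crossphen.simulate import PlantedEffect, SimConfig, simulate_panel, simulate_phenotypes


@pytest.fixture(scope="session")
def small_study():
    """A 60-line, 300-marker study with one strong planted effect."""
    cfg = SimConfig(
        n_lines=60,
        n_markers=300,
        seed=11,
        planted_effects=[PlantedEffect(marker_index=7, trait_index=0, beta_genotype=1.5)],
    )
    panel = simulate_panel(cfg)
    table, truth = simulate_phenotypes(panel, cfg)
    matrix = qc.strain_means(table)
    return cfg, panel, table, truth, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
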