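import numpy as np
import pandas as pd
import pytest

from wheatgs import phenomodel, syndata


@pytest.fixture(scope="session")
def panel():
    """Small structured panel shared across tests (3 subpops, mild divergence)."""
    spec = syndata.PanelSpec(
        n_lines=150, n_markers=400, n_subpops=3, fst=0.15,
        maf_range=(0.1, 0.5), n_chroms=5, map_length_per_chrom=1.5, seed=11,
    )
    g, labels = syndata.simulate_panel(spec)
    return g, labels


@pytest.fixture(scope="session")
def trait(panel):
    g, _ = panel
    return syndata.sample_architecture(
        g, n_qtl=20, seed=5, effect_sd=0.12, n_major=2, major_effect=0.15,
        target_h2=0.5, mu=3.2, env_main_sd=0.3, gxe_sd=0.1,
    )


@pytest.fixture(scope="session")
def pheno(panel, trait):
    g, _ = panel
    design = syndata.EnvDesign(n_envs=4, n_reps=2)
    return syndata.simulate_phenotypes(g, trait, design, seed=7)


@pytest.fixture(scope="session")
def blups(pheno):
    _, b = phenomodel.fit_env_model(pheno)
    return b


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def two_marker_map():
    """One chromosome, two markers 10 cM apart."""
    return pd.DataFrame(
        {"marker": ["A", "B"], "chrom": ["chr1", "chr1"], "position_cM": [0.0, 10.0]}
    )
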