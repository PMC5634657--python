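import numpy as np
import pytest

from netmsea.containers import GeneSetCollection
from netmsea.synth import SyntheticStudySpec, simulate_modules, simulate_study

UNIVERSE_400 = [f"G{i:05d}" for i in range(1, 401)]


@pytest.fixture(scope="session")
def gene_universe():
    return list(UNIVERSE_400)


@pytest.fixture(scope="session")
def null_study():
    """A no-signal synthetic study shared across calibration tests."""
    spec = SyntheticStudySpec(n_markers=2000, n_genes=400, seed=11)
    return simulate_study(spec)


@pytest.fixture(scope="session")
def planted_design():
    """50 modules with the first one carrying planted GWAS signal."""
    mods = simulate_modules(50, (15, 25), 0.02, UNIVERSE_400, seed=3)
    planted = next(iter(mods))
    spec = SyntheticStudySpec(n_markers=2000, n_genes=400,
                              planted_module=planted, planted_fraction=0.5,
                              enrichment_shape=0.2, seed=21)
    return simulate_study(spec, modules=mods), mods, planted


@pytest.fixture()
def random_sets(null_study):
    """100 random 20-gene sets over the mapped-gene universe."""
    rng = np.random.default_rng(17)
    genes = sorted(null_study.mapping["gene_id"].unique())
    return GeneSetCollection({
        f"R{i:03d}": rng.choice(genes, 20, replace=False)
        for i in range(100)})
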