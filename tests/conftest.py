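import pytest

from moacliff.chem_io import AGONIST, ANTAGONIST
from moacliff.preprocess import run_pipeline
from moacliff.synthetic import SimulationConfig, generate_library, paper_toy_fixture


@pytest.fixture(scope="session")
def toy():
    """Hand-written two-assay fixture with in-study structures."""
    return paper_toy_fixture()


@pytest.fixture(scope="session")
def small_library():
    """A compact seeded synthetic library with ground truth."""
    config = SimulationConfig(
        seed=7,
        n_scaffold_templates=15,
        n_compounds=120,
        n_dual_active=4,
        n_planted_strong_cliffs=2,
        n_planted_weak_cliffs=2,
    )
    return generate_library(config)


@pytest.fixture(scope="session")
def small_curated(small_library):
    """Both assays of the small library after full curation."""
    ag_raw, ant_raw, truth = small_library
    return {AGONIST: run_pipeline(ag_raw), ANTAGONIST: run_pipeline(ant_raw)}, truth
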