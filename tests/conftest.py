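import numpy as np
import pandas as pd
import pytest

from micoprog.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete linked cohort used across integration tests."""
    cfg = CohortConfig(
        n_samples=90,
        n_genes=120,
        n_taxa=40,
        clone_richness=200,
        n_templates=8000,
        seed=20240817,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_repertoire_factory(rng):
    """Random clone tables with a mix of productive and nonproductive clones."""
    from micoprog.tcr import Repertoire

    def make(n_clones=30, max_count=50, sample_id="R", seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        counts = local.integers(1, max_count, size=n_clones)
        productive = local.random(n_clones) > 0.2
        # guarantee at least two productive clones
        productive[:2] = True
        clones = pd.DataFrame(
            {
                "sequence": [f"c{i}" for i in range(n_clones)],
                "templates": counts,
                "productive": productive,
            }
        )
        return Repertoire(sample_id=sample_id, clones=clones)

    return make
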