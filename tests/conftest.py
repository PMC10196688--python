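import numpy as np
import pytest

import microgen as mg


def make_cohort(seed=0, n_taxa=12, n_phyla=2, n_timepoints=5, n_subjects=6,
                sparsity=0.25, **kw):
    """Small fully observed synthetic cohort for unit tests."""
    spec = mg.SimulationSpec(
        n_taxa=n_taxa, n_phyla=n_phyla, n_timepoints=n_timepoints,
        n_template_subjects=n_subjects, sparsity=sparsity, seed=seed, **kw)
    return mg.generate_base_cohort(spec)


@pytest.fixture
def cohort():
    return make_cohort()


@pytest.fixture
def masked_cohort():
    ds = make_cohort(seed=1)
    return mg.ampute(ds, mg.MissingnessSpec(mechanism="MCAR", rate=0.25, seed=2))


@pytest.fixture
def clr_masked(masked_cohort):
    return mg.clr_transform(mg.add_pseudocount(masked_cohort))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
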