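import numpy as np
import pytest

import mslight as m


@pytest.fixture(scope="session")
def templates():
    """Default-geometry phantom templates on the 24^3 study grid."""
    return m.make_tissue_templates((24, 24, 24), seed=1)


@pytest.fixture(scope="session")
def effect_cfg(templates):
    return m.default_effect_config(templates)


@pytest.fixture(scope="session")
def cohort(templates, effect_cfg):
    """Small planted-effect cohort shared by the unit tests (the full-size
    41+26 cohort is exercised by the acceptance tests)."""
    return m.simulate_cohort(10, 8, cfg=effect_cfg, seed=11, templates=templates)


@pytest.fixture(scope="session")
def spaces(cohort):
    return m.tissue_search_spaces(m.group_lesion_mask(cohort), cohort.templates)


@pytest.fixture(scope="session")
def pre_unc(cohort):
    return m.preprocess_cohort(cohort, variant=m.UNCORRECTED)


@pytest.fixture(scope="session")
def pre_cor(cohort):
    return m.preprocess_cohort(cohort, variant=m.CORRECTED)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
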