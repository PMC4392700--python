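import pytest

from hco.annotate import AnnotationConfig
from hco.model import build_hco_schema
from hco.synthetic import CohortConfig, build_reference_tbox, generate_cohort, \
    generate_mini_fma
from hco.workflow import saturate_bundle


@pytest.fixture(scope="session")
def schema():
    return build_hco_schema()


@pytest.fixture(scope="session")
def mini_fma():
    return generate_mini_fma()


@pytest.fixture(scope="session")
def reference_tbox():
    return build_reference_tbox()


@pytest.fixture(scope="session")
def small_cohort_config():
    # scaled-down cohort: planted structure identical to the full-size one
    return CohortConfig(n_subjects=2, n_parcels=120, noise_rate=0.0,
                        rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def saturated_subject(small_cohort, reference_tbox):
    return saturate_bundle(small_cohort[0], reference_tbox,
                           AnnotationConfig())
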