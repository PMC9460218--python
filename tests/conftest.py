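import warnings

import numpy as np
import pytest

from metabologenome import CohortConfig, generate_cohort, write_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort (19 subjects x 6 time points), seed 1."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every planted effect switched off."""
    return generate_cohort(
        CohortConfig(
            baseline_dependence=0.0,
            planted_taxon_effect=0.0,
            planted_metabolite_lfc=0.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, default_cohort):
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(default_cohort, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_exclusion_warnings():
    # responder scoring warns per all-excluded feature; irrelevant to most tests
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*all subjects excluded.*", category=UserWarning
        )
        yield
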