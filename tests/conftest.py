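import numpy as np
import pytest

import fnirskit as fk


@pytest.fixture(scope="session")
def layout():
    return fk.default_layout()


@pytest.fixture(scope="session")
def paradigm():
    return fk.TaskParadigm()


@pytest.fixture(scope="session")
def config():
    return fk.AnalysisConfig()


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free, artifact-free cohort settings for closed-loop oracles."""
    return fk.CohortSpec(noise=fk.NoiseSpec.off(), artifact_rate_per_min=0.0, seed=5)


@pytest.fixture(scope="session")
def quiet_subject(quiet_spec, layout, paradigm, config):
    rec, truth = fk.simulate_subject(quiet_spec, "HEALTHY", 123, layout, paradigm, config)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_subject(layout, paradigm, config):
    spec = fk.CohortSpec(seed=3)
    rec, truth = fk.simulate_subject(spec, "T2DM_MDD", 456, layout, paradigm, config)
    return rec, truth


@pytest.fixture(scope="session")
def small_cohort(layout, paradigm, config):
    """A processed 10-per-group cohort shared by group-level tests."""
    spec = fk.CohortSpec(n_per_group=10, seed=21)
    recs, truth, clinical = fk.simulate_cohort(spec, layout, paradigm, config)
    cohort = fk.process_cohort(recs, layout, paradigm, config)
    return spec, truth, clinical, cohort
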