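from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from arteryatlas.phantom import ArterySpec, CohortConfig, default_artery_specs, generate_cohort
from arteryatlas.pipeline import process_subject

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


STUDY_SEED = 11  # fixed desk-scale study conditions


@pytest.fixture(scope="session")
def study_cohort():
    """The desk-scale study cohort: 20 deformed subjects on a 64^3 grid."""
    config = CohortConfig(n_subjects=20, seed=STUDY_SEED)
    specs = default_artery_specs(config)
    return [process_subject(s) for s in generate_cohort(specs, config)]


@pytest.fixture(scope="session")
def zero_cohort():
    """Five bit-identical subjects: no deformation, no jitter, no noise, all
    arteries present — plus one artery at prevalence zero."""
    config = CohortConfig(
        n_subjects=5, deform_amplitude_mm=0.0, rigid_jitter=(0.0, 0.0),
        noise_sd=0.0, seed=3,
    )
    specs = [replace(s, prevalence=1.0) for s in default_artery_specs(config)]
    e = config.extent_mm
    specs.append(
        ArterySpec(
            "AComm",
            [[0.46 * e[0], 0.44 * e[1], 0.66 * e[2]],
             [0.54 * e[0], 0.44 * e[1], 0.66 * e[2]]],
            0.8,
            prevalence=0.0,
        )
    )
    return [process_subject(s) for s in generate_cohort(specs, config)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
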