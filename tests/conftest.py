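import dataclasses
import warnings

import numpy as np
import pytest

import vibropredict as vp

PUBLISHED_BETA = {"const": 79.614, "age": -0.2809, "bc_pta4": -0.0795, "wrs_max": 0.1957}


@pytest.fixture(scope="session")
def published_truth() -> vp.PlantedModel:
    """The published three-predictor model as a planted truth (noiseless)."""
    return vp.PlantedModel(beta=PUBLISHED_BETA, noise_sd=0.0)


@pytest.fixture(scope="session")
def large_frame():
    """One large copula draw under the study conditions (n = 5000, fixed seed)."""
    spec = dataclasses.replace(vp.STUDY_SPEC, n=5000, seed=42)
    return vp.generate_frame(spec)


@pytest.fixture(scope="session")
def study_frame():
    """A 20-patient synthetic cohort under the study conditions."""
    recs = vp.generate(dataclasses.replace(vp.STUDY_SPEC, seed=3))
    return vp.cohort_to_frame(recs)


@pytest.fixture(scope="session")
def planted_frame_200(published_truth):
    """Planted-truth cohort: n = 200, outcome noise SD 3 %."""
    truth = dataclasses.replace(published_truth, noise_sd=3.0)
    spec = dataclasses.replace(vp.STUDY_SPEC, n=200, seed=11)
    return vp.cohort_to_frame(vp.generate_planted(spec, truth))


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def flat_map(level: float) -> dict[float, float]:
    """Flat audiogram at the PTA4 frequencies."""
    return {f: level for f in (0.5, 1.0, 2.0, 4.0)}
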