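import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mariabands.cohort import CohortTable, validate_frame
from mariabands.simulate import generate_cohort, preset_configs

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_frame(n=4, **overrides):
    """A small well-formed cohort frame; overrides patch whole columns."""
    base = pd.DataFrame({
        "patient_id": [f"P{i // 7 + 1:03d}" for i in range(n)],
        "segment": [["I", "II", "III", "IV", "V", "VI", "VII"][i % 7]
                    for i in range(n)],
        "wall_thickness": np.linspace(3.0, 6.0, n),
        "t2_ratio": np.linspace(1.1, 2.0, n),
        "edema": [i % 2 for i in range(n)],
        "ulceration": [0] * n,
        "wsi_pre": [100.0] * n,
        "wsi_post": np.linspace(150.0, 300.0, n),
        "sd_noise_pre": [5.0] * n,
        "sd_noise_post": [5.0] * n,
        "dwi_signal": [i % 4 for i in range(n)],
        "adc": np.linspace(1.0, 2.0, n),
        "pathological": [1] * n,
    })
    for col, vals in overrides.items():
        base[col] = vals
    return base


@pytest.fixture
def small_frame():
    return make_frame()


@pytest.fixture
def small_cohort(small_frame):
    return CohortTable(frame=validate_frame(small_frame), provenance="fixture")


@pytest.fixture(scope="session")
def maria_preset_cohort():
    """One seeded cohort from the published-tables preset."""
    cohort, truth = generate_cohort(preset_configs("maria_clusters", seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def separated_cohort():
    cohort, truth = generate_cohort(preset_configs("well_separated", seed=11))
    return cohort, truth
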