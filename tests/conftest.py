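import numpy as np
import pandas as pd
import pytest

from octvbm import ScanGeometry, TemplateSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20230928)


@pytest.fixture
def small_geometry():
    """Native B-scan count, cropped laterally for fast tests."""
    return ScanGeometry().crop_columns(64)


@pytest.fixture
def small_spec(small_geometry):
    return TemplateSpec(geometry=small_geometry)


@pytest.fixture
def crop128_spec():
    return TemplateSpec(geometry=ScanGeometry().crop_columns(128))


@pytest.fixture
def two_group_covariates():
    def make(n_per_group, rng, groups=("HC", "MS")):
        n = n_per_group * len(groups)
        return pd.DataFrame({
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": np.repeat(groups, n_per_group),
            "age": rng.normal(35, 10, n),
            "sex": rng.choice(["M", "F"], n),
        })

    return make
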