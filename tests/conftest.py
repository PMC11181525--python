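import numpy as np
import pandas as pd
import pytest

from survimpute.roster import CategoricalSpec
from survimpute.synthcohort import (
    default_female_config,
    default_missingness_spec,
    apply_missingness,
    generate_cohort,
)


@pytest.fixture(scope="session")
def toy_roster():
    return [
        CategoricalSpec(
            name="group",
            levels=("A", "B"),
            probs=(0.6, 0.4),
            betas={"B": -0.5},
            ref_level="A",
            kind="binary",
        ),
        CategoricalSpec(
            name="grade",
            levels=("low", "mid", "high"),
            probs=(0.3, 0.5, 0.2),
            betas={"mid": 0.2, "high": 0.4},
            ref_level="low",
            kind="ordinal",
        ),
    ]


@pytest.fixture(scope="session")
def female_cfg_small():
    return default_female_config(n=4000, seed=11)


@pytest.fixture(scope="session")
def female_cohort_small(female_cfg_small):
    return generate_cohort(female_cfg_small)


@pytest.fixture(scope="session")
def female_cfg_20k():
    return default_female_config(n=20_000, seed=42)


@pytest.fixture(scope="session")
def female_cohort_20k(female_cfg_20k):
    return generate_cohort(female_cfg_20k)


@pytest.fixture(scope="session")
def punctured_20k(female_cohort_20k):
    spec = default_missingness_spec("female", seed=42)
    cohort, mask = apply_missingness(female_cohort_20k, spec)
    return cohort, mask


def make_surv_frame(time, event, weight=None, **extra):
    """Tiny cohort frame with the mandatory survival columns."""
    n = len(time)
    frame = pd.DataFrame(
        {
            "sex": ["female"] * n,
            "cycle": [1] * n,
            "age": np.full(n, 50.0),
            "weight": np.ones(n) if weight is None else np.asarray(weight, float),
            "time": np.asarray(time, float),
            "event": np.asarray(event, int),
        }
    )
    for k, v in extra.items():
        frame[k] = v
    return frame


@pytest.fixture
def surv_frame_factory():
    return make_surv_frame
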