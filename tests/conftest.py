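import numpy as np
import pandas as pd
import pytest

from graftree.cohort import Cohort, CovariateSpec, HazardModelSpec, generate_cohort

NO_CENSOR = HazardModelSpec(baseline_rate=0.01, admin_censor_time=1e9,
                            admin_censor_min=1e9 - 1, dropout_rate=0.0)


def binary_cov(name="flag", p=0.3):
    return CovariateSpec(name=name, kind="binary", p=p)


def simple_covs():
    return [
        CovariateSpec(name="flag", kind="binary", p=0.3),
        CovariateSpec(name="level", kind="continuous", mean=0.0, sd=1.0),
        CovariateSpec(name="group", kind="categorical",
                      categories=("a", "b", "c"), frequencies=(0.5, 0.3, 0.2)),
    ]


@pytest.fixture
def signal_cohort():
    """n=1500 cohort with one strong binary effect and moderate censoring."""
    hz = HazardModelSpec(baseline_rate=0.002, log_hr_effects={"flag": np.log(4.0)},
                         admin_censor_time=200.0, admin_censor_min=30.0,
                         dropout_rate=0.003)
    return generate_cohort(1500, simple_covs(), hz, seed=42)


@pytest.fixture
def null_cohort():
    """n=1000 cohort with no covariate effects."""
    hz = HazardModelSpec(baseline_rate=0.004, admin_censor_time=200.0,
                         admin_censor_min=30.0, dropout_rate=0.002)
    return generate_cohort(1000, simple_covs(), hz, seed=7)


def random_node(rng, n_max=30, p_max=3, with_categorical=True):
    """Random small node (columns, kinds, events, times) for oracle checks."""
    n = int(rng.integers(6, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    columns, kinds = [], []
    for j in range(p):
        kind = rng.choice(["ordered", "ordered", "categorical"]) if with_categorical else "ordered"
        if kind == "categorical":
            k = int(rng.integers(2, 5))
            columns.append(rng.choice(np.array(list("abcd")[:k], dtype=object), size=n))
        else:
            columns.append(np.round(rng.normal(size=n), 2))
        kinds.append(kind)
    events = (rng.random(n) < 0.5).astype(int)
    times = np.round(rng.exponential(10.0, size=n), 3) + 0.5
    return columns, kinds, events, times


def node_frame(columns, kinds, events, times):
    data = {}
    for j, col in enumerate(columns):
        data[f"x{j}"] = col
    df = pd.DataFrame(data)
    return Cohort(df, times, events)
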