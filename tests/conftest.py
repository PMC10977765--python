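import warnings

import numpy as np
import pandas as pd
import pytest

from remisml.cohort import CohortTable, FeatureMeta
from remisml.impute import ImputedStack, multiple_impute
from remisml.synthetic import SyntheticConfig, generate_cohort, inject_missingness

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings(
    "ignore", category=RuntimeWarning, message=".*invalid value encountered.*"
)


def tiny_config(**overrides) -> SyntheticConfig:
    """A deliberately small cohort configuration for fast unit tests."""
    base = dict(
        n_per_site=60,
        n_sites=1,
        n_imaging_measures=2,
        n_imaging_regions=8,
        n_hdrs_items=6,
        n_qids_items=4,
        n_clinical=3,
        missing_rate_features=0.03,
        missing_rate_outcome=0.1,
        seed=17,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def manual_cohort(values: dict, features: list[FeatureMeta], hdrs8=None, study="T",
                  site=None, arm=None) -> CohortTable:
    """Hand-built cohort from explicit columns (index p1..pn)."""
    frame = pd.DataFrame(values, dtype=float)
    n = len(frame)
    idx = pd.Index([f"p{i+1}" for i in range(n)], name="participant_id")
    frame.index = idx
    if hdrs8 is None:
        hdrs8 = [5.0] * n
    return CohortTable(
        values=frame[[f.name for f in features]],
        features=features,
        study=study,
        site=pd.Series(site or ["s1"] * n, index=idx),
        arm=pd.Series(arm or ["active"] * n, index=idx),
        hdrs17_week8=pd.Series(hdrs8, index=idx, dtype=float),
    )


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortTable:
    cfg = tiny_config()
    return inject_missingness(generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def tiny_stack(tiny_cohort) -> ImputedStack:
    return multiple_impute(tiny_cohort, M=3, seed=5, max_iter=4, n_nearest_features=10)


@pytest.fixture(scope="session")
def complete_cohort() -> CohortTable:
    return generate_cohort(tiny_config(missing_rate_features=0.0, missing_rate_outcome=0.0))
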