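import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import leafagree as la

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design130():
    """The study's native design: 2 cultivars x 5 replicates x 13 time points."""
    return la.build_design()


@pytest.fixture(scope="session")
def truth130(design130):
    return la.simulate_growth(design130, la.GrowthParams(), seed=42)


@pytest.fixture(scope="session")
def expert_annotations(truth130, design130):
    return la.simulate_observer_counts(
        truth130, design130, la.expert_profile(), seed=7, dot_times=True
    )


@pytest.fixture(scope="session")
def pool_annotations(truth130, design130):
    """Tool-mode first readings from the default 9-observer roster."""
    frames = [
        la.simulate_observer_counts(truth130, design130, profile, seed=100 + 7 * i)
        for i, profile in enumerate(la.default_observer_pool())
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def citizen_study(truth130, design130):
    return la.simulate_citizen_study(truth130, design130, seed=11)


@pytest.fixture()
def paired_small():
    return la.PairedCounts(
        image_ids=["i1", "i2", "i3"],
        x_ref=np.array([5.0, 6.0, 7.0]),
        x_other=np.array([4.0, 6.0, 9.0]),
    )
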