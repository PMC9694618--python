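import numpy as np
import pytest

from cindexlab.cohort import Cohort, Episode


@pytest.fixture
def small_cohort() -> Cohort:
    """Five episodes, both groups present, hand-pickable numbers."""
    return Cohort(
        episodes=[
            Episode("e1", 0, pct=0.2, crp=4.0, il6=20.0),
            Episode("e2", 0, pct=0.5, crp=8.0, il6=50.0),
            Episode("e3", 0, pct=1.0, crp=12.0, il6=90.0),
            Episode("e4", 1, pct=5.0, crp=18.0, il6=300.0),
            Episode("e5", 1, pct=12.0, crp=20.0, il6=400.0, patient_id="p9"),
        ],
        provenance="fixture",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220151)
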