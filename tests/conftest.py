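import numpy as np
import pytest

from stdac.io_data import AtlasGeometry, SubjectTimeSeries, zscore_columns
from stdac.synthetic import SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_geometry():
    """Six ROIs on an irregular but fixed layout (deterministic distances)."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [3.0, 0.0, 0.0],
            [0.0, 4.0, 0.0],
            [10.0, 0.0, 0.0],
            [0.0, 0.0, 12.0],
            [7.0, 7.0, 7.0],
        ]
    )
    return AtlasGeometry(roi_names=[f"R{i}" for i in range(6)], coords=coords)


@pytest.fixture()
def small_subject(rng):
    sig = zscore_columns(rng.standard_normal((40, 6)))
    return SubjectTimeSeries("subj01", sig, "control")


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast synthetic cohort: 8 per class, 12 ROIs, 60 time points."""
    spec = SimulationSpec(
        n_per_class=8,
        m=12,
        t=60,
        planted_edges=((0, 1, (0.0, 0.6)), (4, 5, (0.0, 0.5))),
        seed=7,
    )
    return simulate_cohort(spec)
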