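import numpy as np
import pytest

from brainspaces import (
    BrainState,
    ConnectivityMatrix,
    harmonize_rois,
)


def random_connectivity(rng: np.random.Generator, labels) -> ConnectivityMatrix:
    """A valid random correlation matrix over the given labels."""
    n = len(labels)
    x = rng.standard_normal((max(3 * n, 30), n))
    c = np.corrcoef(x, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(tuple(labels), c)


def make_state(
    state_id: str,
    matrix: ConnectivityMatrix,
    subject_id: str | None = None,
    timepoint: str = "baseline",
    diagnosis: str = "normal",
) -> BrainState:
    return BrainState(
        state_id=state_id,
        subject_id=subject_id or state_id,
        timepoint=timepoint,
        diagnosis=diagnosis,
        matrix=matrix,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labels5():
    return tuple(f"ROI_{c}" for c in "ABCDE")


@pytest.fixture
def small_collection(rng, labels5):
    """Five random states over five ROIs, harmonized."""
    states = [
        make_state(f"s{i}", random_connectivity(rng, labels5)) for i in range(5)
    ]
    return harmonize_rois(states)
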