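import numpy as np
import pytest

import rocshape as rs


@pytest.fixture
def higher():
    return rs.Direction.HIGHER_PREDICTS_EVENT


@pytest.fixture
def lower():
    return rs.Direction.LOWER_PREDICTS_EVENT


@pytest.fixture
def alternating_sample():
    """values 1..4, labels 0,1,0,1: AUROC 3/4 with a hand-enumerable ROC."""
    return rs.BinaryOutcomeSample(np.array([1.0, 2, 3, 4]), np.array([0, 1, 0, 1]))


@pytest.fixture
def separable_sample():
    """Perfectly separated classes."""
    return rs.BinaryOutcomeSample(np.array([1.0, 2, 10, 11]), np.array([0, 0, 1, 1]))


@pytest.fixture(scope="session")
def symmetric_u_sample():
    """One large draw from the canonical symmetric-U null-bias model."""
    return rs.simulate_dataset(rs.symmetric_u_model(), 20000, 2024)


def curve_from_points(points):
    """Build an ROCCurve from (fpr, tpr) vertices with dummy thresholds."""
    f = np.array([p[0] for p in points], dtype=float)
    t = np.array([p[1] for p in points], dtype=float)
    return rs.ROCCurve(thresholds=np.full(len(f), np.nan), fpr=f, tpr=t)
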