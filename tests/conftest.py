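"""Shared fixtures: the two printed toy matrices and common problems."""

from pathlib import Path

import numpy as np
import pytest

from cmcs import BinaryModeMatrix, InterventionProblem

DATA = Path(__file__).parent / "data"

NAMES = tuple(f"R{i}" for i in range(1, 9))

DESIRED_TOY = np.array(
    [
        [0, 1, 0, 0, 1, 0, 1, 0],
        [0, 0, 0, 0, 0, 1, 0, 0],
        [1, 0, 1, 0, 1, 0, 0, 0],
        [1, 1, 0, 0, 0, 0, 1, 0],
        [1, 0, 1, 0, 0, 0, 1, 0],
    ],
    dtype=np.uint8,
)

TARGET_TOY = np.array(
    [
        [0, 1, 0, 0, 0, 0, 0, 0],
        [0, 1, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 0, 0, 1, 0],
        [1, 0, 0, 1, 0, 0, 1, 0],
        [0, 0, 0, 1, 0, 0, 1, 1],
        [1, 0, 1, 0, 0, 0, 1, 1],
    ],
    dtype=np.uint8,
)


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def desired_toy() -> BinaryModeMatrix:
    """Five desired modes over eight reactions (essentiality example)."""
    return BinaryModeMatrix(DESIRED_TOY.copy(), NAMES)


@pytest.fixture
def target_toy() -> BinaryModeMatrix:
    """Six residual target modes (superset-elimination example)."""
    return BinaryModeMatrix(TARGET_TOY.copy(), NAMES)


@pytest.fixture
def empty_matrix() -> BinaryModeMatrix:
    return BinaryModeMatrix(np.zeros((0, 8), dtype=np.uint8), NAMES)


@pytest.fixture
def toy_hypergraph() -> InterventionProblem:
    """The two-edge hypergraph {a,b}, {a,c} with no survival constraint."""
    targets = BinaryModeMatrix.from_supports(
        [{"a", "b"}, {"a", "c"}], ["a", "b", "c"]
    )
    desired = BinaryModeMatrix.from_supports([], ["a", "b", "c"])
    return InterventionProblem(targets=targets, desired=desired, n=0)


@pytest.fixture
def combined_toy(desired_toy, target_toy) -> InterventionProblem:
    """Desired and target toy tables combined, n=3."""
    return InterventionProblem(targets=target_toy, desired=desired_toy, n=3)
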