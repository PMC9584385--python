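import numpy as np
import pytest

from fractalrad import VoxelMask


def brute_force_box_count(grid: np.ndarray, r: int) -> tuple[int, list[int]]:
    """Independent triple-loop oracle for occupied-box counting.

    Crops to the foreground bounding box and walks the corner-anchored
    non-overlapping lattice explicitly.
    """
    idx = np.argwhere(grid)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    masses = []
    for i in range(0, sub.shape[0], r):
        for j in range(0, sub.shape[1], r):
            for k in range(0, sub.shape[2], r):
                m = int(sub[i : i + r, j : j + r, k : k + r].sum())
                if m > 0:
                    masses.append(m)
    return len(masses), masses


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-comparison AUC oracle: P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_mask(rng: np.random.Generator, max_side: int = 32, p: float = 0.3) -> VoxelMask:
    shape = rng.integers(3, max_side + 1, size=3)
    grid = (rng.random(shape) < p).astype(np.uint8)
    if grid.sum() == 0:
        grid[tuple(rng.integers(0, shape))] = 1
    return VoxelMask(grid=grid)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def box_count_oracle():
    return brute_force_box_count


@pytest.fixture
def auc_oracle():
    return brute_force_auc
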