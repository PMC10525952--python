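import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_box_count(binary: np.ndarray, size: int) -> int:
    """Independent double-loop occupancy oracle for box counting."""
    h, w = binary.shape
    count = 0
    for y0 in range(0, h, size):
        for x0 in range(0, w, size):
            if binary[y0:y0 + size, x0:x0 + size].any():
                count += 1
    return count


def all_pairs_auc(scores, labels, direction="le") -> float:
    """All positive-negative pairs oracle for the AUC (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction == "ge":
        scores = -scores
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
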