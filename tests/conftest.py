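import numpy as np
import pytest

from diacascade import FeatureTable, gaussian_spec, generate


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 rows x 2 attributes with known hand-checkable values."""
    return FeatureTable(
        attribute_names=["a", "b"],
        values=np.array([[1.0, 10.0], [3.0, 20.0], [4.0, 40.0]]),
        labels=np.array([1, 2, 1]),
    )


@pytest.fixture
def separable_table() -> FeatureTable:
    """Well-separated 4-class synthetic table (200 rows)."""
    return generate(gaussian_spec(n_per_class=50, separation=4.0, seed=42))


def brute_force_ratio(levels, labels, smoothing):
    """Independent nested-loop oracle for the co-occurrence ratio matrix."""
    n, k = levels.shape
    out = np.empty((16, k))
    for j in range(k):
        for v in (1, 2, 3, 4):
            for c in (1, 2, 3, 4):
                num = den = 0
                for i in range(n):
                    if levels[i, j] == v and labels[i] == c:
                        num += 1
                    if levels[i, j] == v and labels[i] != c:
                        den += 1
                row = (v - 1) * 4 + (c - 1)
                if smoothing > 0:
                    out[row, j] = (num + smoothing) / (den + smoothing)
                elif den > 0:
                    out[row, j] = num / den
                else:
                    out[row, j] = np.inf if num > 0 else 0.0
    return out


def brute_force_confusion(truth, pred):
    """Independent nested-loop oracle for the 4x4 confusion matrix."""
    conf = np.zeros((4, 4), dtype=int)
    for t, p in zip(truth, pred):
        conf[t - 1, p - 1] += 1
    return conf
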