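import numpy as np
import pytest

from ghostcyto import benchmarks
from ghostcyto.gating import threshold_label


@pytest.fixture(scope="session")
def small_two_class():
    """A small simulated two-class run shared by unit tests: (events, labels)."""
    spec = benchmarks.two_class_spec(n_per_class=150, seed=11)
    events, _ = benchmarks.simulate_benchmark(spec, benchmarks.two_class_optics(), seed=11)
    labels = threshold_label(events, benchmarks.two_class_label_rule())
    return events, labels


def brute_force_waveform(mask: np.ndarray, cmap: np.ndarray) -> np.ndarray:
    """Independent oracle for the compressive waveform: padded double loop.

    For each translation t, shift the map by t-(h-1) pixels along the flow
    axis and sum the elementwise product with the mask over the overlap.
    """
    F, W = mask.shape
    h, w = cmap.shape
    out = np.zeros(F + h - 1)
    for t in range(F + h - 1):
        total = 0.0
        for i in range(h):
            s = t - (h - 1) + i
            if 0 <= s < F:
                for j in range(w):
                    total += cmap[i, j] * mask[s, j]
        out[t] = total
    return out


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pairwise probability-of-correct-ranking oracle, ties counted 1/2."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ray_casting_inside(point, vertices) -> bool:
    """Independent even-odd point-in-polygon test (boundary not special-cased)."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
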