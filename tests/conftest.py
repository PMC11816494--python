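import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


def cubicpat_triple_loop(data: np.ndarray) -> np.ndarray:
    """Literal triple-loop transcription of the coding routine.

    Independent oracle for the vectorized extractor: per time sample, build
    the channel vector, stable-descending-sort it, emit every consecutive
    rank triplet as a base-n code and increment the histogram.
    """
    data = np.asarray(data, dtype=float)
    ln, n = data.shape
    histo = np.zeros(n**3, dtype=np.int64)
    for i in range(ln):
        C = data[i]
        ids = sorted(range(1, n + 1), key=lambda k: (-C[k - 1], k))
        for j in range(n - 2):
            m = (ids[j] - 1) * n * n + (ids[j + 1] - 1) * n + (ids[j + 2] - 1)
            histo[m] += 1
    return histo


@pytest.fixture
def reference_extractor():
    return cubicpat_triple_loop


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
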