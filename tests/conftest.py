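import numpy as np
import pytest

from tbikit.presets import default_presets


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def burst_oracle(times, min_spikes=3, max_isi_s=0.300, tol=1e-9):
    """Exhaustive maximal-window burst grouping, independent of the
    implementation: every contiguous window whose internal gaps are all
    <= the limit and whose neighbours (if any) sit beyond the limit is a
    maximal run; runs with >= min_spikes spikes are bursts."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    limit = max_isi_s + tol
    found = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            window = times[i : j + 1]
            if np.all(np.diff(window) <= limit):
                left_max = i == 0 or times[i] - times[i - 1] > limit
                right_max = j == n - 1 or times[j + 1] - times[j] > limit
                if left_max and right_max:
                    found.append((times[i], times[j], j - i + 1))
    return found
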