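import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from corrshape import AnalysisRegion, CorrelogramSpec, Recording, SpikeTrain, assign_bin


def brute_force_counts(ref_times, cmp_times, spec: CorrelogramSpec, auto=False):
    """Independent oracle: double loop over all (t_r, t_c) pairs."""
    counts = np.zeros(spec.n_bins, dtype=int)
    K = spec.half_bins
    for i, tr in enumerate(ref_times):
        for j, tc in enumerate(cmp_times):
            if auto and i == j:
                continue
            lag = tc - tr
            k = assign_bin(lag, spec.bin_width_s)
            if abs(k) <= K:
                counts[k + K] += 1
    return counts


@pytest.fixture
def two_unit_recording():
    a = SpikeTrain("a", np.array([0.1, 0.2, 0.3]))
    b = SpikeTrain("b", np.array([0.15, 0.25, 0.35]))
    return Recording((a, b), duration=1.0)


@pytest.fixture
def full_region():
    return AnalysisRegion(1, 0.0, 1.0)


def random_train(rng, n, duration=10.0):
    return np.sort(rng.uniform(0, duration, size=n))
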