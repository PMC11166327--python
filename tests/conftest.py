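import numpy as np
import pytest

from dnadapt.trial_design import (make_stimulus_timecourse,
                                  temporal_conditions)

FS = 512.0
EPOCH_LEN_S = 1.6
ONSET_S = 0.1


@pytest.fixture(scope="session")
def conditions():
    return {(c.kind, c.level): c for c in temporal_conditions()}


@pytest.fixture(scope="session")
def stimuli(conditions):
    """Canonical stimulus time courses at 512 Hz for all 12 conditions."""
    return {key: make_stimulus_timecourse(c, FS, EPOCH_LEN_S, ONSET_S)
            for key, c in conditions.items()}


@pytest.fixture(scope="session")
def onset_index():
    return round(ONSET_S * FS)


def brute_force_convolve(x, k):
    """O(N*K) direct causal convolution oracle, truncated to len(x)."""
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        for j in range(min(i + 1, len(k))):
            out[i] += x[i - j] * k[j]
    return out
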