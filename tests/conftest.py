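import numpy as np
import pytest

from baitsow.synthetic import TrialDesign, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One noisy 19-block synthetic trial series (fixed seed) with truths."""
    counts, truths = generate_trial(TrialDesign(seed=1234))
    return counts, truths


def exact_moment_group(mean, sd, n):
    """n values realizing the given sample mean and SD (ddof=1) exactly."""
    z = np.arange(n, dtype=float)
    z -= z.mean()
    z /= z.std(ddof=1)
    return mean + sd * z
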