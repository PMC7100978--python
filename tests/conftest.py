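import numpy as np
import pytest

import mosaiq as mq


@pytest.fixture(scope="session")
def small_culture():
    """~550-cell culture with a handful of large clones (shared, read-only)."""
    return mq.grow_culture(mq.GrowthParams(final_size=512), seed=7)


@pytest.fixture(scope="session")
def small_table(small_culture):
    """Measurements for the small culture at low ambiguity (sigma=0.1)."""
    return mq.synthesize_measurements(
        small_culture, mq.FluorescenceParams(sigma_alpha=0.1), seed=11
    )


@pytest.fixture(scope="session")
def annotated_small(small_table):
    """Annotated small table plus pipeline diagnostics (shared, read-only)."""
    config = mq.AnnotationConfig(marker_channel=1, seed=0)
    return mq.annotate_detailed(small_table, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def three_group_sample(n_per_group, sigma, seed, context_shrink=3.0):
    """(X, Y, dosages): three equal dosage groups with clone-like context.

    X is the log fluorescence of each cell; Y emulates the neighborhood mean
    for pure clones (centred on the group mean with reduced spread).
    """
    rng = np.random.default_rng(seed)
    dosages = np.repeat([0, 1, 2], n_per_group)
    mu = (dosages - 1) * np.log(2.0)
    X = rng.normal(mu, sigma)
    Y = rng.normal(mu, sigma / context_shrink)
    return X, Y, dosages
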