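import numpy as np
import pytest

from herniamech.synthetic_data import (
    CohortConfig,
    PhantomConfig,
    generate_cohort,
    generate_phantom_pair,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def worked_example():
    """The published single-patient design example with expected report values."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def phantom_pair():
    """Default 1 mm phantom pair: 5 cm orifice, 4 cm spherical-cap bulge."""
    return generate_phantom_pair(PhantomConfig())


@pytest.fixture(scope="session")
def phantom_pair_2mm():
    """The same phantom geometry voxelized at 2 mm (resolution robustness)."""
    return generate_phantom_pair(
        PhantomConfig(shape=(80, 80, 35), spacing=(2.0, 2.0, 2.0))
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded default-size synthetic cohort (119 primary + 44 recurrent)."""
    return generate_cohort(CohortConfig(seed=1))


def brute_force_mannwhitney(x, y):
    """Independent oracle: exhaustive enumeration of the U permutation null.

    Iterates every assignment of the pooled midranks to the first sample and
    counts tail probabilities directly; two-sided p is
    min(1, 2*min(P(U<=u), P(U>=u))).
    """
    import itertools

    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array(
        [
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            for idx in itertools.combinations(range(n), n1)
        ]
    )
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
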