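import warnings

import numpy as np
import pytest

from gamquant import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_filter_warnings():
    """Cohort filter warnings (necrosis exclusions) are expected in simulations."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="excluded .* cores")
        yield


@pytest.fixture(scope="session")
def default_spot():
    return syn.generate_spot(syn.SpotSpec(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    return syn.generate_cohort(syn.CohortSpec(n_patients=80, seed=11))


def brute_force_li(counts, edges):
    """Independent exhaustive minimizer of the minimum-cross-entropy criterion.

    Plain-python re-derivation from the definition: for every interior bin
    edge, classify bins below/above, compute each side's intensity mass and
    mean, and evaluate -m1*log(mu1) - m2*log(mu2).  Ties resolve to the
    lowest edge within a 1e-9 relative tolerance of the minimum (the
    operation's documented tie rule).
    """
    centers = [(edges[i] + edges[i + 1]) / 2.0 for i in range(len(counts))]
    vals = {}
    for k in range(1, len(counts)):
        w1 = sum(counts[:k]); w2 = sum(counts[k:])
        if w1 == 0 or w2 == 0:
            continue
        m1 = sum(c * x for c, x in zip(counts[:k], centers[:k]))
        m2 = sum(c * x for c, x in zip(counts[k:], centers[k:]))
        vals[edges[k]] = -m1 * np.log(m1 / w1) - m2 * np.log(m2 / w2)
    lo = min(vals.values())
    tol = 1e-9 * max(1.0, abs(lo))
    return next(e for e in sorted(vals) if vals[e] <= lo + tol)
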