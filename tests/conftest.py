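import logging

import numpy as np
import pytest

from scag.core import ScagParams
from scag.synthetic import SamplingSpec, make_y_skeleton, sample_cloud

# per-branch warnings are expected on hard fixtures; keep test output clean
logging.getLogger("scag").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_params() -> ScagParams:
    return ScagParams.for_unit("cm")


@pytest.fixture(scope="session")
def y45():
    """Vertical stem with one 45-degree branch at a known node, plus truth."""
    skel = make_y_skeleton(angle_deg=45.0, height=20.0, attach_frac=0.5, branch_length=8.0)
    cloud, truth = sample_cloud(skel, SamplingSpec())
    return cloud, truth, skel


@pytest.fixture(scope="session")
def y60():
    skel = make_y_skeleton(angle_deg=60.0, height=20.0, attach_frac=0.5, branch_length=8.0)
    cloud, truth = sample_cloud(skel, SamplingSpec())
    return cloud, truth, skel


def brute_force_match(predicted, labeled, radius):
    """Literal per-prediction / per-label matching, quadratic and obvious."""
    predicted = [np.asarray(p, float) for p in predicted]
    labeled = [np.asarray(l, float) for l in labeled]
    tp = fp = fn = 0
    for p in predicted:
        if any(float(np.linalg.norm(p - l)) < radius for l in labeled):
            tp += 1
        else:
            fp += 1
    for l in labeled:
        if not any(float(np.linalg.norm(p - l)) < radius for p in predicted):
            fn += 1
    return tp, fp, fn


def brute_force_dtw(a, b):
    """Minimal cumulative |a_i - b_j| over all monotone paths, by recursion."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        prev = []
        if i > 0:
            prev.append(go(i - 1, j))
        if j > 0:
            prev.append(go(i, j - 1))
        if i > 0 and j > 0:
            prev.append(go(i - 1, j - 1))
        return c + min(prev)

    return go(len(a) - 1, len(b) - 1)
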