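import numpy as np
import pandas as pd
import pytest

import acebounds as ab


@pytest.fixture
def toy_joint() -> ab.BinaryJoint:
    """Joint table with p11=0.3, p01=0.2, p10=0.1, p00=0.4."""
    return ab.BinaryJoint.from_probs(0.3, 0.2, 0.1, 0.4)


@pytest.fixture
def toy_sample() -> ab.ObservedSample:
    """Ten equally weighted records matching toy_joint: 3x(y=1,a=1),
    2x(y=0,a=1), 1x(y=1,a=0), 4x(y=0,a=0)."""
    a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    y = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
    return ab.ObservedSample(a=a, y=y)


@pytest.fixture
def stratified_sample() -> ab.ObservedSample:
    """Equal covariate strata with Pr(Y=1|A=1,W=0)=0.2 and
    Pr(Y=1|A=1,W=1)=0.6, so the standardized mu_1 is 0.40."""
    rows = []
    for w, p1 in ((0, 0.2), (1, 0.6)):
        k1 = int(round(10 * p1))
        rows += [(1, 1, w)] * k1 + [(1, 0, w)] * (10 - k1)
        rows += [(0, 1, w)] * 3 + [(0, 0, w)] * 7
    a, y, w = map(np.array, zip(*rows))
    return ab.ObservedSample(a=a, y=y, covariates=pd.DataFrame({"w0": w}))


@pytest.fixture
def small_cohort() -> ab.WeightedCohort:
    return ab.simulate_cohort(ab.CohortParams(n=300, seed=11))


def extreme_imputation_bounds(joint: ab.BinaryJoint):
    """Brute-force oracle: enumerate the four extreme imputations
    Pr(Y^a=1 | A != a) in {0, 1} for each arm and take min/max of psi.

    Independent of the closed-form bound formulas under test.
    """
    arm = {}
    for a in (0, 1):
        arm[a] = [joint.pr(1, a) + q * joint.pr_a(1 - a) for q in (0.0, 1.0)]
    psis = [m1 - m0 for m1 in arm[1] for m0 in arm[0]]
    return min(psis), max(psis), (min(arm[1]), max(arm[1])), (min(arm[0]), max(arm[0]))
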