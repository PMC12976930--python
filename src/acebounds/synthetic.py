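"""Synthetic data generators with known ground truth.

Two generators make every other module testable without external data:

* :func:`simulate_observational` — an observational data-generating process
  (DGP) over a binary confounder W, treatment A and outcome Y, built from
  Neyman potential outcomes so the sample carries its own ground truth:
  W ~ Bern(pw); A | W ~ Bern(expit(alpha0 + alpha1 W));
  Y^a | W ~ Bern(expit(beta0 + beta1 a + beta2 W)); Y = Y^A by causal
  consistency.  :func:`true_ace` gives the closed-form ACE and
  :func:`population_joint` the exact population table of (Y, A).
* :func:`simulate_cohort` — a weighted hypertensive SBP cohort: a
  right-skewed location-scale draw truncated below at 140 mm Hg with
  gamma-distributed survey-style weights.  This is a fixture emulating the
  *shape* of a weighted blood-pressure survey (skew, truncation,
  heterogeneous weights); it is not calibrated to any real survey.

All randomness flows through one integer seed per call via named
generators; there is no global state.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .distributions import BinaryJoint, ObservedSample, WeightedCohort

__all__ = [
    "DGPParams",
    "CohortParams",
    "simulate_observational",
    "true_ace",
    "population_joint",
    "simulate_cohort",
    "random_joint",
]


@dataclass(frozen=True)
class DGPParams:
    """Observational DGP parameters.

    ``pw`` is Pr(W=1); ``alpha`` are treatment-model log-odds coefficients
    (intercept, W effect); ``beta`` are outcome-model log-odds coefficients
    (intercept, A effect, W effect).  Defaults give a moderately confounded
    study: W raises both treatment uptake and outcome risk, and treatment
    helps (beta1 > 0 on the "good outcome" scale is left to the caller's
    interpretation of Y).
    """

    pw: float = 0.4
    alpha: tuple[float, float] = (-0.4, 1.2)
    beta: tuple[float, float, float] = (-1.0, 0.7, 0.9)
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pw <= 1.0:
            raise ValueError("pw must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.alpha) != 2 or len(self.beta) != 3:
            raise ValueError("alpha has 2 coefficients and beta has 3")


@dataclass(frozen=True)
class CohortParams:
    """Synthetic hypertensive-cohort parameters.

    SBP is ``location + Gamma(shape, scale)`` (mm Hg), right-skewed, kept
    only when at or above ``truncation_min`` (rejection sampling).  Weights
    are Gamma with unit mean and coefficient of variation
    ``weight_dispersion`` (0 means unit weights).  Defaults: location 120,
    shape 4, scale 8 — mean about 152, SD 16 before truncation, so roughly
    three quarters of draws survive a 140 cutoff.
    """

    n: int = 1000
    seed: int = 0
    location: float = 120.0
    shape: float = 4.0
    scale: float = 8.0
    truncation_min: float = 140.0
    weight_dispersion: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.truncation_min <= 0:
            raise ValueError("truncation_min must be positive")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")


def simulate_observational(p: DGPParams) -> ObservedSample:
    """Draw an observational sample with attached potential outcomes.

    Each unit's two potential outcomes share one uniform per arm
    (``Y^a = 1{U_a < Pr(Y^a=1|W)}``), which fixes a joint law for
    (Y^0, Y^1) without affecting the marginals; the empirical ACE from the
    attached potential outcomes is then stable across seeds.  The observed
    outcome is the potential outcome under the received treatment.
    """
    rng = np.random.default_rng(p.seed)
    w = (rng.uniform(size=p.n) < p.pw).astype(np.int8)
    pa = expit(p.alpha[0] + p.alpha[1] * w)
    a = (rng.uniform(size=p.n) < pa).astype(np.int8)
    u0 = rng.uniform(size=p.n)
    u1 = rng.uniform(size=p.n)
    y0 = (u0 < expit(p.beta[0] + p.beta[2] * w)).astype(np.int8)
    y1 = (u1 < expit(p.beta[0] + p.beta[1] + p.beta[2] * w)).astype(np.int8)
    y = np.where(a == 1, y1, y0).astype(np.int8)
    import pandas as pd

    return ObservedSample(
        a=a,
        y=y,
        covariates=pd.DataFrame({"w0": w}),
        context_label=f"synthetic observational DGP (seed {p.seed})",
        y0=y0,
        y1=y1,
    )


def true_ace(p: DGPParams) -> float:
    """Closed-form ACE of the DGP:
    ``sum_w [expit(b0+b1+b2 w) - expit(b0+b2 w)] Pr(W=w)``."""
    b0, b1, b2 = p.beta
    out = 0.0
    for w, pw in ((0, 1.0 - p.pw), (1, p.pw)):
        out += (expit(b0 + b1 + b2 * w) - expit(b0 + b2 * w)) * pw
    return float(out)


def population_joint(p: DGPParams) -> BinaryJoint:
    """Exact population joint table of (Y, A) implied by the DGP,
    obtained by summing over the confounder."""
    b0, b1, b2 = p.beta
    tab = np.zeros((2, 2))
    for w, pw in ((0, 1.0 - p.pw), (1, p.pw)):
        pa1 = expit(p.alpha[0] + p.alpha[1] * w)
        for a, pa in ((0, 1.0 - pa1), (1, pa1)):
            py1 = expit(b0 + b1 * a + b2 * w)
            tab[1, a] += pw * pa * py1
            tab[0, a] += pw * pa * (1.0 - py1)
    return BinaryJoint(tab)


def simulate_cohort(p: CohortParams) -> WeightedCohort:
    """Draw a weighted SBP cohort supported on ``[truncation_min, inf)``.

    Rejection-samples the shifted gamma until ``n`` draws at or above the
    cutoff are retained; raises if the acceptance probability is
    numerically zero for the chosen parameters.
    """
    rng = np.random.default_rng(p.seed)
    values = np.empty(0)
    attempts = 0
    while values.size < p.n:
        batch = p.location + rng.gamma(p.shape, p.scale, size=max(p.n, 1000))
        values = np.concatenate([values, batch[batch >= p.truncation_min]])
        attempts += 1
        if attempts >= 1000 and values.size == 0:
            raise ValueError(
                "truncation infeasible: no draws reached "
                f"{p.truncation_min} after {attempts} batches"
            )
    values = values[: p.n]
    if p.weight_dispersion == 0:
        weights = np.ones(p.n)
    else:
        k = 1.0 / p.weight_dispersion**2
        weights = rng.gamma(k, 1.0 / k, size=p.n)
    return WeightedCohort(values, weights, support_min=p.truncation_min)


def random_joint(rng: np.random.Generator) -> BinaryJoint:
    """One joint table of (Y, A) drawn flat on the probability simplex."""
    cells = rng.dirichlet(np.ones(4))
    return BinaryJoint(cells.reshape(2, 2))
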