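"""Amlodipine pharmacodynamic case study.

The scientific question: among US adults (18+) with systolic blood pressure
(SBP) of at least 140 mm Hg, what is the difference in the risk of
hypertension (SBP >= 140) 24 hours after a 10 mg dose of amlodipine versus
placebo?

The mechanistic model composes three pieces:

* ``f(b)`` — the baseline SBP distribution of the context, represented as a
  :class:`~acebounds.distributions.WeightedCohort` supported on
  ``[140, inf)``;
* ``g(theta) = theta0 * theta1`` — the effective drug concentration at
  24 h, a proportion model: dose (mg) times the fraction of active drug
  remaining (:class:`DoseParams`);
* an SBP response built on a Hill (E-max) curve (:class:`HillParams`):

      ybar(b, a, m; lambda) = b - (lambda0 + a*lambda1*m/(lambda2 + m)
                                   + a*lambda3)

  with the binary outcome ``h = 1{ybar < 140}`` — hypertension *resolved*
  at 24 h.  Note the direction: ``h = 1`` is the good outcome, so positive
  psi_bar means benefit.

The computed arm mean ``mu_bar_a`` is the cohort-weighted average of the
indicator; bounds over the parameter boxes follow by grid or corner search.
With ``lambda0 = lambda3 = 0`` (no SBP change except through the drug, and
no direct drug effect) the placebo arm mean is identically zero on any
cohort respecting the support constraint, so psi_bar reduces to mu_bar_1.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .distributions import WeightedCohort
from .mechanistic import ParameterBox, vacuousness_diagnostic, VacuousnessReport
from .statistical_id import Bounds

__all__ = [
    "HillParams",
    "DoseParams",
    "effective_concentration",
    "hill_sbp",
    "below_threshold",
    "mu_bar_pd",
    "psi_bar_pd",
    "case_study_bounds",
    "case_study_vacuousness",
    "DEFAULT_DOSE_MG",
    "HYPERTENSION_THRESHOLD",
    "THETA1_BOX",
    "LAMBDA1_BOX",
    "LAMBDA2_BOX",
]

logger = logging.getLogger(__name__)

# warn loudly only the first time a negative SBP prediction is seen
_warned_negative_sbp = False

#: Treatment dose in mg (placebo is 0 mg).
DEFAULT_DOSE_MG = 10.0
#: Hypertension cutoff in mm Hg; outcome is 1 when predicted SBP < cutoff.
HYPERTENSION_THRESHOLD = 140.0

# Literature-informed parameter ranges: fraction of active drug remaining
# at 24 h, maximum SBP response (mm Hg), and concentration at half-maximal
# response (mg).
THETA1_BOX = (0.25, 0.40)
LAMBDA1_BOX = (16.3, 36.3)
LAMBDA2_BOX = (0.1, 13.0)


@dataclass(frozen=True)
class DoseParams:
    """Effective-concentration parameters: dose (mg) and the fraction of
    active drug remaining at 24 h."""

    theta0: float = DEFAULT_DOSE_MG
    theta1: float = 0.325

    def __post_init__(self) -> None:
        if self.theta0 < 0:
            raise ValueError("dose theta0 must be nonnegative")
        if not 0.0 <= self.theta1 <= 1.0:
            raise ValueError("remaining fraction theta1 must lie in [0, 1]")


@dataclass(frozen=True)
class HillParams:
    """Hill (E-max) SBP response parameters.

    lambda0: constant SBP shift (mm Hg); lambda1: maximum response (mm Hg);
    lambda2: concentration at half-maximal response (mg, >= 0);
    lambda3: direct treatment effect not through concentration (mm Hg).
    """

    lambda0: float = 0.0
    lambda1: float = 26.3
    lambda2: float = 6.55
    lambda3: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda2 < 0:
            raise ValueError("half-maximal concentration lambda2 must be >= 0")


def effective_concentration(p: DoseParams) -> float:
    """Effective concentration at 24 h: ``theta0 * theta1`` (mg)."""
    return p.theta0 * p.theta1


def hill_sbp(b, a: int, m: float, p: HillParams):
    """Predicted SBP at 24 h from baseline ``b`` (mm Hg).

    ``b - (lambda0 + a*lambda1*m/(lambda2+m) + a*lambda3)``.  Accepts a
    scalar or array ``b``.  The prediction is deliberately not clamped at
    zero; callers are warned when it goes negative.
    """
    if m < 0:
        raise ValueError("effective concentration m must be nonnegative")
    if p.lambda2 + m == 0:
        raise ZeroDivisionError(
            "Hill response undefined: lambda2 + m = 0 (no half-max scale)"
        )
    b = np.asarray(b, dtype=float)
    drop = p.lambda0 + a * p.lambda1 * m / (p.lambda2 + m) + a * p.lambda3
    out = b - drop
    if out.ndim == 0:
        return float(out)
    return out


def below_threshold(
    b, a: int, m: float, p: HillParams, threshold: float = HYPERTENSION_THRESHOLD
):
    """Indicator that predicted SBP falls strictly below the cutoff.

    1 means hypertension resolved at 24 h.  The inequality is strict: a
    prediction exactly at the threshold counts as still hypertensive.
    """
    pred = hill_sbp(b, a, m, p)
    out = np.asarray(pred) < threshold
    if out.ndim == 0:
        return int(out)
    return out.astype(np.int8)


def mu_bar_pd(
    cohort: WeightedCohort,
    a: int,
    dose: DoseParams,
    p: HillParams,
    threshold: float = HYPERTENSION_THRESHOLD,
) -> float:
    """Computed arm mean: cohort-weighted probability of resolved
    hypertension under treatment set to ``a``.

    The placebo arm uses dose 0 mg, so its effective concentration is zero
    regardless of ``theta1``.
    """
    if a not in (0, 1):
        raise ValueError("treatment arm must be 0 or 1")
    arm_dose = DoseParams(theta0=dose.theta0 if a == 1 else 0.0, theta1=dose.theta1)
    m = effective_concentration(arm_dose)
    pred = hill_sbp(cohort.values, a, m, p)
    if np.any(np.asarray(pred) < 0):
        global _warned_negative_sbp
        level = logging.DEBUG if _warned_negative_sbp else logging.WARNING
        _warned_negative_sbp = True
        logger.log(
            level,
            "predicted SBP went negative for some cohort members; "
            "indicator computed on the raw value",
        )
    return cohort.weighted_mean(np.asarray(pred) < threshold)


def psi_bar_pd(
    cohort: WeightedCohort, dose: DoseParams, p: HillParams
) -> float:
    """Computed ACE ``mu_bar_1 - mu_bar_0`` for the case-study model."""
    return mu_bar_pd(cohort, 1, dose, p) - mu_bar_pd(cohort, 0, dose, p)


def case_study_bounds(
    cohort: WeightedCohort,
    theta1_box: tuple[float, float] = THETA1_BOX,
    lambda1_box: tuple[float, float] = LAMBDA1_BOX,
    lambda2_box: tuple[float, float] = LAMBDA2_BOX,
    resolution: int = 25,
    strategy: str = "grid",
    dose_mg: float = DEFAULT_DOSE_MG,
) -> Bounds:
    """Bounds for psi over the case-study parameter boxes.

    ``lambda0`` and ``lambda3`` are fixed at zero (no SBP change except
    through the effective concentration), which forces ``mu_bar_0 = 0`` on
    any cohort supported on ``[140, inf)``; it is still computed, not
    assumed.  psi_bar is nondecreasing in ``theta1`` and ``lambda1`` and
    nonincreasing in ``lambda2``, so ``strategy="corners"`` evaluates only
    the two extreme vertices; ``"grid"`` scans ``resolution`` points per
    free box dimension.
    """
    for name, (lo, hi) in (
        ("theta1", theta1_box),
        ("lambda1", lambda1_box),
        ("lambda2", lambda2_box),
    ):
        if lo > hi:
            raise ValueError(f"{name} box has lower > upper: [{lo}, {hi}]")
    if not (0.0 <= theta1_box[0] and theta1_box[1] <= 1.0):
        raise ValueError("theta1 box must lie within [0, 1]")
    if lambda2_box[0] < 0:
        raise ValueError("lambda2 box must be nonnegative")

    if strategy == "grid":
        if resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        axes = [
            np.linspace(lo, hi, resolution) if lo < hi else np.array([lo])
            for lo, hi in (theta1_box, lambda1_box, lambda2_box)
        ]
    elif strategy == "corners":
        # psi_bar monotone: up in theta1 and lambda1, down in lambda2.
        axes = None
    else:
        raise ValueError("strategy must be 'grid' or 'corners'")

    def _psi(t1: float, l1: float, l2: float) -> float:
        return psi_bar_pd(
            cohort,
            DoseParams(theta0=dose_mg, theta1=t1),
            HillParams(lambda0=0.0, lambda1=l1, lambda2=l2, lambda3=0.0),
        )

    if strategy == "corners":
        lo = _psi(theta1_box[0], lambda1_box[0], lambda2_box[1])
        hi = _psi(theta1_box[1], lambda1_box[1], lambda2_box[0])
        return Bounds(min(lo, hi), max(lo, hi))

    vals = [_psi(t1, l1, l2) for t1, l1, l2 in itertools.product(*axes)]
    return Bounds(min(vals), max(vals))


def case_study_vacuousness(
    cohort: WeightedCohort,
    magnitude_schedule=(50.0, 100.0, 200.0),
    tol: float = 0.01,
    seed: int = 0,
) -> VacuousnessReport:
    """Vacuousness probe for the case-study model with all lambda free.

    Searches psi_bar over ``(theta1, lambda0..lambda3)`` with entries capped
    at each scheduled magnitude (theta1 within [0, 1]; lambda2 >= 0).  The
    default schedule is larger than the generic one because driving both
    arm means to their extremes requires shifts beyond ``max(b) - 140``.
    """
    # lambda2 floor keeps the search off the undefined point lambda2 + m = 0
    # (reachable when theta1 = 0); the envelope is insensitive to it.
    space = ParameterBox.from_dict(
        {
            "theta1": (0.0, 1.0),
            "lambda0": (-np.inf, np.inf),
            "lambda1": (-np.inf, np.inf),
            "lambda2": (1e-6, np.inf),
            "lambda3": (-np.inf, np.inf),
        }
    )

    def psi_fn(vec: np.ndarray) -> float:
        t1, l0, l1, l2, l3 = vec
        return psi_bar_pd(
            cohort,
            DoseParams(theta0=DEFAULT_DOSE_MG, theta1=t1),
            HillParams(lambda0=l0, lambda1=l1, lambda2=l2, lambda3=l3),
        )

    return vacuousness_diagnostic(
        None,
        magnitude_schedule=magnitude_schedule,
        tol=tol,
        seed=seed,
        psi_fn=psi_fn,
        param_space=space,
        with_components=False,
    )
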