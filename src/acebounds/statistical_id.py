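"""Identification of the average causal effect (ACE) from observed binary data.

The target parameter is the ACE

    psi = Pr(Y^1 = 1) - Pr(Y^0 = 1)

for a binary treatment A and binary outcome Y in a fixed context, where Y^a
denotes the potential outcome under treatment set to ``a``.  By the axioms of
probability psi lies in [-1, 1]; everything here narrows that parameter space
using only causal consistency (Y = Y^A) plus whatever extra assumptions each
routine states.

Three classical results are implemented:

* **Nonparametric bounds** (:func:`arm_mean_bounds`,
  :func:`ace_nonparametric_bounds`) — worst-case imputation of the
  unobserved counterfactual arm.  The ACE bounds always have width exactly 1
  and always contain the null value 0.
* **Randomization point identification** (:func:`ace_randomized`) — under
  marginal exchangeability with positivity, psi equals the contrast of
  observed arm means.
* **The g-formula** (:func:`g_formula_estimate`) — standardization of
  stratum-specific outcome risks over the covariate distribution under
  conditional exchangeability; saturated or logistic outcome models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distributions import BinaryJoint, ObservedSample

__all__ = [
    "Bounds",
    "OutcomeModelSpec",
    "arm_mean_bounds",
    "ace_nonparametric_bounds",
    "ace_randomized",
    "g_formula_estimate",
    "PositivityError",
    "FitFailureError",
]

logger = logging.getLogger(__name__)


class PositivityError(ValueError):
    """A required treatment level is unsupported (zero weight) somewhere."""


class FitFailureError(RuntimeError):
    """An outcome-model fit did not converge."""


@dataclass(frozen=True)
class Bounds:
    """A closed interval ``[lower, upper]`` for a causal parameter, together
    with the parameter space ``[space_lower, space_upper]`` it lives in."""

    lower: float
    upper: float
    space_lower: float = -1.0
    space_upper: float = 1.0

    def __post_init__(self) -> None:
        if not (
            self.space_lower <= self.lower + 1e-12
            and self.lower <= self.upper + 1e-12
            and self.upper <= self.space_upper + 1e-12
        ):
            raise ValueError(
                f"require space_lower <= lower <= upper <= space_upper; got {self}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= x <= self.upper + tol

    def __iter__(self):
        return iter((self.lower, self.upper))


def arm_mean_bounds(joint: BinaryJoint, a: int) -> Bounds:
    """Nonparametric bounds for the arm mean ``mu_a = Pr(Y^a = 1)``.

    Decomposing mu_a by the received treatment and using causal consistency
    leaves one unknown, ``Pr(Y^a=1 | A != a)``, which is only known to lie in
    [0, 1].  Setting it to 0 and 1 gives

        mu_a in [ Pr(Y=1, A=a),  Pr(Y=1, A=a) + Pr(A != a) ].
    """
    if a not in (0, 1):
        raise ValueError("treatment arm must be 0 or 1")
    lower = joint.pr(1, a)
    return Bounds(lower, lower + joint.pr_a(1 - a), 0.0, 1.0)


def ace_nonparametric_bounds(joint: BinaryJoint) -> Bounds:
    """Nonparametric bounds for the ACE from the joint table of (Y, A).

    Differencing the per-arm bounds in opposite directions gives

        psi in [ -Pr(Y=0,A=1) - Pr(Y=1,A=0),  Pr(Y=1,A=1) + Pr(Y=0,A=0) ].

    The interval always has width exactly 1 — a halving of the [-1, 1]
    parameter space — and always contains the null psi = 0, so data on
    (Y, A) alone can never certify any effect.
    """
    lower = -joint.pr(0, 1) - joint.pr(1, 0)
    upper = joint.pr(1, 1) + joint.pr(0, 0)
    return Bounds(lower, upper)


def _arm_mean(sample: ObservedSample, a: int) -> float:
    mask = sample.a == a
    w = sample.weight[mask]
    if w.sum() <= 0:
        raise PositivityError(f"no positive-weight records with A={a}")
    return float(np.average(sample.y[mask], weights=w))


def ace_randomized(sample: ObservedSample) -> float:
    """Point estimate of the ACE under unconditional randomization.

    Randomization yields marginal exchangeability with positivity by design,
    so psi is identified by the contrast of weighted observed arm means.
    Raises :class:`PositivityError` if either arm is absent.
    """
    return _arm_mean(sample, 1) - _arm_mean(sample, 0)


@dataclass
class OutcomeModelSpec:
    """Specification of the outcome model ``m(A, W; gamma)`` for the g-formula.

    Parameters
    ----------
    kind
        ``"saturated"`` — one weighted mean of Y per observed (A, W) cell;
        requires discrete covariates.  ``"logistic"`` — logistic regression
        with main effects of A and the listed covariates, plus A-by-covariate
        products when ``treatment_interactions`` is set.
    covariates
        Covariate column names; empty means the crude (unadjusted) model.
    treatment_interactions
        Include A*W product terms in the logistic design (a fully saturated
        parameterization for a single binary W).
    """

    kind: str = "saturated"
    covariates: tuple[str, ...] = ()
    treatment_interactions: bool = False
    coefficients_: pd.Series | None = field(default=None, repr=False)
    strata_: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("saturated", "logistic"):
            raise ValueError("model kind must be 'saturated' or 'logistic'")
        self.covariates = tuple(self.covariates)


def _covariate_matrix(sample: ObservedSample, names: tuple[str, ...]) -> pd.DataFrame:
    if not names:
        return pd.DataFrame(index=range(sample.n))
    if sample.covariates is None:
        raise ValueError("model names covariates but the sample has none")
    missing = [c for c in names if c not in sample.covariates.columns]
    if missing:
        raise ValueError(f"covariates not present in sample: {missing}")
    return sample.covariates[list(names)].reset_index(drop=True)


def _saturated_predictions(
    sample: ObservedSample, model: OutcomeModelSpec, a: int
) -> np.ndarray:
    W = _covariate_matrix(sample, model.covariates)
    df = W.copy()
    df["_a"] = sample.a
    df["_y"] = sample.y
    df["_w"] = sample.weight
    keys = list(model.covariates) + ["_a"]

    grouped = df.groupby(keys, dropna=False, observed=True)
    cells = grouped.apply(
        lambda g: np.average(g["_y"], weights=g["_w"]) if g["_w"].sum() > 0 else np.nan,
        include_groups=False,
    )
    dropped = int(cells.isna().sum())
    if dropped:
        logger.warning("dropping %d zero-weight strata from standardization", dropped)
        cells = cells.dropna()
    model.strata_ = cells.rename("risk").reset_index()

    lookup = {k if isinstance(k, tuple) else (k,): v for k, v in cells.items()}
    if not model.covariates:
        if (a,) not in lookup:
            raise PositivityError(f"no positive-weight records with A={a}")
        return np.full(sample.n, lookup[(a,)])

    preds = np.empty(sample.n, dtype=float)
    for i in range(sample.n):
        key = tuple(W.iloc[i][c] for c in model.covariates) + (a,)
        if key not in lookup:
            raise PositivityError(
                f"empty stratum under the saturated model: W={key[:-1]}, A={a}"
            )
        preds[i] = lookup[key]
    return preds


def _logistic_design(
    a: np.ndarray, W: pd.DataFrame, model: OutcomeModelSpec
) -> np.ndarray:
    cols = [np.ones(a.shape[0]), a.astype(float)]
    for c in model.covariates:
        cols.append(W[c].to_numpy(float))
    if model.treatment_interactions:
        for c in model.covariates:
            cols.append(a.astype(float) * W[c].to_numpy(float))
    return np.column_stack(cols)


def _logistic_predictions(
    sample: ObservedSample, model: OutcomeModelSpec, a: int
) -> np.ndarray:
    W = _covariate_matrix(sample, model.covariates)
    if not (sample.weight[sample.a == a].sum() > 0):
        raise PositivityError(f"no positive-weight records with A={a}")
    X = _logistic_design(sample.a, W, model)
    glm = sm.GLM(
        sample.y.astype(float),
        X,
        family=sm.families.Binomial(),
        freq_weights=sample.weight,
    )
    try:
        res = glm.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # perfect separation, singular design, ...
        raise FitFailureError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise FitFailureError("logistic fit did not converge in 100 iterations")
    names = (
        ["const", "a"]
        + list(model.covariates)
        + ([f"a:{c}" for c in model.covariates] if model.treatment_interactions else [])
    )
    model.coefficients_ = pd.Series(res.params, index=names)
    X_set = _logistic_design(np.full(sample.n, a), W, model)
    return np.asarray(res.predict(X_set))


def g_formula_estimate(
    sample: ObservedSample, model: OutcomeModelSpec, a: int
) -> float:
    """Parametric g-formula (standardization) estimate of ``mu_a``.

    Fits the outcome model m(A, W; gamma) on the observed data, predicts
    m(a, W_i; gamma_hat) for every record with treatment set to ``a``, and
    returns the sampling-weighted mean of the predictions.  Under conditional
    exchangeability given W, positivity and correct model specification this
    estimates Pr(Y^a = 1).
    """
    if a not in (0, 1):
        raise ValueError("treatment arm must be 0 or 1")
    if model.kind == "saturated":
        preds = _saturated_predictions(sample, model, a)
    else:
        preds = _logistic_predictions(sample, model, a)
    return float(np.average(preds, weights=sample.weight))
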