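"""Mechanistic (mathematical) models for a binary mediator mechanism
A -> M -> Y, and bound propagation over parameter boxes.

A mechanistic model here needs no data.  It is two component functions:

* a mediator law ``g(a; theta)`` — the probability that the mediator M
  (e.g. an immune response) occurs under treatment set to ``a``;
* an outcome law ``h(a, m; lambda)`` — the probability of the outcome Y
  given treatment ``a`` and mediator value ``m``.

Treatment is set deterministically under intervention (Pr(A=a) := 1), so
the computed arm mean marginalizes the mediator only:

    mu_bar_a(theta, lambda) = h(a,1;lambda) g(a;theta)
                              + h(a,0;lambda) (1 - g(a;theta))

and the computed average causal effect is
``psi_bar = mu_bar_1 - mu_bar_0``.

Given ranges Theta*, Lambda* for the parameters (a *parameter box*), the
model-capture assumption — that the true mechanism probabilities lie in the
image of the component functions over those ranges — turns the model into a
partial identification result:

    psi in [ min psi_bar,  max psi_bar ]  over Theta* x Lambda*.

:func:`bounds_over_box` computes that interval by grid search, or exactly by
corner evaluation when every free parameter carries a declared direction of
monotonicity of psi_bar.

A model is *vacuous* when the achievable psi_bar values (with closure
points) span the whole parameter space [-1, 1]: the functions then impose
no structural assumption, and all structure lives in the parameter ranges.
:func:`vacuousness_diagnostic` probes this numerically.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .statistical_id import Bounds

__all__ = [
    "ParameterBox",
    "MechanisticModel",
    "logistic_example_model",
    "mu_bar",
    "psi_bar",
    "bounds_over_box",
    "vacuousness_diagnostic",
    "VacuousnessReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterBox:
    """Named parameters, each with a closed interval of admissible values.

    A degenerate entry (lower == upper) encodes a fixed parameter choice;
    infinite endpoints declare an unbounded parameter space (allowed for
    declared spaces, not for search boxes).
    """

    names: tuple[str, ...]
    lowers: np.ndarray
    uppers: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.names)
        lowers = np.asarray(self.lowers, dtype=float)
        uppers = np.asarray(self.uppers, dtype=float)
        if len(names) != len(set(names)):
            raise ValueError("parameter names must be unique")
        if lowers.shape != (len(names),) or uppers.shape != (len(names),):
            raise ValueError("lowers/uppers must have one entry per name")
        if (lowers > uppers).any():
            raise ValueError("each entry requires lower <= upper")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lowers", lowers)
        object.__setattr__(self, "uppers", uppers)

    @classmethod
    def from_dict(cls, entries: dict[str, tuple[float, float] | float]) -> "ParameterBox":
        """Build from ``{name: (lower, upper)}``; a bare number fixes the
        parameter (degenerate interval)."""
        names, lo, hi = [], [], []
        for name, v in entries.items():
            names.append(name)
            if np.isscalar(v):
                lo.append(float(v))
                hi.append(float(v))
            else:
                lo.append(float(v[0]))
                hi.append(float(v[1]))
        return cls(tuple(names), np.array(lo), np.array(hi))

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def free(self) -> np.ndarray:
        """Boolean mask of non-degenerate (searchable) entries."""
        return self.lowers < self.uppers

    def contains(self, vec: Sequence[float], tol: float = 1e-9) -> bool:
        v = np.asarray(vec, dtype=float)
        return bool(
            (v >= self.lowers - tol).all() and (v <= self.uppers + tol).all()
        )

    def require_within(self, outer: "ParameterBox") -> None:
        """Check this box nests inside a declared space ``outer`` by name."""
        pos = {n: i for i, n in enumerate(outer.names)}
        for i, n in enumerate(self.names):
            if n not in pos:
                raise ValueError(f"unknown parameter {n!r}")
            j = pos[n]
            if self.lowers[i] < outer.lowers[j] or self.uppers[i] > outer.uppers[j]:
                raise ValueError(
                    f"box entry {n!r} [{self.lowers[i]}, {self.uppers[i]}] exceeds "
                    f"the declared space [{outer.lowers[j]}, {outer.uppers[j]}]"
                )


_UNBOUNDED = (-np.inf, np.inf)


@dataclass
class MechanisticModel:
    """A two-function mechanism for a binary mediator.

    Parameters
    ----------
    mediator_law
        ``g(a, theta) -> Pr(M=1 | set A=a)``, a probability.
    outcome_law
        ``h(a, m, lam) -> Pr(Y=1 | set A=a, M=m)``, a probability.
    theta_space, lambda_space
        Declared parameter spaces (may have infinite endpoints).
    monotonicity
        Optional map ``name -> "increasing" | "decreasing"`` giving the
        direction in which psi_bar moves as the named parameter grows;
        parameters not listed are treated as direction-unknown.
    """

    mediator_law: Callable[[int, np.ndarray], float]
    outcome_law: Callable[[int, int, np.ndarray], float]
    theta_space: ParameterBox
    lambda_space: ParameterBox
    monotonicity: dict[str, str] = field(default_factory=dict)
    name: str = "mechanistic-model"

    def __post_init__(self) -> None:
        for v in self.monotonicity.values():
            if v not in ("increasing", "decreasing"):
                raise ValueError("monotonicity must be 'increasing' or 'decreasing'")

    def g(self, a: int, theta) -> float:
        val = float(self.mediator_law(a, np.asarray(theta, dtype=float)))
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"mediator law returned {val}, outside [0, 1]")
        return val

    def h(self, a: int, m: int, lam) -> float:
        val = float(self.outcome_law(a, m, np.asarray(lam, dtype=float)))
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"outcome law returned {val}, outside [0, 1]")
        return val


def logistic_example_model() -> MechanisticModel:
    """The logistic mediator/outcome example:

    ``g(a; theta) = expit(theta0 + theta1 a)`` and
    ``h(a, m; lambda) = expit(lambda0 + lambda1 a + lambda2 m + lambda3 a m)``,
    with all parameters unbounded.  Both component images cover (0, 1), so
    the model is vacuous: structural assumptions (e.g. "A has no direct
    effect on Y") are encoded by fixing parameters (lambda1 = lambda3 = 0),
    never by the functional form.
    """
    return MechanisticModel(
        mediator_law=lambda a, th: expit(th[0] + th[1] * a),
        outcome_law=lambda a, m, la: expit(la[0] + la[1] * a + la[2] * m + la[3] * a * m),
        theta_space=ParameterBox.from_dict(
            {"theta0": _UNBOUNDED, "theta1": _UNBOUNDED}
        ),
        lambda_space=ParameterBox.from_dict(
            {
                "lambda0": _UNBOUNDED,
                "lambda1": _UNBOUNDED,
                "lambda2": _UNBOUNDED,
                "lambda3": _UNBOUNDED,
            }
        ),
        name="logistic-mediator",
    )


def mu_bar(model: MechanisticModel, a: int, theta, lam) -> float:
    """Computed arm mean ``mu_bar_a(theta, lambda)``.

    Marginalizes the binary mediator with its probability mass
    ``g^m (1-g)^(1-m)``:
    ``h(a,1)g + h(a,0)(1-g)``.  Always in [0, 1] for valid components.
    """
    if a not in (0, 1):
        raise ValueError("treatment arm must be 0 or 1")
    g = model.g(a, theta)
    return model.h(a, 1, lam) * g + model.h(a, 0, lam) * (1.0 - g)


def psi_bar(model: MechanisticModel, theta, lam) -> float:
    """Computed ACE ``psi_bar = mu_bar_1 - mu_bar_0``; always in [-1, 1]."""
    return mu_bar(model, 1, theta, lam) - mu_bar(model, 0, theta, lam)


def _split(model: MechanisticModel, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    j = model.theta_space.k
    return vec[:j], vec[j:]


def _joint_box(theta_box: ParameterBox, lambda_box: ParameterBox) -> ParameterBox:
    return ParameterBox(
        theta_box.names + lambda_box.names,
        np.concatenate([theta_box.lowers, lambda_box.lowers]),
        np.concatenate([theta_box.uppers, lambda_box.uppers]),
    )


def bounds_over_box(
    model: MechanisticModel,
    theta_box: ParameterBox,
    lambda_box: ParameterBox,
    strategy: str = "grid",
    resolution: int = 25,
) -> Bounds:
    """Propagate parameter boxes into bounds for psi.

    Under the model-capture assumption (the true mechanism probabilities lie
    in the component-function images over the boxes), psi lies between the
    minimum and maximum of psi_bar over the box.

    ``strategy="grid"`` evaluates a full product grid with ``resolution``
    points per free dimension (endpoints included).  ``strategy="corners"``
    evaluates only the 2^k box vertices, which is exact when every free
    parameter carries a declared monotonicity direction; it raises otherwise.
    """
    if theta_box.names != model.theta_space.names:
        raise ValueError("theta_box must name exactly the model's theta parameters")
    if lambda_box.names != model.lambda_space.names:
        raise ValueError("lambda_box must name exactly the model's lambda parameters")
    theta_box.require_within(model.theta_space)
    lambda_box.require_within(model.lambda_space)
    box = _joint_box(theta_box, lambda_box)

    if strategy == "grid":
        if resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        axes = [
            np.linspace(lo, hi, resolution) if lo < hi else np.array([lo])
            for lo, hi in zip(box.lowers, box.uppers)
        ]
    elif strategy == "corners":
        undeclared = [
            n
            for n, free in zip(box.names, box.free)
            if free and n not in model.monotonicity
        ]
        if undeclared:
            raise ValueError(
                "corners strategy needs a declared monotonicity for every free "
                f"parameter; missing: {undeclared}"
            )
        axes = [
            np.array([lo, hi]) if lo < hi else np.array([lo])
            for lo, hi in zip(box.lowers, box.uppers)
        ]
    else:
        raise ValueError("strategy must be 'grid' or 'corners'")

    lo = np.inf
    hi = -np.inf
    for point in itertools.product(*axes):
        theta, lam = _split(model, np.asarray(point))
        val = psi_bar(model, theta, lam)
        lo = min(lo, val)
        hi = max(hi, val)
    return Bounds(lo, hi)


# ---------------------------------------------------------------------------
# Vacuousness diagnostic


@dataclass(frozen=True)
class VacuousnessReport:
    """Result of the numerical vacuousness probe.

    ``verdict`` is ``"vacuous-compatible"`` when the achieved psi_bar
    envelope reaches within ``tol`` of both -1 and +1 at the largest probed
    magnitude, else ``"non-vacuous-evidence"``.  The probe is evidence, not
    proof: set equality of the achievable outputs with [-1, 1] is not
    decidable by finite search.
    """

    achieved_min: float
    achieved_max: float
    verdict: str
    tol: float
    per_magnitude: tuple[tuple[float, float, float], ...]  # (mag, min, max)
    component_envelopes: dict | None = None


def _candidate_lattice(lowers: np.ndarray, uppers: np.ndarray) -> np.ndarray | None:
    """5-level lattice per dimension: endpoints, midpoints toward zero, and
    zero where admissible.  Captures e.g. expit saturation points that pure
    corner search misses."""
    axes = []
    for lo, hi in zip(lowers, uppers):
        levels = {lo, hi, lo / 2.0, hi / 2.0}
        if lo <= 0.0 <= hi:
            levels.add(0.0)
        axes.append(sorted(levels))
    n_points = int(np.prod([len(ax) for ax in axes]))
    if n_points > 100_000:
        return None
    return np.array(list(itertools.product(*axes)))


def _search_extremes(
    fn: Callable[[np.ndarray], float],
    lowers: np.ndarray,
    uppers: np.ndarray,
    rng: np.random.Generator,
    n_random: int = 256,
) -> tuple[float, float]:
    """Min/max of ``fn`` over a box: lattice + random scan, then local polish."""
    cand = _candidate_lattice(lowers, uppers)
    pts = rng.uniform(lowers, uppers, size=(n_random, len(lowers)))
    if cand is not None:
        pts = np.vstack([cand, pts])
    vals = np.array([fn(p) for p in pts])
    bnds = list(zip(lowers, uppers))

    def _polish(idx: int, sign: float) -> float:
        try:
            res = minimize(
                lambda v: sign * fn(v), pts[idx], method="L-BFGS-B", bounds=bnds
            )
            return sign * res.fun
        except Exception:  # pragma: no cover - numerical failure is nonfatal
            logger.warning("polish step failed; keeping scanned value")
            return vals[idx]

    lo = min(vals.min(), _polish(int(vals.argmin()), 1.0))
    hi = max(vals.max(), _polish(int(vals.argmax()), -1.0))
    return float(lo), float(hi)


def vacuousness_diagnostic(
    model: MechanisticModel,
    magnitude_schedule: Sequence[float] = (10.0, 20.0, 40.0),
    tol: float = 0.01,
    seed: int = 0,
    psi_fn: Callable[[np.ndarray], float] | None = None,
    param_space: ParameterBox | None = None,
    with_components: bool = True,
) -> VacuousnessReport:
    """Numerically probe whether a mechanistic model is vacuous.

    For each magnitude ``c`` in the schedule, searches psi_bar over
    parameter vectors with every entry bounded by ``c`` in absolute value
    (intersected with the declared parameter spaces), and records the
    achieved envelope.  The verdict compares the envelope at the largest
    magnitude against [-1 + tol, 1 - tol].

    ``psi_fn``/``param_space`` override the default binary-mediator
    computation, letting other model families (e.g. the pharmacodynamic
    case study) reuse the same probe.
    """
    if psi_fn is None:
        space = _joint_box(model.theta_space, model.lambda_space)

        def psi_fn(vec: np.ndarray) -> float:
            theta, lam = _split(model, vec)
            return psi_bar(model, theta, lam)

    else:
        if param_space is None:
            raise ValueError("param_space is required with a custom psi_fn")
        space = param_space

    rng = np.random.default_rng(seed)
    per_mag = []
    achieved_min, achieved_max = np.inf, -np.inf
    for c in sorted(magnitude_schedule):
        lowers = np.maximum(space.lowers, -c)
        uppers = np.minimum(space.uppers, c)
        if (lowers > uppers).any():
            logger.warning("magnitude %g incompatible with the space; skipped", c)
            continue
        try:
            lo, hi = _search_extremes(psi_fn, lowers, uppers, rng)
        except Exception:
            logger.warning("search failed at magnitude %g; skipped", c)
            continue
        achieved_min = min(achieved_min, lo)
        achieved_max = max(achieved_max, hi)
        per_mag.append((float(c), lo, hi))

    verdict = (
        "vacuous-compatible"
        if achieved_min <= -1.0 + tol and achieved_max >= 1.0 - tol
        else "non-vacuous-evidence"
    )

    comp = None
    if with_components and per_mag and psi_fn is not None and model is not None:
        c = per_mag[-1][0]
        comp = {}
        try:
            tl = np.maximum(model.theta_space.lowers, -c)
            tu = np.minimum(model.theta_space.uppers, c)
            ll = np.maximum(model.lambda_space.lowers, -c)
            lu = np.minimum(model.lambda_space.uppers, c)
            for a in (0, 1):
                comp[f"g(a={a})"] = _search_extremes(
                    lambda th, _a=a: model.g(_a, th), tl, tu, rng
                )
                for m in (0, 1):
                    comp[f"h(a={a},m={m})"] = _search_extremes(
                        lambda la, _a=a, _m=m: model.h(_a, _m, la), ll, lu, rng
                    )
        except Exception:  # custom psi_fn models may lack components
            comp = None

    return VacuousnessReport(
        achieved_min=float(achieved_min),
        achieved_max=float(achieved_max),
        verdict=verdict,
        tol=tol,
        per_magnitude=tuple(per_mag),
        component_envelopes=comp,
    )
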