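"""Data containers and I/O for observed samples, joint probability tables,
and weighted baseline cohorts.

The containers here are the common currency of the identification modules:

* :class:`ObservedSample` — unit records of a binary treatment ``a``, a
  binary outcome ``y``, optional baseline covariates and a nonnegative
  sampling weight.  The ``context_label`` carries a free-text reminder of
  the population the sample represents.
* :class:`BinaryJoint` — the joint probability table ``Pr(Y=y, A=a)`` over
  the four cells of a binary treatment/outcome pair, the only input the
  nonparametric bound formulas need.
* :class:`WeightedCohort` — a weighted empirical distribution of baseline
  systolic blood pressure (SBP) values with a hard lower support bound,
  the input to the pharmacodynamic case study.

Weights are carried unnormalized throughout and normalized only when an
average is taken, so repeated construction never compounds rounding.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObservedSample",
    "BinaryJoint",
    "WeightedCohort",
    "joint_from_sample",
    "build_cohort",
    "EmptyContextError",
]


class EmptyContextError(ValueError):
    """Raised when an operation is asked to summarize an empty population
    (no records, or no records with positive weight)."""


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1); got values outside {{0,1}}")
    return arr.astype(np.int8)


@dataclass
class ObservedSample:
    """Unit records ``(A_i, Y_i, W_i, weight_i)`` from one context.

    Parameters
    ----------
    a, y
        Binary treatment and outcome indicators, one per record.
    covariates
        Optional DataFrame of baseline covariates (columns ``w0..wk``).
    weight
        Nonnegative sampling weights; ``None`` means unit weights.
    context_label
        Free-text provenance of the sampled population.
    y0, y1
        Optional potential-outcome vectors.  Only synthetic data carries
        these; they are never written to CSV and never consulted by the
        identification routines.
    """

    a: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame | None = None
    weight: np.ndarray | None = None
    context_label: str = ""
    y0: np.ndarray | None = field(default=None, repr=False)
    y1: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.a = _as_binary(self.a, "a")
        self.y = _as_binary(self.y, "y")
        if self.a.shape != self.y.shape or self.a.ndim != 1:
            raise ValueError("a and y must be 1-d arrays of equal length")
        if self.weight is None:
            self.weight = np.ones(self.a.shape, dtype=float)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        if self.weight.shape != self.a.shape:
            raise ValueError("weight must match the number of records")
        if (self.weight < 0).any():
            raise ValueError("sampling weights must be nonnegative")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != self.n:
                raise ValueError("covariates must have one row per record")
        if self.n == 0 or self.weight.sum() <= 0:
            raise EmptyContextError(
                "sample must contain at least one record with positive weight"
            )

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())

    # -- CSV round trip ---------------------------------------------------
    # Dialect: comma-separated, header row "a,y,weight,w0..wk"; a missing
    # weight column means unit weights.

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"a": self.a, "y": self.y, "weight": self.weight})
        if self.covariates is not None:
            for col in self.covariates.columns:
                df[col] = self.covariates[col].to_numpy()
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, context_label: str = "") -> "ObservedSample":
        df = pd.read_csv(path)
        if "a" not in df.columns or "y" not in df.columns:
            raise ValueError("sample CSV must contain columns 'a' and 'y'")
        weight = df["weight"].to_numpy(float) if "weight" in df.columns else None
        cov_cols = [c for c in df.columns if c not in ("a", "y", "weight")]
        covariates = df[cov_cols] if cov_cols else None
        return cls(
            a=df["a"].to_numpy(),
            y=df["y"].to_numpy(),
            covariates=covariates,
            weight=weight,
            context_label=context_label,
        )


@dataclass(frozen=True)
class BinaryJoint:
    """Joint probability table ``p[y][a] = Pr(Y=y, A=a)``.

    Cells are nonnegative and sum to one (checked to 1e-12).
    """

    p: np.ndarray  # shape (2, 2), indexed [y, a]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (2, 2):
            raise ValueError("joint table must be 2x2, indexed [y, a]")
        if (p < 0).any():
            raise ValueError("joint probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"joint probabilities must sum to 1; got {p.sum()!r}")
        object.__setattr__(self, "p", p)

    @classmethod
    def from_probs(cls, p11: float, p01: float, p10: float, p00: float) -> "BinaryJoint":
        """Build from the four cells ``p_{ya} = Pr(Y=y, A=a)``."""
        return cls(np.array([[p00, p01], [p10, p11]], dtype=float))

    def pr(self, y: int, a: int) -> float:
        """``Pr(Y=y, A=a)``."""
        return float(self.p[y, a])

    def pr_a(self, a: int) -> float:
        """Marginal ``Pr(A=a)``."""
        return float(self.p[:, a].sum())


@dataclass
class WeightedCohort:
    """Weighted empirical distribution of baseline SBP values (mm Hg)
    supported on ``[support_min, inf)``."""

    values: np.ndarray
    weights: np.ndarray
    support_min: float = 140.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.ndim != 1 or self.values.shape != self.weights.shape:
            raise ValueError("values and weights must be 1-d arrays of equal length")
        if (self.weights < 0).any():
            raise ValueError("cohort weights must be nonnegative")
        if self.values.size == 0 or self.weights.sum() <= 0:
            raise EmptyContextError("cohort has no positive-weight records")
        if (self.values < self.support_min).any():
            raise ValueError(
                f"all SBP values must be >= support_min ({self.support_min})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def weighted_mean(self, x) -> float:
        """Weight-normalized mean of a per-record quantity ``x``."""
        x = np.asarray(x, dtype=float)
        return float(np.average(x, weights=self.weights))

    def to_csv(self, path) -> None:
        pd.DataFrame({"sbp": self.values, "weight": self.weights}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, support_min: float = 140.0) -> "WeightedCohort":
        df = pd.read_csv(path)
        if "sbp" not in df.columns:
            raise ValueError("cohort CSV must contain column 'sbp'")
        weights = (
            df["weight"].to_numpy(float)
            if "weight" in df.columns
            else np.ones(len(df))
        )
        return build_cohort(df["sbp"].to_numpy(float), weights, support_min)


def joint_from_sample(sample: ObservedSample) -> BinaryJoint:
    """Weighted empirical joint table of (Y, A) from an observed sample.

    Cell ``(y, a)`` is the weighted proportion of records with ``Y=y, A=a``;
    cells sum to one by construction.
    """
    p = np.zeros((2, 2))
    for y in (0, 1):
        for a in (0, 1):
            mask = (sample.y == y) & (sample.a == a)
            p[y, a] = sample.weight[mask].sum()
    return BinaryJoint(p / sample.total_weight)


def build_cohort(values, weights, support_min: float = 140.0) -> WeightedCohort:
    """Build a weighted SBP cohort, dropping records below the support bound.

    The support constraint is the strict exclusion ``value < support_min``:
    a record exactly at the bound is retained.  Weights of the surviving
    records are kept unnormalized.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    keep = values >= support_min
    if not keep.any() or weights[keep].sum() <= 0:
        raise EmptyContextError(
            f"no records at or above the support bound {support_min}"
        )
    return WeightedCohort(values[keep], weights[keep], support_min=support_min)
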