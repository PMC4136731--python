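"""Bounded logistic structure-function models.

Visual-field sensitivity (VFS, dB) saturates when the ganglion cell complex
(GCC) is thick, collapses steeply once thickness falls below a threshold,
and is floor/ceiling-limited by the perimeter — a sigmoid, not a
polynomial.  Two bounded logistic forms capture this:

multiple model (GCC thickness x1, age x2, sex x3, spherical equivalent x4):

    VFS = theta1 / (1 + exp(b0 + b1*x1 + b2*x2 + b3*x3 + b4*x4))

simple model (GCC thickness only):

    VFS = theta1 / (1 + exp(-theta3 * (gcc - theta2)))

theta1 is the asymptotic maximum sensitivity (dB), theta2 the thickness at
which VFS has fallen to theta1/2 (µm), and theta3 the steepness of the
transition (per µm).  With b2 = b3 = b4 = 0 the multiple model reduces to
the simple one under theta2 = -b0/b1, theta3 = -b1.

Comparator families from the structure-function literature (linear,
quadratic, cubic, broken-stick plateau) are provided for R² comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "CovariateVector",
    "MultipleLogisticParams",
    "SimpleLogisticParams",
    "ComparatorSpec",
    "COMPARATOR_FAMILIES",
    "predict_vfs_multiple",
    "predict_vfs_simple",
    "predict_comparator",
]

# Exponent clip bound: exp(±700) is the edge of double range; clipping
# there leaves every representable prediction unchanged.
_EXP_CLIP = 700.0

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class CovariateVector:
    """One eye's explanatory variables.

    gcc_um: GCC thickness (µm); age_years: age; sex: 0 = male, 1 = female;
    se_diopters: spherical equivalent (negative = myopia).
    """

    gcc_um: float
    age_years: float
    sex: int
    se_diopters: float

    def __post_init__(self) -> None:
        if self.gcc_um <= 0:
            raise ValueError("gcc_um must be positive")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (male) or 1 (female)")


@dataclass(frozen=True)
class MultipleLogisticParams:
    theta1: float
    b0: float
    b1: float
    b2: float
    b3: float
    b4: float

    def __post_init__(self) -> None:
        if self.theta1 <= 0:
            raise ValueError("theta1 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta1, self.b0, self.b1, self.b2, self.b3, self.b4]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "MultipleLogisticParams":
        return cls(*map(float, a))


@dataclass(frozen=True)
class SimpleLogisticParams:
    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        if self.theta1 <= 0:
            raise ValueError("theta1 must be positive")
        if self.theta3 <= 0:
            raise ValueError("theta3 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "SimpleLogisticParams":
        return cls(*map(float, a))


COMPARATOR_FAMILIES = ("linear", "poly2", "poly3", "broken_stick_plateau")


@dataclass(frozen=True)
class ComparatorSpec:
    """A comparator model: ``linear`` (a + b·gcc), ``poly2``/``poly3``
    (ascending coefficients), or ``broken_stick_plateau`` (0 below a
    thickness floor, linear above; coefficients = (floor, slope))."""

    family: str
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in COMPARATOR_FAMILIES:
            raise ValueError(
                f"unknown comparator family {self.family!r}; "
                f"expected one of {COMPARATOR_FAMILIES}"
            )


def _sigmoid_of(linear_predictor: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(linear_predictor, -_EXP_CLIP, _EXP_CLIP)))


def predict_vfs_multiple(
    params: MultipleLogisticParams,
    gcc_um: ArrayLike,
    age_years: ArrayLike,
    sex: ArrayLike,
    se_diopters: ArrayLike,
) -> np.ndarray | float:
    """Predicted mean VFS (dB) from the multiple logistic model.

    Output lies strictly in (0, theta1); with the usual b1 < 0 it rises
    sigmoidally with GCC thickness.  Accepts scalars or arrays
    (broadcast together).
    """
    gcc, age, sx, se = np.broadcast_arrays(
        *map(np.asarray, (gcc_um, age_years, sex, se_diopters))
    )
    lp = (
        params.b0
        + params.b1 * gcc
        + params.b2 * age
        + params.b3 * sx
        + params.b4 * se
    )
    out = params.theta1 * _sigmoid_of(lp)
    return float(out) if out.ndim == 0 else out


def predict_vfs_from_covariates(
    params: MultipleLogisticParams, cov: CovariateVector
) -> float:
    return float(
        predict_vfs_multiple(
            params, cov.gcc_um, cov.age_years, cov.sex, cov.se_diopters
        )
    )


def predict_vfs_simple(
    params: SimpleLogisticParams, gcc_um: ArrayLike
) -> np.ndarray | float:
    """Predicted mean VFS (dB) from the single-covariate logistic model.

    Strictly increasing in GCC thickness; equals theta1/2 at
    gcc = theta2 and approaches theta1 for thick GCC.
    """
    gcc = np.asarray(gcc_um, dtype=float)
    out = params.theta1 * _sigmoid_of(-params.theta3 * (gcc - params.theta2))
    return float(out) if out.ndim == 0 else out


def predict_comparator(
    spec: ComparatorSpec, gcc_um: ArrayLike
) -> np.ndarray | float:
    gcc = np.asarray(gcc_um, dtype=float)
    c = spec.coefficients
    if spec.family == "linear":
        out = c[0] + c[1] * gcc
    elif spec.family in ("poly2", "poly3"):
        out = np.polynomial.polynomial.polyval(gcc, c)
    else:  # broken_stick_plateau: continuous two-piece, 0 below the floor
        floor, slope = c[0], c[1]
        out = np.where(gcc <= floor, 0.0, slope * (gcc - floor))
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out
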