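"""Nonlinear least-squares fitting of the structure-function models.

Both logistic models (and the comparator families) are fit by the
Gauss-Newton method with analytic Jacobians.  Pure Gauss-Newton is the
default; if a step increases the residual sum of squares the solver
falls back to Levenberg-Marquardt damping with an adaptive factor, so
accepted iterations never increase the SSE.  Asymptotic standard errors
come from sigma^2 (J'J)^-1 with sigma^2 = SSE/(n-p), and per-parameter
Wald p-values from the t distribution with n-p degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ComparatorSpec,
    MultipleLogisticParams,
    SimpleLogisticParams,
    predict_vfs_multiple,
    predict_vfs_simple,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "NonIdentifiableError",
    "SingularJacobianError",
    "ResidualModel",
    "MultipleLogisticData",
    "SimpleLogisticData",
    "ComparatorData",
    "default_init",
    "gauss_newton_solve",
    "fit_area_model",
    "wald_inference",
    "MODEL_KINDS",
]

MODEL_KINDS = ("multiple", "simple", "linear", "poly2", "poly3", "plateau")

_EXP_CLIP = 700.0


class NonIdentifiableError(ValueError):
    """The data cannot identify the model parameters."""


class SingularJacobianError(np.linalg.LinAlgError):
    """The normal equations are numerically singular."""


@dataclass(frozen=True)
class FitOptions:
    """Solver controls.

    ``init`` is a starting vector or ``"auto"`` (data-driven start);
    ``tol`` is the relative-SSE-change convergence threshold;
    ``damping`` is the initial Levenberg-Marquardt factor (0 = pure
    Gauss-Newton); ``seed`` seeds the multi-start fallback only.
    """

    init: Sequence[float] | str = "auto"
    tol: float = 1e-10
    max_iter: int = 200
    damping: float = 0.0
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")


@dataclass
class FitResult:
    """Estimates and inference for one fitted model."""

    params: np.ndarray
    param_names: tuple[str, ...]
    residuals: np.ndarray
    fitted: np.ndarray
    sse: float
    covariance: Optional[np.ndarray]
    std_errors: Optional[np.ndarray]
    p_values: Optional[np.ndarray]
    converged: bool
    n_iter: int
    n_obs: int
    model_kind: str = ""
    area: str = ""

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "area": self.area,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "sse": float(self.sse),
            "estimates": {
                name: float(v) for name, v in zip(self.param_names, self.params)
            },
            "std_errors": None
            if self.std_errors is None
            else {
                name: float(v)
                for name, v in zip(self.param_names, self.std_errors)
            },
            "p_values": None
            if self.p_values is None
            else {
                name: float(v)
                for name, v in zip(self.param_names, self.p_values)
            },
        }


class ResidualModel(Protocol):
    """A model exposing observations, predictions and an analytic
    Jacobian of the predictions with respect to the parameters."""

    observed: np.ndarray
    param_names: tuple[str, ...]

    def predict(self, params: np.ndarray) -> np.ndarray: ...

    def jacobian(self, params: np.ndarray) -> np.ndarray: ...


def _sigmoid(lp: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(lp, -_EXP_CLIP, _EXP_CLIP)))


@dataclass
class MultipleLogisticData:
    """(covariates, mean VFS) data bound to the multiple logistic model."""

    gcc: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    se: np.ndarray
    observed: np.ndarray
    param_names: tuple[str, ...] = ("theta1", "b0", "b1", "b2", "b3", "b4")

    def predict(self, params: np.ndarray) -> np.ndarray:
        theta1, b0, b1, b2, b3, b4 = params
        lp = b0 + b1 * self.gcc + b2 * self.age + b3 * self.sex + b4 * self.se
        return theta1 * _sigmoid(lp)

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        theta1, b0, b1, b2, b3, b4 = params
        lp = b0 + b1 * self.gcc + b2 * self.age + b3 * self.sex + b4 * self.se
        s = _sigmoid(lp)
        d_lp = -theta1 * s * (1.0 - s)  # d f / d (linear predictor)
        ones = np.ones_like(self.gcc)
        return np.column_stack(
            [s, d_lp * ones, d_lp * self.gcc, d_lp * self.age,
             d_lp * self.sex, d_lp * self.se]
        )


@dataclass
class SimpleLogisticData:
    """(GCC thickness, mean VFS) data bound to the simple logistic model."""

    gcc: np.ndarray
    observed: np.ndarray
    param_names: tuple[str, ...] = ("theta1", "theta2", "theta3")

    def predict(self, params: np.ndarray) -> np.ndarray:
        theta1, theta2, theta3 = params
        return theta1 * _sigmoid(-theta3 * (self.gcc - theta2))

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        theta1, theta2, theta3 = params
        s = _sigmoid(-theta3 * (self.gcc - theta2))
        core = theta1 * s * (1.0 - s)
        return np.column_stack(
            [s, -theta3 * core, (self.gcc - theta2) * core]
        )


@dataclass
class ComparatorData:
    """GCC-only data bound to a comparator family."""

    gcc: np.ndarray
    observed: np.ndarray
    family: str = "linear"

    @property
    def param_names(self) -> tuple[str, ...]:
        return {
            "linear": ("a", "b"),
            "poly2": ("c0", "c1", "c2"),
            "poly3": ("c0", "c1", "c2", "c3"),
            "broken_stick_plateau": ("floor", "slope"),
        }[self.family]

    def predict(self, params: np.ndarray) -> np.ndarray:
        from .models import predict_comparator

        return np.asarray(
            predict_comparator(
                ComparatorSpec(self.family, tuple(params)), self.gcc
            )
        )

    def jacobian(self, params: np.ndarray) -> np.ndarray:
        g = self.gcc
        if self.family == "linear":
            return np.column_stack([np.ones_like(g), g])
        if self.family in ("poly2", "poly3"):
            order = len(params) - 1
            return np.column_stack([g**k for k in range(order + 1)])
        floor, slope = params
        above = (g > floor).astype(float)
        return np.column_stack([-slope * above, (g - floor) * above])


def default_init(model: ResidualModel) -> np.ndarray:
    """Data-driven starting values.

    theta1 starts at the maximum observed VFS.  For the simple model
    theta2 starts at the median GCC thickness and theta3 at 0.1/µm; for
    the multiple model b0 and b1 come from a least-squares fit of the
    logit-linearised response on GCC thickness, with b2 = b3 = b4 = 0.
    Comparator families start from an ordinary linear least-squares seed.
    """
    y = np.asarray(model.observed, dtype=float)
    if y.size == 0:
        raise NonIdentifiableError("empty dataset")
    if np.ptp(y) == 0:
        raise NonIdentifiableError(
            "constant response: model parameters are not identifiable"
        )
    theta1 = float(np.max(y))
    if isinstance(model, SimpleLogisticData):
        return np.array([theta1, float(np.median(model.gcc)), 0.1])
    if isinstance(model, MultipleLogisticData):
        # Logit-linearised seed: log(theta1/y - 1) ~ b0 + b1 * gcc.
        frac = np.clip(y / (theta1 * 1.02), 1e-3, 1.0 - 1e-3)
        logit = np.log(1.0 / frac - 1.0)
        A = np.column_stack([np.ones_like(model.gcc), model.gcc])
        (b0, b1), *_ = np.linalg.lstsq(A, logit, rcond=None)
        return np.array([theta1, b0, b1, 0.0, 0.0, 0.0])
    if isinstance(model, ComparatorData):
        if model.family == "broken_stick_plateau":
            return np.array([float(np.quantile(model.gcc, 0.25)), 0.5])
        order = {"linear": 1, "poly2": 2, "poly3": 3}[model.family]
        A = np.column_stack([model.gcc**k for k in range(order + 1)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return coef
    raise TypeError(f"no default initialisation for {type(model).__name__}")


def _solve_normal_equations(
    JTJ: np.ndarray, JTr: np.ndarray, lam: float
) -> np.ndarray:
    A = JTJ + lam * np.diag(np.diag(JTJ))
    try:
        step = np.linalg.solve(A, JTr)
    except np.linalg.LinAlgError as exc:
        raise SingularJacobianError(
            f"singular normal equations (cond={np.linalg.cond(A):.3e})"
        ) from exc
    if not np.all(np.isfinite(step)):
        raise SingularJacobianError(
            f"non-finite Gauss-Newton step (cond={np.linalg.cond(A):.3e})"
        )
    return step


def gauss_newton_solve(
    model: ResidualModel,
    init: Optional[Sequence[float]] = None,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Minimise the residual sum of squares by Gauss-Newton iteration.

    Steps solve (J'J + lam*diag(J'J)) delta = J'r.  With ``lam = 0``
    (the default) this is pure Gauss-Newton; a step that would increase
    the SSE is rejected and retried with adaptive Levenberg-Marquardt
    damping, so the SSE trace over accepted steps is non-increasing.
    Convergence is declared when the relative SSE change falls below
    ``options.tol``.  Non-convergence is reported honestly via the
    ``converged`` flag, never silently.
    """
    y = np.asarray(model.observed, dtype=float)
    theta = np.array(
        default_init(model) if init is None else init, dtype=float
    )
    n, p = y.size, theta.size
    if n <= p:
        raise NonIdentifiableError(
            f"underdetermined fit: {n} observations for {p} parameters"
        )

    resid = y - model.predict(theta)
    sse = float(resid @ resid)
    lam = options.damping
    converged = False
    n_iter = 0
    for n_iter in range(1, options.max_iter + 1):
        J = model.jacobian(theta)
        JTJ = J.T @ J
        JTr = J.T @ resid
        accepted = False
        for _ in range(60):  # adaptive damping retries within one iteration
            step = _solve_normal_equations(JTJ, JTr, lam)
            cand = theta + step
            cand_resid = y - model.predict(cand)
            cand_sse = float(cand_resid @ cand_resid)
            if np.isfinite(cand_sse) and cand_sse <= sse * (1.0 + 1e-14):
                accepted = True
                break
            lam = 1e-3 if lam == 0.0 else lam * 10.0
            if lam > 1e12:
                break
        if not accepted:
            break
        rel_change = abs(sse - cand_sse) / max(sse, 1e-300)
        theta, resid, sse = cand, cand_resid, cand_sse
        if lam > 0.0:
            lam /= 10.0
        if rel_change < options.tol:
            converged = True
            break

    covariance = std_errors = p_values = None
    J = model.jacobian(theta)
    JTJ = J.T @ J
    dof = n - p
    cond = np.linalg.cond(JTJ)
    if np.isfinite(cond) and cond < 1e14:
        sigma2 = sse / dof
        covariance = sigma2 * np.linalg.inv(JTJ)
        std_errors = np.sqrt(np.maximum(np.diag(covariance), 0.0))
        p_values = _wald_p(theta, std_errors, dof)

    result = FitResult(
        params=theta,
        param_names=tuple(model.param_names),
        residuals=resid,
        fitted=y - resid,
        sse=sse,
        covariance=covariance,
        std_errors=std_errors,
        p_values=p_values,
        converged=converged,
        n_iter=n_iter,
        n_obs=n,
    )
    if result.param_names and result.param_names[0] == "theta1":
        t1 = result.params[0]
        if not (0.0 < t1 <= 50.0):
            warnings.warn(
                f"theta1 = {t1:.2f} dB outside the plausible (0, 50] range",
                stacklevel=2,
            )
    return result


def _wald_p(
    estimates: np.ndarray, std_errors: np.ndarray, dof: int
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = estimates / std_errors
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    p[std_errors == 0.0] = np.nan  # undefined, reported as such
    return p


def wald_inference(fit: FitResult) -> np.ndarray:
    """Two-sided per-parameter Wald p-values, t with n - p df."""
    if fit.std_errors is None:
        raise ValueError("fit has no covariance; cannot compute p-values")
    return _wald_p(fit.params, fit.std_errors, fit.n_obs - fit.params.size)


def _build_model(
    data: pd.DataFrame, area: str, model_kind: str
) -> ResidualModel:
    gcc_col, vfs_col = f"gcc_{area}_um", f"vfs_{area}_db"
    required = [gcc_col, vfs_col]
    if model_kind == "multiple":
        required += ["age_years", "sex", "se_diopters"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise KeyError(f"dataset is missing columns: {missing}")
    gcc = data[gcc_col].to_numpy(dtype=float)
    y = data[vfs_col].to_numpy(dtype=float)
    if model_kind == "multiple":
        return MultipleLogisticData(
            gcc=gcc,
            age=data["age_years"].to_numpy(dtype=float),
            sex=data["sex"].to_numpy(dtype=float),
            se=data["se_diopters"].to_numpy(dtype=float),
            observed=y,
        )
    if model_kind == "simple":
        return SimpleLogisticData(gcc=gcc, observed=y)
    family = {"plateau": "broken_stick_plateau"}.get(model_kind, model_kind)
    return ComparatorData(gcc=gcc, observed=y, family=family)


def fit_area_model(
    data: pd.DataFrame,
    area: str,
    model_kind: str = "multiple",
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one area's structure-function model to an eye-level table.

    ``area`` is one of the 11 canonical names (``whole``, ``superior``,
    ``inferior``, ``3_1``..``6_4``); ``model_kind`` one of
    ``multiple | simple | linear | poly2 | poly3 | plateau``.  If the
    default start fails to converge, up to ``options.n_restarts``
    seeded jittered restarts are tried and the best-SSE converged fit
    wins (first index on ties).
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(
            f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}"
        )
    model = _build_model(data, area, model_kind)
    init = (
        default_init(model)
        if isinstance(options.init, str)
        else np.asarray(options.init, dtype=float)
    )
    result = gauss_newton_solve(model, init, options)
    if not result.converged and options.n_restarts > 0:
        rng = np.random.default_rng(options.seed)
        best = result if result.converged else None
        for _ in range(options.n_restarts):
            jitter = init * (1.0 + 0.2 * rng.standard_normal(init.size))
            jitter += 0.01 * rng.standard_normal(init.size)
            try:
                cand = gauss_newton_solve(model, jitter, options)
            except (SingularJacobianError, NonIdentifiableError):
                continue
            if cand.converged and (best is None or cand.sse < best.sse):
                best = cand
        if best is not None:
            result = best
    result.model_kind = model_kind
    result.area = area
    return result
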