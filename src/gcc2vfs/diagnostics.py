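"""Model-adequacy statistics for the fitted structure-function models.

Three diagnostics are reported per area, mirroring how the logistic fits
are judged:

* a chi-square goodness-of-fit comparing observed sensitivities (O, dB)
  with model-expected ones (E, dB), chi2 = sum (O-E)^2 / E with
  df = n - (number of fitted parameters); large p (toward 1) = good fit;
* a model-effect ANOVA F testing whether the model predicts the response
  at all, with df1 = 1 and df2 = n - 2 (the regression-of-observed-on-
  predicted reading of "model effect");
* the coefficient of determination R^2 = 1 - SSE/SST.

The F and R^2 are linked by the identity F = r2/(1-r2) * (n-2), which the
test suite exercises.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GofResult",
    "AnovaResult",
    "chi_square_gof",
    "model_effect_anova",
    "r_squared",
]


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float
    r2: float


def chi_square_gof(
    observed: np.ndarray,
    expected: np.ndarray,
    n_params: int,
    *,
    min_expected: float = 0.5,
) -> GofResult:
    """Chi-square goodness-of-fit between observed and expected VFS.

    ``n_params`` is the number of parameters the expected values were
    fitted with (6 for the multiple model, 3 for the simple one, 0 if E
    is fixed a priori).  Expected values at or below ``min_expected`` dB
    produce a warning naming the offending eyes; their terms are kept.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(E <= 0):
        raise ValueError("expected sensitivities must be positive")
    tiny = np.flatnonzero(E <= min_expected)
    if tiny.size:
        warnings.warn(
            f"expected VFS <= {min_expected} dB at indices {tiny.tolist()}; "
            "their chi-square terms may dominate",
            stacklevel=2,
        )
    chi2 = float(np.sum((O - E) ** 2 / E))
    df = O.size - n_params
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    return GofResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSE/SST with SST centred on the observed mean.  A constant
    observed vector has SST = 0 and yields NaN (undefined)."""
    O = np.asarray(observed, dtype=float)
    P = np.asarray(predicted, dtype=float)
    if O.shape != P.shape:
        raise ValueError("observed and predicted must have equal length")
    sst = float(np.sum((O - O.mean()) ** 2))
    if sst == 0.0:
        return math.nan
    sse = float(np.sum((O - P) ** 2))
    return 1.0 - sse / sst


def model_effect_anova(
    observed: np.ndarray, predicted: np.ndarray
) -> AnovaResult:
    """Model-effect F test: does the model predict the response?

    F = [(SST - SSE)/1] / [SSE/(n-2)], df1 = 1, df2 = n - 2.  A perfect
    fit (SSE = 0) reports F = +inf with p = 0; a constant observed
    vector is undefined and reported as NaN throughout.
    """
    O = np.asarray(observed, dtype=float)
    P = np.asarray(predicted, dtype=float)
    if O.shape != P.shape:
        raise ValueError("observed and predicted must have equal length")
    n = O.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    df1, df2 = 1, n - 2
    r2 = r_squared(O, P)
    if math.isnan(r2):
        return AnovaResult(
            F=math.nan, df1=df1, df2=df2, p_value=math.nan, r2=math.nan
        )
    sst = float(np.sum((O - O.mean()) ** 2))
    sse = float(np.sum((O - P) ** 2))
    if sse == 0.0:
        return AnovaResult(F=math.inf, df1=df1, df2=df2, p_value=0.0, r2=r2)
    F = ((sst - sse) / df1) / (sse / df2)
    F = max(F, 0.0)
    return AnovaResult(
        F=F, df1=df1, df2=df2, p_value=float(stats.f.sf(F, df1, df2)), r2=r2
    )
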