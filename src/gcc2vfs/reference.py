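"""Published reference fits shipped with the package.

The original 83-eye cohort's per-area parameter estimates and fit
diagnostics (multiple and simple logistic models for the whole field,
hemifields and the eight GCC-map sectors) are packaged as a flat YAML
fixture.  They serve as generative truth for synthetic cohorts, as
starting points, and as reference values in validation tests.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml

from .models import MultipleLogisticParams, SimpleLogisticParams

__all__ = [
    "load_reference",
    "reference_multiple_params",
    "reference_simple_params",
    "reference_diagnostics",
    "REFERENCE_N_EYES",
]

REFERENCE_N_EYES = 83


@lru_cache(maxsize=1)
def load_reference() -> dict[str, Any]:
    """Raw reference tables as nested dicts keyed by area name."""
    path = resources.files("gcc2vfs.data").joinpath("reference_fits.yaml")
    return yaml.safe_load(path.read_text())


def reference_multiple_params(area: str = "whole") -> MultipleLogisticParams:
    return MultipleLogisticParams(**load_reference()["multiple"][area])


def reference_simple_params(area: str = "whole") -> SimpleLogisticParams:
    return SimpleLogisticParams(**load_reference()["simple"][area])


def reference_diagnostics(model_kind: str, area: str = "whole") -> dict[str, float]:
    """Published goodness-of-fit p, ANOVA F and R² for one area.

    ``model_kind`` is ``"multiple"`` or ``"simple"``.
    """
    return dict(load_reference()[f"diagnostics_{model_kind}"][area])
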