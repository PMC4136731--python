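"""Synthetic eye cohorts with the study population's covariate structure.

Generates eye-level tables (one row per right eye) whose covariates match
the original cohort's published summary — 83 eyes, age 55.9 ± 11.9 years,
spherical equivalent -3.8 ± 3.4 D, 35/83 female — and whose per-area mean
visual-field sensitivities are drawn from the multiple logistic model plus
homoscedastic Gaussian noise, truncated to the perimeter's detectable
range.  Age, sex and SE are sampled independently (the cohort showed no
significant pairwise association among them), and each area's GCC
thickness is drawn independently from a two-component normal mixture — a
"healthy" component on the sensitivity plateau and an "atrophic" one on
the steep limb — so every regime of the sigmoid is represented and the
curve parameters stay identifiable.

The generated table uses the same schema as the canonical study table, so
it is accepted unchanged by every fitting and diagnostic routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import AREAS
from .models import MultipleLogisticParams, predict_vfs_multiple
from .reference import load_reference

__all__ = [
    "GccMixture",
    "CohortConfig",
    "sample_covariates",
    "simulate_vfs",
    "generate_cohort",
    "DEFAULT_NOISE_SD",
]

#: Residual SD (dB) of mean VFS about the logistic prediction.  Chosen by
#: a one-off calibration so that refitting the default whole-field cohort
#: reproduces the R^2 observed in the original study (~0.72); see
#: docs/methods.md.
DEFAULT_NOISE_SD = 5.9


@dataclass(frozen=True)
class GccMixture:
    """Two-component normal mixture for per-area GCC thickness (µm)."""

    healthy_mean: float = 95.0
    healthy_sd: float = 8.0
    atrophic_mean: float = 60.0
    atrophic_sd: float = 12.0
    p_healthy: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_healthy <= 1.0:
            raise ValueError("p_healthy must be in [0, 1]")
        if self.healthy_sd <= 0 or self.atrophic_sd <= 0:
            raise ValueError("mixture SDs must be positive")


def _default_true_params() -> dict[str, MultipleLogisticParams]:
    return {
        area: MultipleLogisticParams(**row)
        for area, row in load_reference()["multiple"].items()
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Defaults reproduce the study conditions: n = 83 right eyes,
    age ~ N(55.9, 11.9²) truncated to [20, 90] years, SE ~ N(-3.8, 3.4²)
    truncated to [-15, +6] D, P(female) = 35/83, GCC from the healthy/
    atrophic mixture truncated to [20, 130] µm, VFS from the published
    multiple-model parameters plus N(0, noise_sd²) clipped to
    [floor_db, ceiling_db].
    """

    n_eyes: int = 83
    seed: int = 0
    age_mean: float = 55.9
    age_sd: float = 11.9
    se_mean: float = -3.8
    se_sd: float = 3.4
    p_female: float = 35.0 / 83.0
    gcc_dist: GccMixture = field(default_factory=GccMixture)
    true_params: Optional[Mapping[str, MultipleLogisticParams]] = None
    noise_sd: float = DEFAULT_NOISE_SD
    floor_db: float = 0.0
    ceiling_db: float = 40.0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.age_sd <= 0 or self.se_sd <= 0:
            raise ValueError("covariate SDs must be positive")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.floor_db >= self.ceiling_db:
            raise ValueError("floor_db must be below ceiling_db")

    def resolved_true_params(self) -> Mapping[str, MultipleLogisticParams]:
        return (
            _default_true_params()
            if self.true_params is None
            else self.true_params
        )


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=n, random_state=rng
    )


def sample_covariates(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw eye-level covariates: age, sex, SE and per-area GCC.

    Age is truncated to [20, 90] years, SE to [-15, +6] D and GCC to
    [20, 130] µm; sex is Bernoulli(p_female) coded 0 = male, 1 = female.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_eyes
    out = pd.DataFrame(
        {
            "eye_id": [f"synth-{i:04d}" for i in range(n)],
            "age_years": _truncated_normal(
                rng, n, config.age_mean, config.age_sd, 20.0, 90.0
            ),
            "sex": (rng.random(n) < config.p_female).astype(int),
            "se_diopters": _truncated_normal(
                rng, n, config.se_mean, config.se_sd, -15.0, 6.0
            ),
        }
    )
    mix = config.gcc_dist
    for area in AREAS:
        healthy = rng.random(n) < mix.p_healthy
        mean = np.where(healthy, mix.healthy_mean, mix.atrophic_mean)
        sd = np.where(healthy, mix.healthy_sd, mix.atrophic_sd)
        # Componentwise truncated draws keep the mixture inside [20, 130] µm.
        a = (20.0 - mean) / sd
        b = (130.0 - mean) / sd
        out[f"gcc_{area}_um"] = stats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, random_state=rng
        )
    return out


def simulate_vfs(
    covariates: pd.DataFrame,
    true_params: Mapping[str, MultipleLogisticParams],
    noise_sd: float = DEFAULT_NOISE_SD,
    floor_db: float = 0.0,
    ceiling_db: float = 40.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-area mean VFS from the multiple logistic model.

    vfs = prediction + N(0, noise_sd²), clipped to [floor_db,
    ceiling_db].  Returns a frame of ``vfs_<area>_db`` columns with a
    ``clip_fraction`` entry in ``.attrs`` reporting the share of
    observations that hit either bound.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    out = pd.DataFrame(index=covariates.index)
    n_clipped = total = 0
    for area, params in true_params.items():
        mean = predict_vfs_multiple(
            params,
            covariates[f"gcc_{area}_um"].to_numpy(),
            covariates["age_years"].to_numpy(),
            covariates["sex"].to_numpy(),
            covariates["se_diopters"].to_numpy(),
        )
        raw = mean + noise_sd * rng.standard_normal(len(covariates))
        clipped = np.clip(raw, floor_db, ceiling_db)
        n_clipped += int(np.sum(raw != clipped))
        total += raw.size
        out[f"vfs_{area}_db"] = clipped
    out.attrs["clip_fraction"] = n_clipped / total if total else 0.0
    return out


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Generate a full synthetic study table (covariates + per-area VFS).

    Byte-identical for a fixed seed.  The returned frame carries the
    generating config and clip fraction in ``.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    cov = sample_covariates(config, rng)
    vfs = simulate_vfs(
        cov,
        config.resolved_true_params(),
        noise_sd=config.noise_sd,
        floor_db=config.floor_db,
        ceiling_db=config.ceiling_db,
        rng=rng,
    )
    table = pd.concat([cov, vfs], axis=1)
    table.attrs["config"] = config
    table.attrs["clip_fraction"] = vfs.attrs["clip_fraction"]
    return table
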