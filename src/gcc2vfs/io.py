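"""Canonical study-table schema, readers, quality filters and pipeline.

The canonical eye-level table is CSV-first: one row per eye with
``eye_id``, ``age_years``, ``sex`` (0 = male, 1 = female),
``se_diopters``, and paired ``gcc_<area>_um`` / ``vfs_<area>_db``
columns for the 11 areas (whole, superior, inferior, 3_1..3_4,
6_1..6_4).  Optional reliability fields (``fixation_loss_frac``,
``false_pos_frac``, ``false_neg_frac``, ``ssi``) drive the record-level
quality filters: perimetry is kept only with fixation losses < 33% and
false positives/negatives < 20%, and OCT scans only with signal
strength index >= 7/10.

An XLSX import adapter converts a deposited spreadsheet into this schema
through an explicit column-mapping config — the source file's internal
headers are never guessed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .diagnostics import chi_square_gof, model_effect_anova
from .estimation import FitOptions, fit_area_model
from .geometry import AREAS

__all__ = [
    "REQUIRED_COLUMNS",
    "RELIABILITY_COLUMNS",
    "FilterReport",
    "read_study_table",
    "write_study_table",
    "reliability_filter",
    "ssi_filter",
    "apply_quality_filters",
    "run_pipeline",
]

logger = logging.getLogger("gcc2vfs")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "eye_id",
    "age_years",
    "sex",
    "se_diopters",
    *[f"gcc_{a}_um" for a in AREAS],
    *[f"vfs_{a}_db" for a in AREAS],
)

RELIABILITY_COLUMNS: tuple[str, ...] = (
    "fixation_loss_frac",
    "false_pos_frac",
    "false_neg_frac",
)

_N_PARAMS = {"multiple": 6, "simple": 3, "linear": 2,
             "poly2": 3, "poly3": 4, "plateau": 2}


@dataclass
class FilterReport:
    """Accounting of record-level quality exclusions."""

    n_input: int
    n_excluded_reliability: int
    n_excluded_ssi: int
    n_retained: int
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.n_input
            != self.n_retained
            + self.n_excluded_reliability
            + self.n_excluded_ssi
        ):
            raise ValueError("filter report counts do not balance")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_reliability": self.n_excluded_reliability,
            "n_excluded_ssi": self.n_excluded_ssi,
            "n_retained": self.n_retained,
            "excluded": dict(self.excluded),
        }


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing required columns: {missing}")
    if table["eye_id"].duplicated().any():
        dupes = table.loc[table["eye_id"].duplicated(), "eye_id"].tolist()
        raise ValueError(f"duplicate eye_id values: {dupes}")
    numeric = [c for c in REQUIRED_COLUMNS if c != "eye_id"]
    for col in numeric:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cells in column {col!r} at rows {bad.tolist()}"
            )
        table[col] = coerced
    # Unit lint: values outside physiological/instrument ranges usually
    # mean a unit mix-up, not real eyes.
    for a in AREAS:
        gcc = table[f"gcc_{a}_um"]
        if ((gcc < 20) | (gcc > 130)).any():
            warnings.warn(
                f"gcc_{a}_um outside [20, 130] µm for some eyes", stacklevel=3
            )
        vfs = table[f"vfs_{a}_db"]
        if ((vfs < 0) | (vfs > 40)).any():
            warnings.warn(
                f"vfs_{a}_db outside [0, 40] dB for some eyes", stacklevel=3
            )
    return table


def read_study_table(
    path: str | Path,
    *,
    column_map: Optional[Mapping[str, str] | str | Path] = None,
    percent_dialect: str = "fraction",
) -> pd.DataFrame:
    """Read and validate a canonical study table.

    CSV is the canonical format.  An ``.xlsx`` file is accepted in import
    mode: ``column_map`` (a mapping or a YAML file of
    ``source header -> canonical column``) must then be supplied, since
    deposited spreadsheets carry their own headers.  ``percent_dialect``
    declares how reliability fields are coded: ``"fraction"`` (0-1) or
    ``"percent"`` (0-100, converted on read); it is never auto-detected.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        if column_map is None:
            raise ValueError(
                "XLSX import requires an explicit column_map "
                "(source header -> canonical column)"
            )
        if isinstance(column_map, (str, Path)):
            column_map = yaml.safe_load(Path(column_map).read_text())
        table = pd.read_excel(path).rename(columns=dict(column_map))
    else:
        table = pd.read_csv(path)
    if percent_dialect not in ("fraction", "percent"):
        raise ValueError("percent_dialect must be 'fraction' or 'percent'")
    if percent_dialect == "percent":
        for col in RELIABILITY_COLUMNS:
            if col in table.columns:
                table[col] = table[col] / 100.0
    return _validate(table)


def write_study_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def reliability_filter(record: Mapping[str, float]) -> tuple[bool, str]:
    """Perimetry reliability: keep iff fixation losses < 33% and false
    positives and false negatives < 20% (strict).  Records without the
    reliability fields pass with a warning."""
    if not all(c in record and pd.notna(record[c]) for c in RELIABILITY_COLUMNS):
        warnings.warn(
            "reliability fields absent; record passed through unfiltered",
            stacklevel=2,
        )
        return True, ""
    if not record["fixation_loss_frac"] < 0.33:
        return False, "fixation losses"
    if not record["false_pos_frac"] < 0.20:
        return False, "false positives"
    if not record["false_neg_frac"] < 0.20:
        return False, "false negatives"
    return True, ""


def ssi_filter(record: Mapping[str, float]) -> tuple[bool, str]:
    """OCT image quality: keep iff signal strength index >= 7/10.
    Records without an SSI pass with a warning."""
    if "ssi" not in record or pd.isna(record["ssi"]):
        warnings.warn(
            "ssi absent; record passed through unfiltered", stacklevel=2
        )
        return True, ""
    if record["ssi"] < 7:
        return False, "signal strength index"
    return True, ""


def apply_quality_filters(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the reliability and SSI filters; order-independent."""
    keep_mask = []
    excluded: dict[str, str] = {}
    n_rel = n_ssi = 0
    has_rel = all(c in table.columns for c in RELIABILITY_COLUMNS)
    has_ssi = "ssi" in table.columns
    with warnings.catch_warnings():
        if not (has_rel and has_ssi):
            warnings.simplefilter("ignore")  # warn once below, not per row
        for _, row in table.iterrows():
            rec = row.to_dict()
            ok_rel, reason_rel = reliability_filter(rec)
            ok_ssi, reason_ssi = ssi_filter(rec)
            keep = ok_rel and ok_ssi
            keep_mask.append(keep)
            if not ok_rel:
                n_rel += 1
                excluded[str(rec["eye_id"])] = reason_rel
            elif not ok_ssi:
                n_ssi += 1
                excluded[str(rec["eye_id"])] = reason_ssi
    if not has_rel:
        warnings.warn("reliability fields absent; perimetry filter skipped",
                      stacklevel=2)
    if not has_ssi:
        warnings.warn("ssi column absent; OCT quality filter skipped",
                      stacklevel=2)
    kept = table.loc[keep_mask].reset_index(drop=True)
    report = FilterReport(
        n_input=len(table),
        n_excluded_reliability=n_rel,
        n_excluded_ssi=n_ssi,
        n_retained=len(kept),
        excluded=excluded,
    )
    return kept, report


def run_pipeline(
    table: pd.DataFrame,
    *,
    model_kinds: tuple[str, ...] = ("multiple", "simple"),
    areas: tuple[str, ...] = AREAS,
    options: FitOptions = FitOptions(),
    out_dir: Optional[str | Path] = None,
    gof_alpha: float = 0.05,
) -> dict:
    """Filter, fit and diagnose every requested area and model.

    Returns (and, if ``out_dir`` is given, writes) a bundle with the
    fitted parameter tables, a per-area diagnostics table flagging areas
    whose goodness-of-fit is rejected at ``gof_alpha``, the filter
    report, and a provenance log (seed, config hash).  Deterministic for
    a fixed table and options.
    """
    kept, report = apply_quality_filters(table)
    fits = []
    diag_rows = []
    for model_kind in model_kinds:
        for area in areas:
            fit = fit_area_model(kept, area, model_kind, options)
            fits.append(fit.to_dict())
            observed = kept[f"vfs_{area}_db"].to_numpy(dtype=float)
            gof = chi_square_gof(observed, fit.fitted, _N_PARAMS[model_kind])
            anova = model_effect_anova(observed, fit.fitted)
            diag_rows.append(
                {
                    "model_kind": model_kind,
                    "area": area,
                    "gof_chi2": gof.chi2,
                    "gof_p": gof.p_value,
                    "F": anova.F,
                    "anova_p": anova.p_value,
                    "r2": anova.r2,
                    "gof_rejected": gof.p_value < gof_alpha,
                    "converged": bool(fit.converged),
                }
            )
    diagnostics = pd.DataFrame(diag_rows)
    config_repr = json.dumps(
        {
            "model_kinds": list(model_kinds),
            "areas": list(areas),
            "tol": options.tol,
            "max_iter": options.max_iter,
            "damping": options.damping,
            "seed": options.seed,
        },
        sort_keys=True,
    )
    bundle = {
        "fits": fits,
        "diagnostics": diagnostics,
        "filter_report": report,
        "log": {
            "seed": options.seed,
            "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
            "n_eyes_fit": len(kept),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "fits.json").write_text(json.dumps(fits, indent=2) + "\n")
        diagnostics.to_csv(out / "diagnostics.csv", index=False)
        (out / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
        (out / "log.json").write_text(
            json.dumps(bundle["log"], indent=2) + "\n"
        )
        logger.info("pipeline bundle written to %s", out)
    return bundle
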