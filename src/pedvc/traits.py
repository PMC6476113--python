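"""Trait derivation and covariate design construction.

Covers the glycated-serum-protein conversions and the shared fixed-effect
design used by every variance-component model: intercept, age, age^2, sex,
age-by-sex interactions, BMI, and (optionally) serum storage time in days.
Age is mean-centered before squaring/interacting to reduce collinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GSP_LINEAR_RANGE",
    "percent_ga",
    "inverse_normal_transform",
    "CovariateDesign",
    "build_design",
]

#: assay linear range for GSP, micromol/L
GSP_LINEAR_RANGE = (21.0, 1354.0)

#: Blom offset for the rank-based inverse normal transform
BLOM_C = 3.0 / 8.0


def percent_ga(gsp, albumin):
    """Convert glycated serum protein to percent glycated albumin.

    %GA = (GSP[umol/L] * 0.182 + 1.97) / (albumin[g/dL] + 2.9)

    Strictly increasing in GSP and strictly decreasing in albumin.
    Values of GSP outside the assay linear range [21, 1354] umol/L trigger a
    warning (they may be extrapolations), not an error.
    """
    gsp = np.asarray(gsp, dtype=float)
    albumin = np.asarray(albumin, dtype=float)
    if np.any(albumin <= 0):
        raise ValueError("albumin must be positive (g/dL)")
    finite = np.isfinite(gsp)
    if np.any((gsp[finite] < GSP_LINEAR_RANGE[0]) | (gsp[finite] > GSP_LINEAR_RANGE[1])):
        warnings.warn(
            "GSP value(s) outside the assay linear range "
            f"[{GSP_LINEAR_RANGE[0]}, {GSP_LINEAR_RANGE[1]}] umol/L",
            stacklevel=2,
        )
    out = (gsp * 0.182 + 1.97) / (albumin + 2.9)
    return out if out.ndim else float(out)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    Non-missing values are mapped to Phi^{-1}((r - 3/8) / (n + 1/4)) where r
    is the 1-based rank (average rank for ties) among the n non-missing
    values; missing values stay missing. Monotone in the input; ties map to
    equal outputs.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("inverse normal transform needs at least 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    quantiles = (ranks - BLOM_C) / (n - 2.0 * BLOM_C + 1.0)
    out = np.full(x.shape, np.nan)
    out[mask] = stats.norm.ppf(quantiles)
    return out


@dataclass(frozen=True)
class CovariateDesign:
    """A full-column-rank fixed-effect design for a set of individuals.

    ``matrix`` rows align with ``ids``; ``columns`` labels the retained
    columns (constant-within-sample columns other than the intercept are
    dropped to restore rank). ``age_center`` records the centering constant
    applied to age before squaring/interacting, so coefficients can be
    interpreted and the design reproduced.
    """

    ids: list[str]
    columns: list[str]
    matrix: np.ndarray
    age_center: float

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.columns)


#: canonical covariate column order
_FULL_COLUMNS = [
    "intercept", "age", "age2", "sex", "age_x_sex", "age2_x_sex", "bmi",
    "storage_days",
]

_SEX_MALE = {"male", "m", "1", "1.0"}
_SEX_FEMALE = {"female", "f", "2", "2.0"}


def _code_sex(values) -> np.ndarray:
    """Code sex 0 = female, 1 = male; unrecognized -> NaN."""
    out = np.full(len(values), np.nan)
    for k, v in enumerate(values):
        s = str(v).strip().lower()
        if s in _SEX_MALE:
            out[k] = 1.0
        elif s in _SEX_FEMALE:
            out[k] = 0.0
    return out


def build_design(
    pheno: pd.DataFrame,
    trait: str | None = None,
    include_storage: bool = True,
) -> CovariateDesign:
    """Build the covariate design from a phenotype table.

    Requires columns ``id``, ``age``, ``sex``, ``bmi`` and, when
    ``include_storage``, ``storage_days``. Individuals missing any required
    covariate (or the trait, when ``trait`` is given) are dropped
    (complete-case). Sex is coded 0/1 (female/male); age is centered at the
    retained-sample mean before squaring and interacting. Columns constant
    within the retained sample (e.g. sex in a single-sex sample) are dropped,
    keeping the design full column rank.
    """
    cols = {c.lower(): c for c in pheno.columns}
    required = ["id", "age", "sex", "bmi"] + (["storage_days"] if include_storage else [])
    for c in required:
        if c not in cols:
            raise ValueError(f"phenotype table lacks required column {c!r}")
    if trait is not None and trait.lower() not in cols:
        raise ValueError(f"phenotype table lacks trait column {trait!r}")

    ids = pheno[cols["id"]].astype(str).to_numpy()
    age = pd.to_numeric(pheno[cols["age"]], errors="coerce").to_numpy(dtype=float)
    bmi = pd.to_numeric(pheno[cols["bmi"]], errors="coerce").to_numpy(dtype=float)
    sex = _code_sex(pheno[cols["sex"]].to_numpy())
    keep = np.isfinite(age) & np.isfinite(bmi) & np.isfinite(sex)
    if np.any(age[np.isfinite(age)] < 0):
        raise ValueError("age must be non-negative")
    if np.any(bmi[np.isfinite(bmi)] <= 0):
        raise ValueError("BMI must be positive")

    storage = None
    if include_storage:
        storage = pd.to_numeric(
            pheno[cols["storage_days"]], errors="coerce"
        ).to_numpy(dtype=float)
        if np.any(storage[np.isfinite(storage)] < 0):
            raise ValueError("storage_days must be non-negative")
        keep &= np.isfinite(storage)
    if trait is not None:
        tvals = pd.to_numeric(pheno[cols[trait.lower()]], errors="coerce").to_numpy(float)
        keep &= np.isfinite(tvals)

    if not np.any(keep):
        raise ValueError("no individuals remain after complete-case filtering")

    age_k = age[keep]
    center = float(age_k.mean())
    age_c = age_k - center
    sex_k = sex[keep]
    columns = {
        "intercept": np.ones(keep.sum()),
        "age": age_c,
        "age2": age_c**2,
        "sex": sex_k,
        "age_x_sex": age_c * sex_k,
        "age2_x_sex": age_c**2 * sex_k,
        "bmi": bmi[keep],
    }
    if include_storage:
        columns["storage_days"] = storage[keep]

    labels, arrays = [], []
    for name in _FULL_COLUMNS:
        if name not in columns:
            continue
        col = columns[name]
        if name != "intercept" and np.ptp(col) == 0.0:
            continue  # constant within sample: drop to keep full rank
        labels.append(name)
        arrays.append(col)
    matrix = np.column_stack(arrays)
    if (matrix.shape[0] >= matrix.shape[1]
            and np.linalg.matrix_rank(matrix) < matrix.shape[1]):
        # collinearity beyond constant columns (e.g. duplicated covariates)
        raise ValueError("covariate design is rank-deficient after filtering")
    return CovariateDesign(
        ids=[str(i) for i in ids[keep]], columns=labels, matrix=matrix,
        age_center=center,
    )
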