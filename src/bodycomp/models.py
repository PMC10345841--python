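"""Whole-body mass estimation from single-level CT measurements.

Three linear estimators map CT-derived predictors at the L3 level to
whole-body fat mass (FM) and fat-free mass (FFM) in kilograms:

* **Model 1** — the Mourtzakis-form area model widely used in clinical
  practice: ``FM = 0.042 · fat_area + 11.2`` and
  ``FFM = 0.3 · muscle_area + 6.06`` (areas in cm²).
* **Model 2** — the same functional form refit on a mixed-BMI cohort:
  ``FM = 0.058 · fat_area + 7.35`` and ``FFM = 0.27 · muscle_area + 13.31``.
* **Density-weighted model** (the "FocusedON" model) — uses tissue
  percentages and radiodensity instead of raw areas.  Tissue density is
  approximated linearly from mean HU, ``ρ = HU/1000 + 1``; body volume is
  extrapolated as ``V_total = weight / ρ_ROI``; the predictor is
  ``x = (weight / ρ_ROI) · FAT% · ρ_FAT`` and
  ``FM = 0.0069 · x + 4.53``, with ``FFM = weight − FM`` by construction.

The density unit label "kg/cm³" follows the source convention verbatim; the
slope absorbs the unit scale, so the formulas are evaluated exactly as
printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "DensityRule",
    "DEFAULT_DENSITY_RULE",
    "hu_to_density",
    "LinearMassModel",
    "MODEL1_FM",
    "MODEL1_FFM",
    "MODEL2_FM",
    "MODEL2_FFM",
    "MODEL3_FM",
    "model1_fm",
    "model1_ffm",
    "model2_fm",
    "model2_ffm",
    "model3_fm",
    "model3_ffm",
    "Model3Result",
    "density_weighted_predictor",
    "fit_linear",
    "FitResult",
    "sample_size",
    "SampleSize",
    "inflate_sample",
]

PredictorKind = Literal["fat_area_cm2", "muscle_area_cm2", "density_weighted_fat"]


@dataclass(frozen=True)
class DensityRule:
    """Linear HU → density conversion: ``density = scale·HU + offset``.

    Defaults give water (0 HU) density 1 and fat (≈ −100 HU) density 0.9,
    in the source's printed units (kg/cm³ label, g/cm³ magnitude).
    """

    scale: float = 1.0 / 1000.0
    offset: float = 1.0


DEFAULT_DENSITY_RULE = DensityRule()


def hu_to_density(hu, rule: DensityRule = DEFAULT_DENSITY_RULE):
    """Convert Hounsfield units to approximate tissue density.

    Accepts scalars or arrays; ``hu_to_density(0) == 1.0`` exactly.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("hu must be finite")
    out = rule.scale * hu + rule.offset
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LinearMassModel:
    """Affine map from a CT-derived predictor to mass in kg."""

    slope: float
    intercept: float
    predictor_kind: PredictorKind

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or not math.isfinite(self.intercept):
            raise ValueError("slope and intercept must be finite")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = self.slope * x + self.intercept
        return float(out) if out.ndim == 0 else out


MODEL1_FM = LinearMassModel(0.042, 11.2, "fat_area_cm2")
MODEL1_FFM = LinearMassModel(0.3, 6.06, "muscle_area_cm2")
MODEL2_FM = LinearMassModel(0.058, 7.35, "fat_area_cm2")
MODEL2_FFM = LinearMassModel(0.27, 13.31, "muscle_area_cm2")
MODEL3_FM = LinearMassModel(0.0069, 4.53, "density_weighted_fat")


def _check_area(area) -> np.ndarray:
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("tissue area must be non-negative")
    return area


def model1_fm(fat_area_cm2):
    """Model 1 fat mass (kg) from total fat area (cm²) at L3."""
    return MODEL1_FM.predict(_check_area(fat_area_cm2))


def model1_ffm(muscle_area_cm2):
    """Model 1 fat-free mass (kg) from skeletal muscle area (cm²) at L3."""
    return MODEL1_FFM.predict(_check_area(muscle_area_cm2))


def model2_fm(fat_area_cm2):
    """Model 2 (mixed-BMI refit) fat mass (kg) from fat area (cm²)."""
    return MODEL2_FM.predict(_check_area(fat_area_cm2))


def model2_ffm(muscle_area_cm2):
    """Model 2 (mixed-BMI refit) fat-free mass (kg) from muscle area (cm²)."""
    return MODEL2_FFM.predict(_check_area(muscle_area_cm2))


class Model3Result(NamedTuple):
    """Density-weighted fat-mass estimate with its derivation chain."""

    fm_kg: float
    predictor: float
    rho_roi: float      # density of the whole body ROI
    rho_fat: float      # density of the fat compartment
    v_total_cm3: float  # extrapolated body volume, weight / rho_roi
    v_fat_cm3: float    # fat volume, v_total · fat_pct / 100
    m_fat_kg: float     # fat mass by the density chain, v_fat · rho_fat


def density_weighted_predictor(
    weight_kg: float,
    roi_mean_hu: float,
    fat_pct: float,
    fat_mean_hu: float,
    rule: DensityRule = DEFAULT_DENSITY_RULE,
) -> Model3Result:
    """Compute the density-weighted fat predictor and its intermediates.

    The predictor is ``(weight / ρ_ROI) · FAT% · ρ_FAT`` with FAT% on the
    0–100 scale (the model slope absorbs the /100).
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if not 0.0 <= fat_pct <= 100.0:
        raise ValueError(f"fat_pct must lie in [0, 100], got {fat_pct}")
    rho_roi = hu_to_density(roi_mean_hu, rule)
    if rho_roi <= 0:
        raise ValueError(f"rho_roi = {rho_roi:.4f} <= 0: nonphysical ROI mean HU")
    rho_fat = hu_to_density(fat_mean_hu, rule)
    v_total = weight_kg / rho_roi
    v_fat = v_total * fat_pct / 100.0
    x = v_total * fat_pct * rho_fat
    return Model3Result(
        fm_kg=float("nan"),
        predictor=x,
        rho_roi=rho_roi,
        rho_fat=rho_fat,
        v_total_cm3=v_total,
        v_fat_cm3=v_fat,
        m_fat_kg=v_fat * rho_fat,
    )


def model3_fm(
    weight_kg: float,
    roi_mean_hu: float,
    fat_pct: float,
    fat_mean_hu: float,
    model: LinearMassModel = MODEL3_FM,
    rule: DensityRule = DEFAULT_DENSITY_RULE,
) -> Model3Result:
    """Density-weighted fat mass (kg); intermediates exposed for inspection."""
    chain = density_weighted_predictor(weight_kg, roi_mean_hu, fat_pct, fat_mean_hu, rule)
    return chain._replace(fm_kg=model.predict(chain.predictor))


def model3_ffm(weight_kg, fm_kg):
    """Fat-free mass as the exact complement of fat mass: ``weight − FM``."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    fm_kg = np.asarray(fm_kg, dtype=float)
    out = weight_kg - fm_kg
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting


class FitResult(NamedTuple):
    model: LinearMassModel
    residual_sd: float
    r_squared: float
    n: int


def fit_linear(
    predictor,
    reference_kg,
    predictor_kind: PredictorKind = "fat_area_cm2",
) -> FitResult:
    """Ordinary least squares fit of ``reference = slope·predictor + intercept``.

    Requires at least three points and non-degenerate predictor variance.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(reference_kg, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predictor and reference must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"insufficient data: need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = slope * x + intercept
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = x.size - 2
    return FitResult(
        model=LinearMassModel(float(slope), float(intercept), predictor_kind),
        residual_sd=math.sqrt(ss_res / dof) if dof > 0 else float("nan"),
        r_squared=r2,
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Sample size (Cohen form)


class SampleSize(NamedTuple):
    n: float       # z²·s²/d², unrounded
    n_ceil: int    # ceiling-rounded


def sample_size(z: float, s: float, d: float) -> SampleSize:
    """Cohen sample-size formula ``N = z²·s²/d²``.

    ``z`` is the standard-normal critical value (1.96 at the 5% level),
    ``s`` the standard deviation of the estimating variable, ``d`` the
    desired precision.
    """
    if z <= 0 or s <= 0:
        raise ValueError("z and s must be positive")
    if d <= 0:
        raise ValueError("precision d must be positive")
    n = (z**2 * s**2) / d**2
    return SampleSize(n=n, n_ceil=math.ceil(n))


def inflate_sample(n: float, factor: float) -> float:
    """Inflate a base sample size by a variability factor (e.g. 51 × 1.35)."""
    if n <= 0 or factor <= 0:
        raise ValueError("n and factor must be positive")
    return n * factor
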