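"""Synthetic L3 cross-sections and synthetic cohorts with ground truth.

The phantom emulates the gross radiological anatomy of an axial abdominal
CT slice at the L3 level as concentric ellipses: a subcutaneous fat ring
under the skin, an abdominal-wall muscle band, and a visceral cavity
containing visceral fat, soft-tissue "organs" and a vertebral-body bone
placeholder.  Visceral fat lines the deep surface of the muscle wall (as
retro-/intraperitoneal fat does) and otherwise forms random blobs.  HU
values are drawn from tissue-specific truncated normals so that, with the
default parameters, every tissue's HU support lies strictly inside its
segmentation threshold window — which makes exact segmentation recovery a
testable oracle.

The cohort generator produces paired "DXA-style" reference masses from a
stated generative model (the density-weighted mass model plus additive
Gaussian noise, or optionally the area-based model form), so least-squares
parameter recovery is testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import CTSlice, LabelMask
from .models import DEFAULT_DENSITY_RULE, DensityRule, hu_to_density

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "analytic_areas",
    "GT_LEGEND",
    "GT_TO_SEGMENT_CLASS",
    "AIR_HU",
]

AIR_HU = -1000.0

#: Ground-truth label legend written by :func:`generate_phantom`.
GT_LEGEND = {
    1: "muscle",
    2: "sat",
    3: "vat",
    4: "imat",
    5: "visceral_other",
    6: "bone",
}

#: Map from ground-truth tissue names to the classes emitted by the
#: threshold segmenter (organs and bone are "other" there).
GT_TO_SEGMENT_CLASS = {
    "muscle": "muscle",
    "sat": "sat",
    "vat": "vat",
    "imat": "imat",
    "visceral_other": "other",
    "bone": "other",
}

_GT_ID = {v: k for k, v in GT_LEGEND.items()}


def _default_hu_means() -> dict[str, float]:
    # centred inside each threshold window; organs in the muscle HU range,
    # bone well above every window
    return {
        "muscle": 40.0,
        "sat": -100.0,
        "vat": -90.0,
        "imat": -100.0,
        "visceral_other": 30.0,
        "bone": 400.0,
    }


def _default_hu_sds() -> dict[str, float]:
    return {
        "muscle": 5.0,
        "sat": 5.0,
        "vat": 5.0,
        "imat": 5.0,
        "visceral_other": 10.0,
        "bone": 40.0,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, HU distributions and sampling parameters of the phantom.

    Lengths are in millimetres.  Default geometry approximates an adult
    abdomen (34 × 24 cm body ellipse, 30 mm subcutaneous fat, 15 mm muscle
    wall) on a 256² grid at 1.5 mm spacing.
    """

    body_semiaxes: tuple[float, float] = (170.0, 120.0)
    sat_thickness: float = 30.0
    muscle_thickness: float = 15.0
    visceral_fat_fraction: float = 0.35
    imat_fraction: float = 0.02
    vat_lining_mm: float = 4.5
    bone_radius_mm: float = 18.0
    hu_means: dict[str, float] = field(default_factory=_default_hu_means)
    hu_sds: dict[str, float] = field(default_factory=_default_hu_sds)
    truncation_sd: float = 3.0
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    grid_size: tuple[int, int] = (256, 256)
    n_slices: int = 1
    translation_invariant: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("sat_thickness", "muscle_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.body_semiaxes) <= 0:
            raise ValueError("body_semiaxes must be strictly positive")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be strictly positive")
        if min(self.grid_size) <= 0 or self.n_slices <= 0:
            raise ValueError("grid_size and n_slices must be positive")
        if not 0.0 <= self.visceral_fat_fraction <= 1.0:
            raise ValueError("visceral_fat_fraction must lie in [0, 1]")
        if not 0.0 <= self.imat_fraction <= 1.0:
            raise ValueError("imat_fraction must lie in [0, 1]")
        if self.truncation_sd <= 0:
            raise ValueError("truncation_sd must be positive")
        missing = set(GT_LEGEND.values()) - set(self.hu_means) | (
            set(GT_LEGEND.values()) - set(self.hu_sds)
        )
        if missing:
            raise ValueError(f"hu_means/hu_sds missing tissues: {sorted(missing)}")
        if self.sat_thickness + self.muscle_thickness >= min(self.body_semiaxes):
            raise ValueError("sat_thickness + muscle_thickness exceed body semiaxes")


def _ellipse(shape, spacing, semiaxes) -> np.ndarray:
    rows = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * spacing[0]
    cols = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * spacing[1]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    a, b = semiaxes  # row semiaxis, column semiaxis
    return (rr / a) ** 2 + (cc / b) ** 2 <= 1.0


def _label_geometry(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Build one ground-truth label image from the spec geometry."""
    shape, sp = spec.grid_size, spec.pixel_spacing
    a, b = spec.body_semiaxes
    body = _ellipse(shape, sp, (a, b))
    inner1 = _ellipse(shape, sp, (a - spec.sat_thickness, b - spec.sat_thickness))
    inner2 = _ellipse(
        shape,
        sp,
        (a - spec.sat_thickness - spec.muscle_thickness,
         b - spec.sat_thickness - spec.muscle_thickness),
    )
    labels = np.zeros(shape, dtype=np.int16)
    labels[body & ~inner1] = _GT_ID["sat"]
    labels[inner1 & ~inner2] = _GT_ID["muscle"]
    cavity = inner2

    # vertebral-body placeholder: posterior disc inside the cavity
    cav_b_row = a - spec.sat_thickness - spec.muscle_thickness
    r_bone = min(spec.bone_radius_mm, 0.35 * cav_b_row)
    if r_bone > max(sp):
        rows = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * sp[0]
        cols = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * sp[1]
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        bone = ((rr - 0.55 * cav_b_row) ** 2 + cc**2) <= r_bone**2
        bone &= cavity
        labels[bone] = _GT_ID["bone"]

    # visceral fat: a lining along the deep surface of the muscle wall,
    # plus smoothed-noise blobs up to the requested cavity fraction
    free = cavity & (labels == 0)
    lining_px = max(1, int(round(spec.vat_lining_mm / min(sp))))
    interior = ndimage.binary_erosion(cavity, iterations=lining_px)
    lining = free & ~interior
    labels[lining] = _GT_ID["vat"]
    free = cavity & (labels == 0)
    n_target = int(round(spec.visceral_fat_fraction * int(cavity.sum())))
    n_more = n_target - int(lining.sum())
    if n_more > 0 and free.any():
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
        order = np.argsort(noise[free])[::-1]
        idx = np.flatnonzero(free.ravel())[order[: min(n_more, int(free.sum()))]]
        flat = labels.ravel()
        flat[idx] = _GT_ID["vat"]
        labels = flat.reshape(shape)

    # intramuscular fat: random speckles strictly interior to the band so
    # they stay holes of the band, not bridges to SAT or cavity
    if spec.imat_fraction > 0:
        band = labels == _GT_ID["muscle"]
        core = ndimage.binary_erosion(band, structure=np.ones((3, 3)), iterations=1)
        cand = np.flatnonzero(core.ravel())
        n_imat = int(round(spec.imat_fraction * int(band.sum())))
        if n_imat > 0 and cand.size > 0:
            pick = rng.choice(cand, size=min(n_imat, cand.size), replace=False)
            flat = labels.ravel()
            flat[pick] = _GT_ID["imat"]
            labels = flat.reshape(shape)

    labels[cavity & (labels == 0)] = _GT_ID["visceral_other"]
    return labels


def _sample_hu(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    hu = np.full(labels.shape, AIR_HU, dtype=float)
    for name, lab_id in _GT_ID.items():
        sel = labels == lab_id
        n = int(sel.sum())
        if n == 0:
            continue
        mu, sd = spec.hu_means[name], spec.hu_sds[name]
        t = spec.truncation_sd
        hu[sel] = stats.truncnorm.rvs(-t, t, loc=mu, scale=sd, size=n, random_state=rng)
    return hu


def generate_phantom(spec: PhantomSpec) -> tuple[list[CTSlice], list[LabelMask]]:
    """Generate an L3 phantom stack with ground-truth labels.

    Returns ``n_slices`` paired (CT slice, label mask); identical spec and
    seed give identical output.  With ``translation_invariant=True`` every
    slice is an exact copy of the first, emulating a stack whose content
    does not change along the scanner axis.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    slices: list[CTSlice] = []
    masks: list[LabelMask] = []
    for k in range(spec.n_slices):
        if spec.translation_invariant and k > 0:
            slices.append(replace(slices[0], slice_id=f"phantom[{k}]"))
            masks.append(LabelMask(masks[0].labels.copy(), dict(GT_LEGEND)))
            continue
        labels = _label_geometry(spec, rng)
        hu = _sample_hu(labels, spec, rng)
        slices.append(CTSlice(hu, spec.pixel_spacing, slice_id=f"phantom[{k}]"))
        masks.append(LabelMask(labels, dict(GT_LEGEND)))
    return slices, masks


def analytic_areas(spec: PhantomSpec) -> dict[str, float]:
    """Continuous-geometry compartment areas in cm² (discretization-free).

    The SAT ring and muscle band are ellipse annuli, the cavity the
    innermost ellipse; used as the oracle for pixel-counted areas.
    """
    a, b = spec.body_semiaxes
    a1, b1 = a - spec.sat_thickness, b - spec.sat_thickness
    a2, b2 = a1 - spec.muscle_thickness, b1 - spec.muscle_thickness
    to_cm2 = 1.0 / 100.0
    return {
        "body": math.pi * a * b * to_cm2,
        "sat_ring": math.pi * (a * b - a1 * b1) * to_cm2,
        "muscle_band": math.pi * (a1 * b1 - a2 * b2) * to_cm2,
        "cavity": math.pi * a2 * b2 * to_cm2,
    }


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic subject cohort.

    Reference masses follow the chosen model form plus Gaussian noise:
    the density-weighted form ``FM = m·(weight/ρ_ROI)·FAT%·ρ_FAT + n + ε``
    by default, or the area-based form ``FM = m·fat_area + n + ε``.
    Defaults mirror a 70-subject mixed-BMI validation cohort with the
    printed density-weighted coefficients and 3 kg reference noise.
    """

    n_subjects: int = 70
    weight_range: tuple[float, float] = (55.0, 145.0)   # kg
    height_range: tuple[float, float] = (1.50, 1.90)    # m
    fat_pct_range: tuple[float, float] = (18.0, 55.0)   # % of body ROI area
    fat_hu_range: tuple[float, float] = (-105.0, -85.0)
    roi_hu_noise_sd: float = 5.0                        # HU scatter around trend
    body_area_range: tuple[float, float] = (350.0, 900.0)  # cm² at L3
    muscle_pct_range: tuple[float, float] = (18.0, 35.0)
    true_m: float = 0.0069
    true_n: float = 4.53
    noise_sd: float = 3.0                               # kg, on reference FM
    generative_form: Literal["density_weighted", "linear_area"] = "density_weighted"
    female_fraction: float = 0.59
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3 (fit needs > 2 points)")
        if self.noise_sd < 0 or self.roi_hu_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for name in ("weight_range", "height_range", "fat_pct_range",
                     "fat_hu_range", "body_area_range", "muscle_pct_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is inverted: ({lo}, {hi})")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


def generate_cohort(
    spec: CohortSpec,
    rule: DensityRule = DEFAULT_DENSITY_RULE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a subject table and a paired per-subject CT metric table.

    Returns ``(subjects, ct)``; ``subjects`` has columns id, sex, weight,
    height, bmi, dxa_fm, dxa_ffm, group; ``ct`` has id, body_area_cm2,
    fat_area_cm2, muscle_area_cm2, fat_pct, muscle_pct, roi_mean_hu,
    fat_mean_hu.  The whole-ROI mean HU trends linearly with FAT% between
    lean soft tissue (~30 HU) and fat (~−100 HU), with Gaussian scatter.
    Identical spec and seed give identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    weight = rng.uniform(*spec.weight_range, size=n)
    height = rng.uniform(*spec.height_range, size=n)
    fat_pct = rng.uniform(*spec.fat_pct_range, size=n)
    fat_hu = rng.uniform(*spec.fat_hu_range, size=n)
    body_area = rng.uniform(*spec.body_area_range, size=n)
    muscle_pct = rng.uniform(*spec.muscle_pct_range, size=n)
    sex = np.where(rng.random(n) < spec.female_fraction, "F", "M")

    lean_hu = 30.0
    roi_hu = (fat_pct / 100.0) * fat_hu + (1.0 - fat_pct / 100.0) * lean_hu
    roi_hu = roi_hu + rng.normal(0.0, spec.roi_hu_noise_sd, size=n)

    fat_area = body_area * fat_pct / 100.0
    muscle_area = body_area * muscle_pct / 100.0

    eps = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    if spec.generative_form == "density_weighted":
        rho_roi = hu_to_density(roi_hu, rule)
        rho_fat = hu_to_density(fat_hu, rule)
        predictor = weight / rho_roi * fat_pct * rho_fat
    elif spec.generative_form == "linear_area":
        predictor = fat_area
    else:
        raise ValueError(f"unknown generative_form {spec.generative_form!r}")
    dxa_fm = spec.true_m * predictor + spec.true_n + eps
    dxa_ffm = weight - dxa_fm

    bmi = weight / height**2
    subjects = pd.DataFrame(
        {
            "id": [f"S{i:03d}" for i in range(n)],
            "sex": sex,
            "weight": weight,
            "height": height,
            "bmi": bmi,
            "dxa_fm": dxa_fm,
            "dxa_ffm": dxa_ffm,
            "group": np.where(bmi >= 30.0, "obesity", "normal-BMI"),
        }
    )
    ct = pd.DataFrame(
        {
            "id": subjects["id"],
            "body_area_cm2": body_area,
            "fat_area_cm2": fat_area,
            "muscle_area_cm2": muscle_area,
            "fat_pct": fat_pct,
            "muscle_pct": muscle_pct,
            "roi_mean_hu": roi_hu,
            "fat_mean_hu": fat_hu,
        }
    )
    return subjects, ct
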