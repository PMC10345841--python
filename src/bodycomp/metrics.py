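"""Per-tissue CT variables: areas, percentages, height-normalized indices,
and mean HU, per slice and aggregated over a slice stack.

Areas are physical (pixel count × pixel area, reported in cm²); indices
divide by height squared (cm²/m²), mirroring SMI-style normalization.
FAT% is the share of body-ROI area occupied by all fat compartments
(SAT + VAT + IMAT); the whole-ROI mean HU feeds the density-weighted mass
model as ρ_ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import fsum
from typing import Sequence

import numpy as np

from .io import CTSlice, LabelMask

__all__ = ["TissueMetrics", "compute_metrics", "aggregate_slices", "TISSUE_CLASSES"]

#: Canonical tissue classes.  Legend names outside this set (bone,
#: visceral organs, ...) are pooled into "other".
TISSUE_CLASSES = ("muscle", "sat", "vat", "imat", "other")


def _canonical(name: str) -> str:
    return name if name in TISSUE_CLASSES else "other"


@dataclass
class TissueMetrics:
    """Tissue areas, percentages, indices and HU summaries for one slice
    (or an aggregate over several; see ``n_slices_aggregated``).

    ``mean_hu[tissue]`` is ``None`` when the tissue has no pixels — an
    explicit undefined flag rather than a propagating NaN.
    """

    areas_cm2: dict[str, float]
    pct: dict[str, float]
    mean_hu: dict[str, float | None]
    pixel_counts: dict[str, int]
    body_area_cm2: float
    fat_pct: float
    roi_mean_hu: float
    height_m: float
    n_slices_aggregated: int = 1
    slice_id: str = ""

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError("height must be positive")

    # --- named areas (cm²) and height-normalized indices (cm²/m²) ---
    @property
    def sma(self) -> float:
        """Skeletal muscle area."""
        return self.areas_cm2["muscle"]

    @property
    def smi(self) -> float:
        return self.sma / self.height_m**2

    @property
    def imat_area(self) -> float:
        return self.areas_cm2["imat"]

    @property
    def iimat(self) -> float:
        return self.imat_area / self.height_m**2

    @property
    def vfa(self) -> float:
        """Visceral fat area."""
        return self.areas_cm2["vat"]

    @property
    def vfi(self) -> float:
        return self.vfa / self.height_m**2

    @property
    def sfa(self) -> float:
        """Subcutaneous fat area."""
        return self.areas_cm2["sat"]

    @property
    def sfi(self) -> float:
        return self.sfa / self.height_m**2

    @property
    def fat_mean_hu(self) -> float | None:
        """Pixel-weighted mean HU over all fat (SAT + VAT + IMAT); ρ_FAT source."""
        n = sum(self.pixel_counts[t] for t in ("sat", "vat", "imat"))
        if n == 0:
            return None
        tot = sum(
            self.mean_hu[t] * self.pixel_counts[t]
            for t in ("sat", "vat", "imat")
            if self.pixel_counts[t] > 0
        )
        return tot / n

    def as_row(self) -> dict:
        """Flat dict for tabular export (one CSV row)."""
        row = {
            "slice_id": self.slice_id,
            "n_slices": self.n_slices_aggregated,
            "body_area_cm2": self.body_area_cm2,
            "sma_cm2": self.sma,
            "smi_cm2_m2": self.smi,
            "imat_cm2": self.imat_area,
            "iimat_cm2_m2": self.iimat,
            "vfa_cm2": self.vfa,
            "vfi_cm2_m2": self.vfi,
            "sfa_cm2": self.sfa,
            "sfi_cm2_m2": self.sfi,
            "fat_pct": self.fat_pct,
            "roi_mean_hu": self.roi_mean_hu,
            "fat_mean_hu": self.fat_mean_hu,
        }
        for t in TISSUE_CLASSES:
            row[f"{t}_pct"] = self.pct[t]
            row[f"{t}_mean_hu"] = self.mean_hu[t]
        return row


def compute_metrics(slice_: CTSlice, mask: LabelMask, height_m: float) -> TissueMetrics:
    """Compute per-tissue areas, percentages, indices and mean HU.

    The body ROI is the set of non-background labelled pixels; tissue
    percentages are relative to it and sum (with "other") to 100.
    """
    if slice_.hu.shape != mask.labels.shape:
        raise ValueError("slice and mask shapes differ")
    if height_m <= 0:
        raise ValueError("height must be positive")
    body = mask.labels > 0
    n_body = int(body.sum())
    if n_body == 0:
        raise ValueError("empty body mask")

    px_cm2 = slice_.pixel_area_mm2 / 100.0  # mm² → cm²
    counts = dict.fromkeys(TISSUE_CLASSES, 0)
    hu_sums = dict.fromkeys(TISSUE_CLASSES, 0.0)
    for lab_id, name in mask.legend.items():
        cls = _canonical(name)
        sel = mask.labels == lab_id
        n = int(sel.sum())
        if n == 0:
            continue
        counts[cls] += n
        hu_sums[cls] += float(slice_.hu[sel].sum())

    areas = {t: counts[t] * px_cm2 for t in TISSUE_CLASSES}
    pct = {t: 100.0 * counts[t] / n_body for t in TISSUE_CLASSES}
    mean_hu = {
        t: (hu_sums[t] / counts[t] if counts[t] > 0 else None) for t in TISSUE_CLASSES
    }
    fat_px = counts["sat"] + counts["vat"] + counts["imat"]
    return TissueMetrics(
        areas_cm2=areas,
        pct=pct,
        mean_hu=mean_hu,
        pixel_counts=counts,
        body_area_cm2=n_body * px_cm2,
        fat_pct=100.0 * fat_px / n_body,
        roi_mean_hu=float(slice_.hu[body].mean()),
        height_m=height_m,
        slice_id=slice_.slice_id,
    )


def aggregate_slices(
    per_slice: Sequence[TissueMetrics],
    mode: str = "mean",
    index: int | None = None,
) -> TissueMetrics:
    """Aggregate per-slice metrics into one summary.

    ``mode="single"`` picks the slice at ``index``.  ``mode="mean"``
    averages areas and percentages across slices; mean HU (per tissue and
    whole-ROI) is pixel-count-weighted, so the aggregate equals the value
    that would be computed on the pooled pixel set.
    """
    if len(per_slice) == 0:
        raise ValueError("no slices to aggregate")
    if mode == "single":
        if index is None:
            raise ValueError("mode='single' requires a slice index")
        return replace(per_slice[index], n_slices_aggregated=1)
    if mode != "mean":
        raise ValueError(f"unknown aggregation mode {mode!r}")

    k = len(per_slice)
    heights = {m.height_m for m in per_slice}
    if len(heights) > 1:
        raise ValueError("slices belong to different subjects (heights differ)")

    # math.fsum keeps the mean of identical slices bit-identical to one slice
    areas = {t: fsum(m.areas_cm2[t] for m in per_slice) / k for t in TISSUE_CLASSES}
    pct = {t: fsum(m.pct[t] for m in per_slice) / k for t in TISSUE_CLASSES}
    counts = {t: sum(m.pixel_counts[t] for m in per_slice) for t in TISSUE_CLASSES}
    mean_hu: dict[str, float | None] = {}
    for t in TISSUE_CLASSES:
        if counts[t] == 0:
            mean_hu[t] = None
        else:
            tot = fsum(
                m.mean_hu[t] * m.pixel_counts[t]
                for m in per_slice
                if m.pixel_counts[t] > 0
            )
            mean_hu[t] = tot / counts[t]

    body_px = [sum(m.pixel_counts.values()) for m in per_slice]
    roi_hu = fsum(m.roi_mean_hu * n for m, n in zip(per_slice, body_px)) / sum(body_px)
    return TissueMetrics(
        areas_cm2=areas,
        pct=pct,
        mean_hu=mean_hu,
        pixel_counts=counts,
        body_area_cm2=fsum(m.body_area_cm2 for m in per_slice) / k,
        fat_pct=fsum(m.fat_pct for m in per_slice) / k,
        roi_mean_hu=roi_hu,
        height_m=per_slice[0].height_m,
        n_slices_aggregated=k,
        slice_id="aggregate",
    )
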