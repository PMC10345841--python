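"""HU-threshold tissue segmentation with spatial compartments.

The standard L3 body-composition thresholds are −29..150 HU for skeletal
muscle, −190..−30 HU for subcutaneous adipose tissue (SAT) and −150..−50 HU
for visceral adipose tissue (VAT).  The SAT and VAT windows overlap, so HU
alone cannot separate them: pixels are first assigned to spatial
compartments (subcutaneous zone / abdominal-wall muscle band / visceral
cavity) and the HU windows are applied within each compartment.
Intramuscular adipose tissue (IMAT) is fat-range signal inside the muscle
band; it has no dedicated window and uses the SAT window.

Compartments are derived morphologically: the body is the largest connected
region above −500 HU (hole-filled); the muscle band is the connected shell
of muscle-window pixels reachable from the body surface; everything the
band encloses is the visceral cavity; everything outside it is the
subcutaneous zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CTSlice, LabelMask

__all__ = [
    "ThresholdSet",
    "DEFAULT_THRESHOLDS",
    "CompartmentMap",
    "derive_compartments",
    "segment",
    "SEGMENT_LEGEND",
    "BODY_HU_THRESHOLD",
]

#: HU above which a pixel can belong to the body (excludes air).
BODY_HU_THRESHOLD = -500.0

#: Label ids emitted by :func:`segment`.
SEGMENT_LEGEND = {1: "muscle", 2: "sat", 3: "vat", 4: "imat", 5: "other"}

_ID = {name: k for k, name in SEGMENT_LEGEND.items()}


@dataclass(frozen=True)
class ThresholdSet:
    """Inclusive HU windows per tissue (low, high)."""

    muscle: tuple[float, float] = (-29.0, 150.0)
    sat: tuple[float, float] = (-190.0, -30.0)
    vat: tuple[float, float] = (-150.0, -50.0)

    def __post_init__(self) -> None:
        for name in ("muscle", "sat", "vat"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} window inverted: ({lo}, {hi})")

    def window(self, hu: np.ndarray, name: str) -> np.ndarray:
        """Boolean mask of pixels inside the named window (inclusive bounds)."""
        lo, hi = getattr(self, name)
        return (hu >= lo) & (hu <= hi)


DEFAULT_THRESHOLDS = ThresholdSet()


@dataclass
class CompartmentMap:
    """Disjoint spatial compartments partitioning the body mask."""

    body: np.ndarray
    wall_band: np.ndarray
    visceral_cavity: np.ndarray
    subcutaneous_zone: np.ndarray
    truncated: bool = field(default=False)

    def validate(self) -> None:
        union = self.wall_band | self.visceral_cavity | self.subcutaneous_zone
        overlap = (
            self.wall_band.astype(int)
            + self.visceral_cavity.astype(int)
            + self.subcutaneous_zone.astype(int)
        )
        if not np.array_equal(union, self.body) or overlap.max() > 1:
            raise ValueError("compartments do not partition the body mask")


def derive_compartments(
    slice_: CTSlice,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    body_hu_threshold: float = BODY_HU_THRESHOLD,
) -> CompartmentMap:
    """Split a slice into subcutaneous zone, muscle wall band, and cavity.

    Steps
    -----
    1. body = largest 8-connected component above ``body_hu_threshold``,
       hole-filled.
    2. subcutaneous fat = SAT-window components touching the body surface.
    3. wall band = muscle-window components (outside the subcutaneous fat)
       adjacent to the subcutaneous fat or the body surface; small enclosed
       holes of the band (intramuscular fat) are annexed to the band, the
       single largest enclosed region is the visceral cavity.
    4. subcutaneous zone = body pixels outside the filled band.

    Raises an error when no body region exists; flags (and warns about)
    bodies truncated by the image edge, since their areas are unreliable.
    """
    hu = slice_.hu
    above = hu > body_hu_threshold
    lab, n = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no body region found (image is all air)")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    body = ndimage.binary_fill_holes(body)

    truncated = bool(
        body[0, :].any() or body[-1, :].any() or body[:, 0].any() or body[:, -1].any()
    )
    if truncated:
        warnings.warn("body region touches the image edge; areas may be truncated",
                      stacklevel=2)

    surface = body & ~ndimage.binary_erosion(body, structure=np.ones((3, 3)))

    sat_cand = thresholds.window(hu, "sat") & body
    subcut_fat = _components_touching(sat_cand, surface)

    muscle_cand = thresholds.window(hu, "muscle") & body & ~subcut_fat
    wall = _components_touching(muscle_cand, subcut_fat | surface)

    if not wall.any():
        # no muscle shell: treat the whole body as subcutaneous zone
        empty = np.zeros_like(body)
        return CompartmentMap(body, empty, empty.copy(), body.copy(), truncated)

    wall_filled = ndimage.binary_fill_holes(wall)
    holes = wall_filled & ~wall
    cavity = np.zeros_like(body)
    if holes.any():
        # 4-connectivity for holes (complement of the 8-connected band)
        hlab, hn = ndimage.label(holes)
        hsizes = ndimage.sum_labels(np.ones_like(hlab), hlab, index=np.arange(1, hn + 1))
        cavity = hlab == (1 + int(np.argmax(hsizes)))
    wall_band = (wall | holes) & ~cavity
    subcut_zone = body & ~wall_filled
    cm = CompartmentMap(body, wall_band, cavity, subcut_zone, truncated)
    cm.validate()
    return cm


def _components_touching(mask: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Union of 8-connected components of ``mask`` adjacent to ``anchor``."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    near = ndimage.binary_dilation(anchor, structure=np.ones((3, 3)))
    hit = np.unique(lab[near & (lab > 0)])
    return np.isin(lab, hit[hit > 0])


def segment(
    slice_: CTSlice,
    compartments: CompartmentMap,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> LabelMask:
    """Classify body pixels into muscle / SAT / VAT / IMAT / other.

    Muscle is the muscle window inside the wall band; SAT the SAT window in
    the subcutaneous zone; VAT the VAT window in the visceral cavity; IMAT
    the SAT window inside the wall band.  All window bounds are inclusive.
    Remaining body pixels are labelled "other".
    """
    hu = slice_.hu
    if hu.shape != compartments.body.shape:
        raise ValueError("slice and compartment shapes differ")
    labels = np.zeros(hu.shape, dtype=np.int16)
    body = compartments.body
    labels[body] = _ID["other"]
    labels[compartments.wall_band & thresholds.window(hu, "muscle")] = _ID["muscle"]
    labels[compartments.wall_band & thresholds.window(hu, "sat")] = _ID["imat"]
    labels[compartments.subcutaneous_zone & thresholds.window(hu, "sat")] = _ID["sat"]
    labels[compartments.visceral_cavity & thresholds.window(hu, "vat")] = _ID["vat"]
    return LabelMask(labels, dict(SEGMENT_LEGEND))
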