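"""Reading and writing CT slices, label masks, and cohort tables.

All images are handled in calibrated Hounsfield units (HU).  Stored values
are converted at read time via the DICOM rescale slope/intercept; nothing
downstream ever sees raw stored values.  Pixel spacing is mandatory because
every area in the pipeline is physical (cm²).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTSlice",
    "LabelMask",
    "HU_PLAUSIBLE_RANGE",
    "read_ct",
    "write_ct_nifti",
    "write_ct_dicom",
    "read_labels",
    "write_labels",
    "read_cohort",
    "write_cohort",
    "COHORT_REQUIRED_COLUMNS",
]

#: HU values outside this interval trigger a plausibility warning (air is
#: about -1000; dense cortical bone rarely exceeds ~3000).
HU_PLAUSIBLE_RANGE = (-1100.0, 3100.0)


@dataclass
class CTSlice:
    """A single axial CT slice in calibrated Hounsfield units.

    Parameters
    ----------
    hu:
        2-D float array of HU values, row-major, origin top-left.
    pixel_spacing:
        (row, column) spacing in millimetres; both strictly positive.
    slice_id:
        Free-form label (e.g. filename stem or slice index).
    """

    hu: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 2:
            raise ValueError(f"hu must be 2-D, got shape {self.hu.shape}")
        sr, sc = float(self.pixel_spacing[0]), float(self.pixel_spacing[1])
        if sr <= 0 or sc <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {(sr, sc)}")
        self.pixel_spacing = (sr, sc)
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("hu contains non-finite values")
        lo, hi = HU_PLAUSIBLE_RANGE
        if self.hu.min() < lo or self.hu.max() > hi:
            warnings.warn(
                f"slice {self.slice_id!r}: HU outside plausible range "
                f"[{lo}, {hi}] ({self.hu.min():.0f}..{self.hu.max():.0f})",
                stacklevel=2,
            )

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass
class LabelMask:
    """Integer label image aligned with a :class:`CTSlice`.

    ``legend`` maps each nonzero label to a tissue name; 0 is background.
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from legend")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask for all labels whose legend entry equals ``name``."""
        ids = [k for k, v in self.legend.items() if v == name]
        return np.isin(self.labels, ids)


# ---------------------------------------------------------------------------
# CT image I/O


def read_ct(path: str | Path, format: str | None = None) -> list[CTSlice]:
    """Read a CT volume or single slice into a list of :class:`CTSlice`.

    ``format`` is ``"nifti"`` or ``"dicom"``; inferred from the extension
    when omitted.  DICOM files must carry PixelSpacing and RescaleSlope /
    RescaleIntercept — areas and HU would otherwise be wrong, so their
    absence is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom" if path.suffix.lower() == ".dcm" else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Path) -> list[CTSlice]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()
    if len(zooms) < 2 or zooms[0] <= 0 or zooms[1] <= 0:
        raise ValueError(f"{path}: missing or non-positive pixel spacing (pixdim)")
    spacing = (float(zooms[0]), float(zooms[1]))
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2-D or 3-D image, got {data.ndim}-D")
    return [
        CTSlice(data[:, :, k], spacing, slice_id=f"{path.stem}[{k}]")
        for k in range(data.shape[2])
    ]


def _read_dicom(path: Path) -> list[CTSlice]:
    import pydicom

    if path.is_dir():
        files = sorted(path.glob("*.dcm"))
        if not files:
            raise FileNotFoundError(f"no .dcm files in {path}")
        datasets = [pydicom.dcmread(str(f)) for f in files]
        # order by position along the slice axis when available
        try:
            datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        except (AttributeError, TypeError):
            pass
    else:
        datasets = [pydicom.dcmread(str(path))]

    slices = []
    for ds in datasets:
        for attr in ("PixelSpacing", "RescaleSlope", "RescaleIntercept"):
            if getattr(ds, attr, None) is None:
                raise ValueError(f"{path}: DICOM attribute {attr} is missing")
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        slices.append(CTSlice(hu, spacing, slice_id=str(getattr(ds, "InstanceNumber", ""))))
    return slices


def write_ct_nifti(slices: Sequence[CTSlice], path: str | Path) -> Path:
    """Write a stack of slices (identical shape/spacing) as a NIfTI-1 volume."""
    path = Path(path)
    _check_uniform(slices)
    vol = np.stack([s.hu for s in slices], axis=2).astype(np.float32)
    sr, sc = slices[0].pixel_spacing
    affine = np.diag([sr, sc, 1.0, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((sr, sc, 1.0))
    nib.save(img, str(path))
    return path


def write_ct_dicom(slice_: CTSlice, path: str | Path) -> Path:
    """Write one slice as a minimal single-frame CT DICOM file.

    Stored values are ``HU + 1024`` with RescaleSlope=1 and
    RescaleIntercept=-1024, so any conformant reader decodes back to HU.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = slice_.hu.shape
    ds.PixelSpacing = [slice_.pixel_spacing[0], slice_.pixel_spacing[1]]
    ds.RescaleSlope = 1
    ds.RescaleIntercept = -1024
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    stored = np.clip(np.rint(slice_.hu) + 1024, 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_labels(path: str | Path) -> list[LabelMask]:
    """Read an integer label volume; the legend comes from a JSON sidecar
    ``<path>.legend.json`` when present."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.int32)
    if data.ndim == 2:
        data = data[..., None]
    sidecar = path.with_name(path.name + ".legend.json")
    if sidecar.exists():
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        legend = {int(k): f"label_{int(k)}" for k in np.unique(data) if k != 0}
    return [LabelMask(data[:, :, k], dict(legend)) for k in range(data.shape[2])]


def write_labels(masks: Sequence[LabelMask], path: str | Path) -> Path:
    path = Path(path)
    vol = np.stack([m.labels for m in masks], axis=2).astype(np.int16)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    legend = masks[0].legend
    sidecar = path.with_name(path.name + ".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=1))
    return path


def _check_uniform(slices: Sequence[CTSlice]) -> None:
    if not slices:
        raise ValueError("empty slice list")
    shape = slices[0].hu.shape
    spacing = slices[0].pixel_spacing
    for s in slices[1:]:
        if s.hu.shape != shape or s.pixel_spacing != spacing:
            raise ValueError("slices differ in shape or spacing")


# ---------------------------------------------------------------------------
# Cohort table I/O

#: Minimum columns of a subject table.  weight in kg, height in m,
#: DXA reference masses in kg.
COHORT_REQUIRED_COLUMNS = ("id", "weight", "height")

_NUMERIC_COLUMNS = ("weight", "height", "bmi", "dxa_fm", "dxa_ffm", "dxa_asmm", "dxa_asmmi")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject table (comma-separated, UTF-8, header row).

    Computes ``bmi = weight / height**2`` when absent, checks row-level
    numeric validity, and rejects duplicate ids.  DXA columns are optional;
    when both masses are present, ``dxa_fm + dxa_ffm`` may not exceed body
    weight by more than 5 % (DXA excludes some mass, it never adds any).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty cohort table", stacklevel=2)
        return df
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad_rows: list[str] = []
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            bad_rows.append(f"row {i}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = coerced
    if bad_rows:
        raise ValueError("invalid cohort rows:\n" + "\n".join(bad_rows))

    dup = df["id"][df["id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate subject ids: {dup}")
    if (df["weight"] <= 0).any() or (df["height"] <= 0).any():
        raise ValueError("weight and height must be strictly positive")

    if "bmi" not in df.columns:
        df["bmi"] = df["weight"] / df["height"] ** 2
    if {"dxa_fm", "dxa_ffm"}.issubset(df.columns):
        excess = df["dxa_fm"] + df["dxa_ffm"] > df["weight"] * 1.05
        if excess.any():
            raise ValueError(
                f"dxa_fm + dxa_ffm exceeds weight by >5% for ids "
                f"{df.loc[excess, 'id'].tolist()}"
            )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
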