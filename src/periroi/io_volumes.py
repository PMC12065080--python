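"""Volume and mask I/O with exact physical geometry, plus the case manifest.

Index convention is fixed package-wide: arrays are indexed ``(z, y, x)``,
0-based, with half-open ranges. Physical coordinates are LPS millimetres.
Geometry metadata (``spacing``, ``origin``, ``direction``) is stored in the
ITK physical order ``(x, y, z)``; the convenience property ``spacing_zyx``
gives per-array-axis voxel sizes for spacing-aware array operations.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "CaseRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_manifest",
    "EmptyMaskWarning",
]

_ORTHO_TOL = 1e-6

MANIFEST_COLUMNS = (
    "case_id",
    "image_path",
    "tumor_mask_path",
    "parenchyma_mask_path",
    "label",
    "cohort",
)

COHORTS = ("train", "val1", "val2")

#: Strings accepted for the positive (luminal) and negative (nonluminal) class.
#: The tumor-subtype task is binary: luminal = 1, every nonluminal subtype
#: (HER-2-enriched, triple-negative) = 0.
_LABEL_MAP = {
    "luminal": 1,
    "nonluminal": 0,
    "non-luminal": 0,
    "her-2": 0,
    "her2": 0,
    "her-2 enriched": 0,
    "triple-negative": 0,
    "triple negative": 0,
    "tnbc": 0,
    "1": 1,
    "0": 0,
}


class EmptyMaskWarning(UserWarning):
    """A mask contained no positive voxels (allowed at read time)."""


def _check_direction(direction: np.ndarray) -> np.ndarray:
    """Validate (and, for header round-off, re-orthonormalize) a direction matrix.

    The stored invariant is ||D^T D - I|| < 1e-6. File headers carry limited
    precision, so deviations up to 1e-4 are projected back onto the nearest
    orthonormal matrix (polar decomposition); anything larger is an error.
    """
    d = np.asarray(direction, dtype=float).reshape(3, 3)
    if not np.all(np.isfinite(d)):
        raise ValueError("direction matrix contains non-finite entries")
    dev = np.abs(d.T @ d - np.eye(3)).max()
    if dev > 1e-4:
        raise ValueError(
            f"direction matrix is not orthonormal (max |D^T D - I| = {dev:.2e})"
        )
    if dev > _ORTHO_TOL:
        u, _, vt = np.linalg.svd(d)
        d = u @ vt
    return d


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data
        ``(z, y, x)`` array of intensities (arbitrary units).
    spacing, origin
        Physical ``(x, y, z)`` voxel size / position of voxel (0,0,0), in mm.
    direction
        Row-major 3x3 orthonormal axis-orientation matrix (ITK convention).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in np.asarray(self.direction).ravel())
        if len(self.direction) != 9:
            raise ValueError("direction must be a 3x3 matrix")
        self.direction = tuple(_check_direction(np.asarray(self.direction)).ravel())

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (z, y, x)

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel size per array axis ``(z, y, x)`` in mm."""
        return (self.spacing[2], self.spacing[1], self.spacing[0])

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.direction)

    def same_geometry(self, other: "ImageVolume | MaskVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass
class MaskVolume(ImageVolume):
    """Binary grid sharing an :class:`ImageVolume` geometry. Values in {0, 1}."""

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0).astype(np.uint8)
        super().__post_init__()

    @property
    def n_positive(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_positive == 0


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    image_path: str
    tumor_mask_path: str
    parenchyma_mask_path: Optional[str]
    label: int
    cohort: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")


# -- SimpleITK bridge -------------------------------------------------------

def to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(vol.direction)
    return img


def from_sitk(img: sitk.Image, as_mask: bool = False) -> ImageVolume:
    data = sitk.GetArrayFromImage(img)
    cls = MaskVolume if as_mask else ImageVolume
    return cls(
        data=data,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


# -- readers / writers ------------------------------------------------------

def _read_dicom_series(directory: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(directory))
    if not series_ids:
        raise ValueError(f"no DICOM series found in {directory}")
    if len(series_ids) > 1:
        raise ValueError(
            f"directory {directory} holds {len(series_ids)} DICOM series; "
            f"candidates: {', '.join(series_ids)}"
        )
    # GDCM orders files by ImagePositionPatient projected on the slice normal,
    # which is robust to renumbered InstanceNumber exports.
    files = reader.GetGDCMSeriesFileNames(str(directory), series_ids[0])
    reader.SetFileNames(files)
    return reader.Execute()


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI file or a single-series DICOM directory.

    Intensities are returned unchanged apart from the DICOM rescale
    slope/intercept applied by the reader; geometry comes verbatim from the
    file headers.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if p.is_dir():
        img = _read_dicom_series(p)
    else:
        try:
            img = sitk.ReadImage(str(p))
        except RuntimeError as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"unreadable image file {p}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{p}: expected a 3D volume, got {img.GetDimension()}D")
    vol = from_sitk(img)
    vol.data = vol.data.astype(np.float64, copy=False)
    return vol


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(to_sitk(vol), str(path))


def read_mask(path: str | os.PathLike, reference: ImageVolume) -> MaskVolume:
    """Read an aligned binary mask; any nonzero voxel becomes 1.

    The returned geometry is copied from ``reference``; the stored grid must
    match the reference shape exactly. An all-zero mask is allowed but raises
    :class:`EmptyMaskWarning`.
    """
    p = Path(path)
    img = sitk.ReadImage(str(p))
    data = sitk.GetArrayFromImage(img)
    if data.shape != reference.shape:
        raise ValueError(
            f"mask {p} shape {data.shape} does not match reference shape {reference.shape}"
        )
    mask = MaskVolume(
        data=data,
        spacing=reference.spacing,
        origin=reference.origin,
        direction=reference.direction,
    )
    if mask.is_empty:
        warnings.warn(f"mask {p} contains no positive voxels", EmptyMaskWarning)
    return mask


def write_mask(mask: MaskVolume, path: str | os.PathLike) -> None:
    write_volume(mask, path)


# -- manifest ---------------------------------------------------------------

def _map_label(raw) -> int:
    if isinstance(raw, (int, np.integer)) or (
        isinstance(raw, float) and float(raw).is_integer()
    ):
        val = int(raw)
        if val in (0, 1):
            return val
        raise ValueError(f"unknown numeric label {raw!r} (expected 0/1)")
    key = str(raw).strip().lower()
    if key in _LABEL_MAP:
        return _LABEL_MAP[key]
    raise ValueError(
        f"unknown label {raw!r}; expected 0/1 or one of {sorted(set(_LABEL_MAP))}"
    )


def load_manifest(path: str | os.PathLike) -> list[CaseRecord]:
    """Load and validate a case manifest CSV.

    Required header: ``case_id,image_path,tumor_mask_path,parenchyma_mask_path,
    label,cohort``. Labels may be 0/1 or subtype strings (luminal -> 1,
    HER-2 / triple-negative / nonluminal -> 0); cohorts are restricted to
    ``train``/``val1``/``val2``.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {', '.join(missing)}")
    dupes = df["case_id"][df["case_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate case_id(s) in manifest: {', '.join(map(str, dupes))}")
    records = []
    for row in df.itertuples(index=False):
        paren = row.parenchyma_mask_path
        if paren is None or (isinstance(paren, float) and np.isnan(paren)) or str(paren) == "":
            paren = None
        records.append(
            CaseRecord(
                case_id=str(row.case_id),
                image_path=str(row.image_path),
                tumor_mask_path=str(row.tumor_mask_path),
                parenchyma_mask_path=None if paren is None else str(paren),
                label=_map_label(row.label),
                cohort=str(row.cohort).strip(),
            )
        )
    return records


def write_manifest(records: Sequence[CaseRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "image_path": r.image_path,
                "tumor_mask_path": r.tumor_mask_path,
                "parenchyma_mask_path": r.parenchyma_mask_path or "",
                "label": r.label,
                "cohort": r.cohort,
            }
            for r in records
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
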