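"""Model-ready sample extraction: five ROI dimensionality modes (2D, three
2.5D variants, 3D) under two masking scenarios.

Modes
-----
``2D``
    The single axial slice with maximal in-mask area, replicated into three
    identical channels (planar backbones expect 3 channels).
``2.5D1``
    The three orthogonal planes (axial, coronal, sagittal) through the mask
    centroid — the "three primary slices of the minimum bounding cube".
``2.5D2``
    The max-area axial slice plus its neighbours at offsets {-k, 0, +k}
    (default k = 2), encoding local through-plane continuity.
``2.5D3``
    Per view (axial, coronal, sagittal) independently, the slice with
    maximal in-mask area.
``3D``
    The bounding-cube crop resampled to a cubic patch, single channel.

Scenarios
---------
``ROI_only`` zeroes (fills) every voxel outside the effective mask before
cropping; ``ROI_original`` keeps native surrounding tissue and relies on the
crop alone to limit context. Both scenarios are framed by the bounding cube
of the *expanded* mask, so they differ only in masking, never in framing.

All slice/centroid selections are deterministic (ties break to the lower
index; centroid indices round half-down) and the pre-resize crops are kept
on the returned :class:`Extraction` so every selection can be checked
against exhaustive oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .io_volumes import ImageVolume, MaskVolume
from .peritumoral import clip_to_parenchyma, expand_mask

__all__ = [
    "MODES",
    "SCENARIOS",
    "RoiSpec",
    "BoundingBox",
    "Extraction",
    "effective_mask",
    "apply_scenario",
    "bounding_cube",
    "extract_2d",
    "extract_25d1",
    "extract_25d2",
    "extract_25d3",
    "extract_3d",
    "extract",
]

MODES = ("2D", "2.5D1", "2.5D2", "2.5D3", "3D")
SCENARIOS = ("ROI_only", "ROI_original")

#: canonical channel order for the three-plane modes
CHANNEL_ORDER = ("axial", "coronal", "sagittal")


@dataclass(frozen=True)
class RoiSpec:
    """One cell of the configuration grid.

    ``out_size`` is the planar target side (pixels) for 2D/2.5D modes;
    ``out_size_3d`` the cubic patch side for 3D mode. ``fill_value`` is the
    intensity written outside the mask under ROI_only; with z-scored inputs
    the default 0 is the cohort-typical intensity, avoiding step artifacts.
    """

    mode: str = "2.5D1"
    radius_mm: float = 0.0
    scenario: str = "ROI_original"
    out_size: int = 224
    out_size_3d: int = 64
    slice_offset: int = 2
    fill_value: float = 0.0
    pad_vox: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        if self.out_size < 1 or self.out_size_3d < 1:
            raise ValueError("out sizes must be positive")
        if self.slice_offset < 1:
            raise ValueError("slice_offset must be >= 1")
        if self.pad_vox < 0:
            raise ValueError("pad_vox must be >= 0")


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis half-open index ranges [lo, hi), (z, y, x) order."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    is_cube: bool  #: False when grid clamping broke equal side lengths

    def __post_init__(self) -> None:
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate bounding box {self.lo}..{self.hi}")

    @property
    def sides(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass
class Extraction:
    """A model-ready sample plus its provenance.

    ``sample`` is ``(3, out_size, out_size)`` for planar modes or
    ``(1, s, s, s)`` for 3D. ``crops`` holds the pre-resize crops (one 2D
    array per channel, or the 3D crop), which are the lossless intermediate
    the oracles compare against.
    """

    sample: np.ndarray
    spec: RoiSpec
    bbox: BoundingBox
    crops: list[np.ndarray] = field(default_factory=list)
    slice_indices: dict[str, int] = field(default_factory=dict)
    case_id: Optional[str] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.sample)):
            raise ValueError("extracted sample contains non-finite values")


# -- building blocks --------------------------------------------------------

def effective_mask(
    tumor: MaskVolume,
    radius_mm: float,
    parenchyma: Optional[MaskVolume] = None,
) -> MaskVolume:
    """The expanded (and optionally parenchyma-clipped) mask.

    This single mask defines both the bounding geometry and the keep-set for
    the ROI_only scenario.
    """
    res = expand_mask(tumor, radius_mm)
    if parenchyma is not None:
        res = clip_to_parenchyma(res, parenchyma, tumor)
    return res.expanded


def apply_scenario(vol: ImageVolume, m: MaskVolume, spec: RoiSpec) -> ImageVolume:
    """ROI_only: fill everything outside ``m``; ROI_original: identity."""
    if not vol.same_geometry(m):
        raise ValueError("volume and mask geometries do not match")
    if spec.scenario == "ROI_original":
        return vol
    data = np.where(m.data > 0, vol.data, spec.fill_value)
    return vol.with_data(data)


def bounding_cube(m: MaskVolume, pad_vox: int = 0) -> BoundingBox:
    """Minimum bounding cube of a mask.

    The tight per-axis box is expanded symmetrically to equal side lengths
    (odd leftovers go to the high side), padded by ``pad_vox`` on every
    face, then clamped to the grid. Clamping can break exact cubicity; the
    ``is_cube`` flag records whether it did.
    """
    if m.is_empty:
        raise ValueError("cannot bound an empty mask")
    pos = np.argwhere(m.data > 0)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0) + 1
    side = int((hi - lo).max()) + 2 * pad_vox
    out_lo, out_hi = [], []
    for ax in range(3):
        extra = side - (hi[ax] - lo[ax])
        a = int(lo[ax]) - extra // 2
        b = int(hi[ax]) + (extra - extra // 2)
        a_cl = max(a, 0)
        b_cl = min(b, m.shape[ax])
        out_lo.append(a_cl)
        out_hi.append(b_cl)
    sides = [h - l for l, h in zip(out_lo, out_hi)]
    return BoundingBox(tuple(out_lo), tuple(out_hi), is_cube=len(set(sides)) == 1)


def _resize_plane(plane: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize (no aspect preservation; the cube crop keeps distortion
    minimal). Deterministic; no anti-aliasing so values stay interpolation-only."""
    if plane.shape == (out_size, out_size):
        return plane.astype(np.float64, copy=True)
    return _sk_resize(
        plane.astype(np.float64),
        (out_size, out_size),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
        mode="edge",
    )


def _resize_patch(patch: np.ndarray, out_size: int) -> np.ndarray:
    if patch.shape == (out_size,) * 3:
        return patch.astype(np.float64, copy=True)
    return _sk_resize(
        patch.astype(np.float64),
        (out_size,) * 3,
        order=1,
        preserve_range=True,
        anti_aliasing=False,
        mode="edge",
    )


def _centroid_indices(m: MaskVolume) -> tuple[int, int, int]:
    """Mean positive-voxel index per axis, rounded half-down (2.5 -> 2)."""
    pos = np.argwhere(m.data > 0)
    c = pos.mean(axis=0)
    return tuple(int(np.ceil(ci - 0.5)) for ci in c)


def _max_area_index(m: MaskVolume, axis: int) -> int:
    """Index of the slice (along ``axis``) with maximal in-mask area; ties
    break to the lower index (np.argmax returns the first maximum)."""
    areas = m.data.sum(axis=tuple(a for a in range(3) if a != axis))
    return int(np.argmax(areas))


def _plane(data: np.ndarray, view: str, index: int, bbox: BoundingBox) -> np.ndarray:
    """Extract one view plane cropped to the corresponding bounding-cube face.

    axial (fixed z) -> (y, x); coronal (fixed y) -> (z, x);
    sagittal (fixed x) -> (z, y).
    """
    (z0, y0, x0), (z1, y1, x1) = bbox.lo, bbox.hi
    if view == "axial":
        return data[index, y0:y1, x0:x1]
    if view == "coronal":
        return data[z0:z1, index, x0:x1]
    if view == "sagittal":
        return data[z0:z1, y0:y1, index]
    raise ValueError(f"unknown view {view!r}")


def _stack_planar(crops: Sequence[np.ndarray], out_size: int) -> np.ndarray:
    return np.stack([_resize_plane(c, out_size) for c in crops], axis=0)


# -- mode extractors --------------------------------------------------------

def extract_25d1(vol: ImageVolume, m: MaskVolume, spec: RoiSpec) -> Extraction:
    """Three orthogonal planes through the mask centroid (axial, coronal,
    sagittal), each cropped to the bounding cube's matching face."""
    bbox = bounding_cube(m, spec.pad_vox)
    cz, cy, cx = _centroid_indices(m)
    idx = {"axial": cz, "coronal": cy, "sagittal": cx}
    crops = [_plane(vol.data, v, idx[v], bbox) for v in CHANNEL_ORDER]
    return Extraction(
        sample=_stack_planar(crops, spec.out_size),
        spec=spec,
        bbox=bbox,
        crops=list(crops),
        slice_indices=idx,
    )


def extract_25d2(vol: ImageVolume, m: MaskVolume, spec: RoiSpec) -> Extraction:
    """Central (max-area) axial slice with neighbours at +/- ``slice_offset``.

    Offsets are clamped to the mask's occupied axial range, so a single-slice
    lesion yields three identical channels; clamping is recorded.
    """
    bbox = bounding_cube(m, spec.pad_vox)
    center = _max_area_index(m, axis=0)
    zs = np.flatnonzero(m.data.sum(axis=(1, 2)) > 0)
    z_lo, z_hi = int(zs[0]), int(zs[-1])
    wanted = [center - spec.slice_offset, center, center + spec.slice_offset]
    chosen = [min(max(w, z_lo), z_hi) for w in wanted]
    crops = [_plane(vol.data, "axial", z, bbox) for z in chosen]
    return Extraction(
        sample=_stack_planar(crops, spec.out_size),
        spec=spec,
        bbox=bbox,
        crops=list(crops),
        slice_indices={"lower": chosen[0], "central": chosen[1], "upper": chosen[2]},
        notes={"clamped": chosen != wanted, "axial_extent": (z_lo, z_hi)},
    )


def extract_25d3(vol: ImageVolume, m: MaskVolume, spec: RoiSpec) -> Extraction:
    """Per-view max-area slices (axial, coronal, sagittal independently)."""
    bbox = bounding_cube(m, spec.pad_vox)
    idx = {
        "axial": _max_area_index(m, 0),
        "coronal": _max_area_index(m, 1),
        "sagittal": _max_area_index(m, 2),
    }
    crops = [_plane(vol.data, v, idx[v], bbox) for v in CHANNEL_ORDER]
    return Extraction(
        sample=_stack_planar(crops, spec.out_size),
        spec=spec,
        bbox=bbox,
        crops=list(crops),
        slice_indices=idx,
    )


def extract_2d(vol: ImageVolume, m: MaskVolume, spec: RoiSpec) -> Extraction:
    """Single max-area axial slice replicated into three channels."""
    bbox = bounding_cube(m, spec.pad_vox)
    z = _max_area_index(m, 0)
    crop = _plane(vol.data, "axial", z, bbox)
    return Extraction(
        sample=_stack_planar([crop, crop, crop], spec.out_size),
        spec=spec,
        bbox=bbox,
        crops=[crop],
        slice_indices={"axial": z},
    )


def extract_3d(vol: ImageVolume, m: MaskVolume, spec: RoiSpec) -> Extraction:
    """Bounding-cube crop resampled (trilinear) to a cubic patch."""
    bbox = bounding_cube(m, spec.pad_vox)
    crop = vol.data[bbox.slices()]
    patch = _resize_patch(crop, spec.out_size_3d)
    return Extraction(
        sample=patch[np.newaxis],
        spec=spec,
        bbox=bbox,
        crops=[crop],
        slice_indices={},
    )


_EXTRACTORS = {
    "2D": extract_2d,
    "2.5D1": extract_25d1,
    "2.5D2": extract_25d2,
    "2.5D3": extract_25d3,
    "3D": extract_3d,
}


def extract(
    vol: ImageVolume,
    tumor: MaskVolume,
    spec: RoiSpec,
    parenchyma: Optional[MaskVolume] = None,
    case_id: Optional[str] = None,
) -> Extraction:
    """Full dispatch: effective mask -> scenario masking -> mode extractor.

    The ROI_original crop is framed by the SAME bounding cube as ROI_only
    (the cube of the expanded mask), so the two scenarios differ only in
    masking, not framing.
    """
    m = effective_mask(tumor, spec.radius_mm, parenchyma)
    masked = apply_scenario(vol, m, spec)
    ext = _EXTRACTORS[spec.mode](masked, m, spec)
    ext.case_id = case_id
    return ext
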