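"""Volume standardization: z-score intensity normalization, isotropic
resampling, and bias-field correction.

The default pipeline order is z-score -> resample -> bias-correct. Bias
correction conventionally precedes intensity normalization; the
``bias_first`` flag switches to that order (N4 on raw intensities, then
z-score, then resample). Both orders are exposed because neither is uniquely
"right" for multicenter DCE-MRI and the choice is auditable in the run
config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import SimpleITK as sitk

from .io_volumes import ImageVolume, MaskVolume, from_sitk, to_sitk

__all__ = [
    "PreprocessConfig",
    "zscore_normalize",
    "resample_isotropic",
    "bias_field_correct",
    "preprocess_case",
]


@dataclass
class PreprocessConfig:
    """Knobs for the standardization pipeline.

    target_spacing is in mm per (x, y, z) axis; 1 mm isotropic by default so
    physical expansion radii map to voxel counts directly. Masks are always
    resampled nearest-neighbour to stay binary.
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    normalize: Literal["zscore", "none"] = "zscore"
    bias_correction: Literal["n4", "polynomial", "none"] = "n4"
    bias_first: bool = False
    n4_shrink: int = 2
    n4_iterations: tuple[int, ...] = (20, 20, 20)
    poly_degree: int = 3

    def __post_init__(self) -> None:
        self.target_spacing = tuple(float(s) for s in self.target_spacing)
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be strictly positive")


def zscore_normalize(vol: ImageVolume) -> ImageVolume:
    """Standardize intensities to zero mean, unit (population) sd.

    Statistics are computed over all voxels of the single volume, so no
    cross-case state is needed and per-center global gain/offset differences
    are removed exactly.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if data.size <= 1:
        raise ValueError("z-score normalization needs more than one voxel")
    mean = data.mean()
    sd = data.std()  # population (ddof=0) sd: {0,2} -> {-1,+1}
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a zero-variance volume")
    return vol.with_data((data - mean) / sd)


def _resample(vol: ImageVolume, target_spacing, interp) -> sitk.Image:
    img = to_sitk(vol)
    old_spacing = np.asarray(img.GetSpacing())
    old_size = np.asarray(img.GetSize())
    new_spacing = np.asarray(target_spacing, dtype=float)
    # preserve physical extent to within one voxel per axis
    new_size = np.maximum(1, np.round(old_size * old_spacing / new_spacing)).astype(int)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(new_spacing))
    res.SetSize([int(s) for s in new_size])
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interp)
    res.SetDefaultPixelValue(0.0)
    return res.Execute(img)


def resample_isotropic(
    vol: ImageVolume, config: Optional[PreprocessConfig] = None
) -> ImageVolume:
    """Resample to the configured (default 1 mm isotropic) grid.

    Linear interpolation for images, nearest-neighbour for masks (dispatch on
    the input type). The output grid size is ``round(extent / new_spacing)``
    per axis, so the physical extent is preserved to within one voxel.
    """
    config = config or PreprocessConfig()
    is_mask = isinstance(vol, MaskVolume)
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    img = _resample(vol, config.target_spacing, interp)
    out = from_sitk(img, as_mask=is_mask)
    if min(out.shape) < 1:
        raise ValueError("resampling produced a degenerate (zero-size) grid")
    if not is_mask:
        out.data = out.data.astype(np.float64, copy=False)
    return out


def _poly_design(shape: tuple[int, int, int], degree: int) -> np.ndarray:
    """Design matrix of 3D monomials up to total degree `degree` on [-1,1]^3."""
    zz, yy, xx = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape],
        indexing="ij",
    )
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append((zz**i) * (yy**j) * (xx**k))
    return np.stack([c.ravel() for c in cols], axis=1)


def _polynomial_field(data: np.ndarray, degree: int) -> np.ndarray:
    """Estimate a smooth multiplicative bias field by a log-domain polynomial fit."""
    log = np.log(data)
    A = _poly_design(data.shape, degree)
    coef, *_ = np.linalg.lstsq(A, log.ravel(), rcond=None)
    fit = (A @ coef).reshape(data.shape)
    fit -= fit.mean()  # mean-one field: correct shading, keep overall level
    return np.exp(fit)


def bias_field_correct(
    vol: ImageVolume, config: Optional[PreprocessConfig] = None
) -> ImageVolume:
    """Divide out a smooth, strictly positive estimated bias field.

    method "n4" uses the ITK N4 algorithm (B-spline field, shrink factor and
    iteration schedule from config); "polynomial" fits a degree-3 polynomial
    to the log intensities, which is adequate for the slowly varying shading
    this pipeline targets. Non-positive inputs are shifted internally (the
    offset is restored afterwards, so z-scored inputs are handled).
    """
    config = config or PreprocessConfig()
    data = np.asarray(vol.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite voxels")
    if config.bias_correction == "none":
        return vol.with_data(data)
    lo = data.min()
    rng = data.max() - lo
    if rng == 0:
        return vol.with_data(data)  # uniform volume: nothing to correct
    offset = 0.0
    if lo <= 0:
        offset = -lo + 1e-3 * rng  # make intensities strictly positive
        data = data + offset

    if config.bias_correction == "polynomial":
        corrected = data / _polynomial_field(data, config.poly_degree)
    else:
        img = to_sitk(vol.with_data(data))
        shrunk = img
        if config.n4_shrink > 1:
            shrunk = sitk.Shrink(img, [config.n4_shrink] * 3)
        n4 = sitk.N4BiasFieldCorrectionImageFilter()
        n4.SetMaximumNumberOfIterations(list(config.n4_iterations))
        n4.Execute(shrunk)
        log_field = n4.GetLogBiasFieldAsImage(img)
        field = np.exp(sitk.GetArrayFromImage(log_field))
        corrected = data / field

    return vol.with_data(corrected - offset)


def preprocess_case(
    vol: ImageVolume,
    masks: Optional[dict[str, MaskVolume]] = None,
    config: Optional[PreprocessConfig] = None,
) -> tuple[ImageVolume, dict[str, MaskVolume]]:
    """Run the full standardization pipeline on a volume and aligned masks.

    Default order: z-score -> resample -> bias-correct. With
    ``config.bias_first`` the bias field is removed from raw intensities
    first, then z-score and resampling follow. Masks are resampled
    nearest-neighbour onto the same target grid.
    """
    config = config or PreprocessConfig()
    masks = dict(masks or {})

    def _norm(v):
        return zscore_normalize(v) if config.normalize == "zscore" else v

    if config.bias_first:
        vol = bias_field_correct(vol, config)
        vol = _norm(vol)
        vol = resample_isotropic(vol, config)
    else:
        vol = _norm(vol)
        vol = resample_isotropic(vol, config)
        vol = bias_field_correct(vol, config)

    out_masks = {k: resample_isotropic(m, config) for k, m in masks.items()}
    for k, m in out_masks.items():
        if m.shape != vol.shape:
            raise ValueError(f"mask '{k}' resampled to {m.shape}, image is {vol.shape}")
    return vol, out_masks
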