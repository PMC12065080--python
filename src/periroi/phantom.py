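"""Synthetic breast-MRI-like phantoms with labelled lesions.

Each case is a smooth parenchyma texture plus Gaussian noise, containing one
compact lobulated lesion. The binary class signal is an additive mean shift
(in units of the noise sd) planted either inside the lesion (intratumoral)
or in a distance band outside it (peritumoral shell), with shell distances
computed exactly as the peritumoral expansion does. Multicenter acquisition
is emulated by a per-center global gain/offset. An additive mean shift (not
texture) keeps the Bayes-optimal separability analytically controllable.

Determinism: one global seed streams per-case seeds through
``numpy.random.SeedSequence`` spawn keys, so any case can be regenerated
independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .io_volumes import CaseRecord, ImageVolume, MaskVolume, write_manifest, write_mask, write_volume
from .peritumoral import distance_to_mask_mm

__all__ = ["PhantomConfig", "PhantomCase", "Cohort", "generate_case", "generate_cohort"]


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 48^3 grid at 1 mm isotropic (the pipeline's resampled
    resolution), lesions with 4-8 mm semi-axes (desk-scale versions of the
    clinical lesions) and 15% lobulated margins, class signal of 1.0 noise-sd
    planted in a 3-5 mm peritumoral shell, class-1 prevalence 0.721
    (luminal fraction of the modelled population), and three "centers" with
    +/-10% gain and +/-10 unit offset differences.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z) mm
    lesion_semiaxes_mm: tuple[float, float] = (4.0, 8.0)
    lobulation_amp: float = 0.15
    signal_site: Literal["intratumoral", "peritumoral"] = "peritumoral"
    shell_mm: tuple[float, float] = (3.0, 5.0)
    effect_size: float = 1.0
    noise_sd: float = 10.0
    texture_sd: float = 5.0
    texture_scale_mm: float = 6.0
    background_level: float = 100.0
    air_level: float = 5.0
    lesion_contrast: float = 30.0
    prevalence: float = 0.721
    n_centers: int = 3
    center_gain: tuple[float, float] = (0.9, 1.1)
    center_offset: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.shell_mm[0] >= self.shell_mm[1]:
            raise ValueError("shell inner distance must be < outer distance")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_centers < 1:
            raise ValueError("n_centers must be >= 1")


@dataclass
class PhantomCase:
    case_id: str
    image: ImageVolume
    tumor: MaskVolume
    parenchyma: MaskVolume
    label: int
    cohort: str = "train"
    center: int = 0


@dataclass
class Cohort:
    cases: list[PhantomCase]
    records: list[CaseRecord]
    config: PhantomConfig


def _coords_mm(shape, spacing_zyx):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing_zyx)]
    return np.meshgrid(*axes, indexing="ij")


def _lobulated_lesion(
    shape, spacing_zyx, center_mm, semiaxes_mm, amp, rng
) -> np.ndarray:
    """Lesion mask: ellipsoid with a smooth low-order radial perturbation.

    The boundary is rho(u) = 1 + amp * f(u) with f a random quadratic-plus-
    linear form of the unit direction (rms-normalized), which yields smooth
    lobulated margins without high-frequency speckle.
    """
    zz, yy, xx = _coords_mm(shape, spacing_zyx)
    d = np.stack([zz - center_mm[0], yy - center_mm[1], xx - center_mm[2]])
    rho = np.sqrt(sum((d[i] / semiaxes_mm[i]) ** 2 for i in range(3)))
    r = np.sqrt((d**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r > 0, d / np.maximum(r, 1e-12), 0.0)
    A = rng.normal(size=(3, 3))
    A = (A + A.T) / 2.0
    b = rng.normal(size=3)
    f = np.einsum("i...,ij,j...->...", u, A, u) + np.einsum("i,i...->...", b, u)
    f = f / max(np.sqrt((A**2).sum() / 3 + (b**2).sum() / 3), 1e-12)
    return rho <= 1.0 + amp * f


def generate_case(
    config: PhantomConfig, label: int, seed: int | np.random.SeedSequence
) -> PhantomCase:
    """Generate one phantom case, deterministic per (config, label, seed)."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = tuple(config.grid_shape)
    sp_zyx = (config.spacing[2], config.spacing[1], config.spacing[0])
    extent_mm = np.array([n * s for n, s in zip(shape, sp_zyx)])

    # parenchyma: centered ellipsoid occupying most of the grid
    zz, yy, xx = _coords_mm(shape, sp_zyx)
    center = extent_mm / 2.0
    semi = extent_mm * 0.42
    paren = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0

    # smooth texture: correlated background heterogeneity between cases
    sigma_vox = [config.texture_scale_mm / s for s in sp_zyx]
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    tex_sd = tex.std()
    if tex_sd > 0:
        tex = tex * (config.texture_sd / tex_sd)

    vol = np.where(paren, config.background_level + tex, config.air_level)

    # lesion placement: must fit inside the parenchyma
    a_lo, a_hi = config.lesion_semiaxes_mm
    tumor = None
    for _ in range(100):
        semiaxes = rng.uniform(a_lo, a_hi, size=3)
        margin = semiaxes.max() * (1 + config.lobulation_amp) + 1.0
        c = np.array(
            [rng.uniform(center[i] - semi[i] / 2, center[i] + semi[i] / 2) for i in range(3)]
        )
        cand = _lobulated_lesion(shape, sp_zyx, c, semiaxes, config.lobulation_amp, rng)
        if cand.any() and not (cand & ~paren).any():
            tumor = cand
            break
    if tumor is None:
        raise RuntimeError("lesion could not be placed inside the parenchyma in 100 attempts")

    vol = vol + np.where(tumor, config.lesion_contrast, 0.0)

    # class signal: additive mean shift in noise-sd units
    if label == 1 and config.effect_size > 0:
        shift = config.effect_size * config.noise_sd
        if config.signal_site == "intratumoral":
            vol = vol + np.where(tumor, shift, 0.0)
        else:
            tmask = MaskVolume(data=tumor, spacing=config.spacing)
            dist = distance_to_mask_mm(tmask)
            band = (dist > config.shell_mm[0]) & (dist <= config.shell_mm[1]) & paren
            vol = vol + np.where(band, shift, 0.0)

    vol = vol + rng.normal(0.0, config.noise_sd, size=shape)

    geom = dict(spacing=config.spacing)
    return PhantomCase(
        case_id="",
        image=ImageVolume(data=vol, **geom),
        tumor=MaskVolume(data=tumor, **geom),
        parenchyma=MaskVolume(data=paren, **geom),
        label=int(label),
    )


def _cohort_assignment(
    n: int, cohort_counts: Optional[tuple[int, int, int]]
) -> list[str]:
    if cohort_counts is None:
        # mirror the modelled three-cohort structure: ~25/39/36% of cases
        fracs = np.array([108, 165, 153], dtype=float)
        fracs /= fracs.sum()
        counts = np.floor(fracs * n).astype(int)
        counts[0] += n - counts.sum()
    else:
        counts = np.asarray(cohort_counts, dtype=int)
        if counts.sum() != n or (counts < 0).any():
            raise ValueError(f"cohort_counts {cohort_counts} must be >= 0 and sum to n={n}")
    return ["train"] * counts[0] + ["val1"] * counts[1] + ["val2"] * counts[2]


def generate_cohort(
    config: PhantomConfig,
    n: int,
    seed: int,
    out_dir: Optional[str | Path] = None,
    cohort_counts: Optional[tuple[int, int, int]] = None,
) -> Cohort:
    """Generate ``n`` cases with labels at the configured prevalence.

    Cases are assigned round-robin to ``config.n_centers`` centers; each
    center applies a global multiplicative gain and additive offset drawn
    once per center. If ``out_dir`` is given, volumes and masks are written
    as NIfTI plus a manifest CSV; otherwise everything stays in memory and
    the manifest paths are empty placeholders.
    """
    if n < 2:
        raise ValueError("need at least 2 cases")
    ss = np.random.SeedSequence(seed)
    label_ss, center_ss, *case_ss = ss.spawn(n + 2)
    labels = (np.random.default_rng(label_ss).random(n) < config.prevalence).astype(int)
    crng = np.random.default_rng(center_ss)
    gains = crng.uniform(*config.center_gain, size=config.n_centers)
    offsets = crng.uniform(*config.center_offset, size=config.n_centers)
    cohorts = _cohort_assignment(n, cohort_counts)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cases: list[PhantomCase] = []
    records: list[CaseRecord] = []
    width = max(3, len(str(n)))
    for i in range(n):
        case = generate_case(config, int(labels[i]), case_ss[i])
        center = i % config.n_centers
        case.image = case.image.with_data(case.image.data * gains[center] + offsets[center])
        case.case_id = f"case{i:0{width}d}"
        case.cohort = cohorts[i]
        case.center = center
        cases.append(case)

        if out is not None:
            img_p = out / f"{case.case_id}_image.nii.gz"
            tum_p = out / f"{case.case_id}_tumor.nii.gz"
            par_p = out / f"{case.case_id}_parenchyma.nii.gz"
            write_volume(case.image, img_p)
            write_mask(case.tumor, tum_p)
            write_mask(case.parenchyma, par_p)
            paths = (str(img_p), str(tum_p), str(par_p))
        else:
            paths = ("", "", None)
        records.append(
            CaseRecord(
                case_id=case.case_id,
                image_path=paths[0],
                tumor_mask_path=paths[1],
                parenchyma_mask_path=paths[2],
                label=int(labels[i]),
                cohort=cohorts[i],
            )
        )

    if out is not None:
        write_manifest(records, out / "manifest.csv")
    return Cohort(cases=cases, records=records, config=config)
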