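"""CT-like phantoms with known radioresistant (recurrent) sub-volumes.

Patient imaging of the kind this method targets is not openly available, so
the package ships a generator that emulates the study conditions: an
ellipsoidal gross tumor volume (GTV) in a soft-tissue Hounsfield background
containing an embedded spherical recurrence blob whose voxel texture is
*more heterogeneous* than the controlled remainder — heterogeneity being
the image property the method is designed to pick up.

Texture is spatially correlated Gaussian noise (white noise smoothed with a
Gaussian kernel whose width is the correlation length, then rescaled to the
requested standard deviation).  The recurrent blob's noise SD is the
control SD times the *effect size*; an effect size of 1 is the null
phantom.  Cohorts default to the study design of 28 training + 12
validation patients with the recurrence occupying 2-71% of the GTV.

No claim of CT physics realism is made (no beam hardening, artifacts or
anatomy): the phantoms exist to make every pipeline stage testable against
known ground truth.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import ImageVolume, ROIMask, write_mask, write_volume

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and texture parameters of one phantom patient."""

    shape: tuple[int, int, int] = (40, 40, 28)
    spacing: tuple[float, float, float] = (1.2, 1.2, 3.0)  # mm, CT-like anisotropy
    gtv_center_mm: tuple[float, float, float] | None = None  # default: volume center
    gtv_semiaxes_mm: tuple[float, float, float] = (16.0, 14.0, 15.0)
    rec_center_mm: tuple[float, float, float] | None = None  # default: gtv center
    rec_radius_mm: float = 8.5
    background_mean_hu: float = 0.0
    background_sd_hu: float = 10.0
    #: the tumor-statistics texture extends this far beyond the GTV before
    #: the distinct background begins, so that resampling never blends
    #: background into GTV-surface voxels (which would make the controlled
    #: shell differ from the interior for geometric, not textural, reasons)
    soft_tissue_margin_mm: float = 8.0
    gtv_mean_hu: float = 80.0
    control_noise_sd_hu: float = 15.0
    #: kept below the 3.3 mm analysis voxel: texture power at wavelengths
    #: comparable to sub-region size would couple sample variance to region
    #: size and make even the effect-size-1 null separable by size alone
    control_corr_length_mm: float = 1.5
    effect_size: float = 2.0  # recurrent / control noise-SD ratio, >= 1
    #: None -> control correlation length divided by the effect size, so the
    #: whole heterogeneity contrast is governed by one dial and effect size
    #: 1.0 is an exact null (identically distributed textures)
    recurrent_corr_length_mm: float | None = None
    seed: int = 0

    @property
    def resolved_recurrent_corr_length_mm(self) -> float:
        if self.recurrent_corr_length_mm is not None:
            return self.recurrent_corr_length_mm
        return self.control_corr_length_mm / self.effect_size


@dataclass(frozen=True)
class CohortSpec:
    """Randomisation ranges for a cohort of phantom patients."""

    n_train: int = 28
    n_val: int = 12
    effect_size: float = 2.0
    rec_fraction_range: tuple[float, float] = (0.02, 0.71)  # |rec| / |GTV|
    gtv_semiaxis_range_mm: tuple[float, float] = (12.0, 18.0)
    rec_offset_fraction: float = 0.5  # blob center offset, fraction of semi-axis
    base: PhantomSpec = field(default_factory=PhantomSpec)
    master_seed: int = 0


def _correlated_noise(rng, shape, spacing, corr_length_mm, sd):
    """Zero-mean Gaussian field with the given SD and correlation length.

    White noise is smoothed with a Gaussian kernel of physical width
    ``corr_length_mm`` and rescaled to unit variance empirically before
    scaling by ``sd`` (the smoothing gain is geometry dependent).
    """
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_length_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    g_sd = smooth.std()
    if g_sd == 0:
        return np.zeros(shape)
    return smooth / g_sd * sd


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm):
    coords = [
        (np.arange(n) * s - c) / a
        for n, s, c, a in zip(shape, spacing, center_mm, semiaxes_mm)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ROIMask, ROIMask]:
    """One phantom patient: (CT image, GTV mask, recurrence mask).

    The tumor and a surrounding soft-tissue margin carry one stationary
    correlated texture field; inside the recurrence blob an independent
    finer-scale field scaled by sqrt(effect_size^2 - 1) is *added*, so the
    blob's voxel SD is exactly ``effect_size`` times the control SD and an
    effect size of 1 adds nothing at all — the null phantom is a single
    stationary field with no seams anywhere near the GTV.  Deterministic
    per spec + seed.  The recurrence blob must intersect the GTV (it is
    clipped to it; a blob fully outside is an error).
    """
    if spec.effect_size < 1.0:
        raise ValueError(f"effect size must be >= 1, got {spec.effect_size}")
    rng = np.random.default_rng(spec.seed)
    extent = [n * s for n, s in zip(spec.shape, spec.spacing)]
    gtv_c = spec.gtv_center_mm or tuple(e / 2 for e in extent)
    rec_c = spec.rec_center_mm or gtv_c
    gtv = _ellipsoid_mask(spec.shape, spec.spacing, gtv_c, spec.gtv_semiaxes_mm)
    rec_r = (spec.rec_radius_mm,) * 3
    rec = _ellipsoid_mask(spec.shape, spec.spacing, rec_c, rec_r) & gtv
    if not rec.any():
        raise ValueError("recurrence blob lies entirely outside the GTV")

    background = spec.background_mean_hu + rng.standard_normal(spec.shape) * spec.background_sd_hu
    control_tex = _correlated_noise(
        rng, spec.shape, spec.spacing, spec.control_corr_length_mm, spec.control_noise_sd_hu
    )
    soft_tissue = ndimage.distance_transform_edt(~gtv, sampling=spec.spacing) <= spec.soft_tissue_margin_mm
    data = np.where(soft_tissue, spec.gtv_mean_hu + control_tex, background)
    extra_sd = spec.control_noise_sd_hu * math.sqrt(spec.effect_size**2 - 1.0)
    if extra_sd > 0:
        extra_tex = _correlated_noise(
            rng,
            spec.shape,
            spec.spacing,
            spec.resolved_recurrent_corr_length_mm,
            extra_sd,
        )
        data = np.where(rec, data + extra_tex, data)
    image = ImageVolume(data, spec.spacing)
    return (
        image,
        ROIMask(gtv, spec.spacing),
        ROIMask(rec, spec.spacing),
    )


def _patient_spec(cohort: CohortSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    lo, hi = cohort.gtv_semiaxis_range_mm
    semiaxes = tuple(float(a) for a in rng.uniform(lo, hi, size=3))
    # log-uniform: recurrence fractions are right-skewed in practice (many
    # small recurrences, few near-total); over [0.02, 0.71] this gives a
    # cohort mean of ~0.19 alongside the full printed range
    f_lo, f_hi = cohort.rec_fraction_range
    if f_lo == f_hi:
        frac = float(f_lo)
    else:
        frac = float(np.exp(rng.uniform(np.log(f_lo), np.log(f_hi))))
    # sphere radius giving the target |rec|/|GTV| for a fully interior blob
    rec_radius = float(frac ** (1.0 / 3.0) * np.prod(semiaxes) ** (1.0 / 3.0))
    extent = [n * s for n, s in zip(cohort.base.shape, cohort.base.spacing)]
    gtv_c = tuple(e / 2 for e in extent)
    # offset the blob toward a random direction so recurrence concentrates
    # in one part of the tumor, as focal recurrences do
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    max_off = np.array(semiaxes) - rec_radius
    offset = direction * np.clip(max_off, 0.0, None) * cohort.rec_offset_fraction
    rec_c = tuple(float(c + o) for c, o in zip(gtv_c, offset))
    return replace(
        cohort.base,
        gtv_center_mm=gtv_c,
        gtv_semiaxes_mm=semiaxes,
        rec_center_mm=rec_c,
        rec_radius_mm=rec_radius,
        effect_size=cohort.effect_size,
        seed=seed,
    )


def generate_cohort(
    cohort: CohortSpec, out_dir: str | os.PathLike | None = None
) -> pd.DataFrame:
    """Generate ``n_train + n_val`` phantom patients and a manifest.

    The manifest records patient id, cohort membership (train/validation),
    the per-patient seed, the realised recurrence fraction and the file
    paths when ``out_dir`` is given (NIfTI triplet per patient:
    ``<pid>_ct.nii.gz``, ``<pid>_gtv.nii.gz``, ``<pid>_rec.nii.gz``).
    Reproducible per master seed.
    """
    rng = np.random.default_rng(cohort.master_seed)
    rows = []
    n_total = cohort.n_train + cohort.n_val
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for i in range(n_total):
        pid = f"p{i:03d}"
        split = "train" if i < cohort.n_train else "validation"
        seed = int(rng.integers(0, 2**31 - 1))
        spec = _patient_spec(cohort, rng, seed)
        image, gtv, rec = generate_phantom(spec)
        row = {
            "patient_id": pid,
            "cohort": split,
            "seed": seed,
            "effect_size": cohort.effect_size,
            "gtv_voxels": gtv.voxel_count,
            "rec_voxels": rec.voxel_count,
            "rec_fraction": rec.voxel_count / gtv.voxel_count,
        }
        if out_dir is not None:
            paths = {
                "image_path": os.path.join(out_dir, f"{pid}_ct.nii.gz"),
                "gtv_path": os.path.join(out_dir, f"{pid}_gtv.nii.gz"),
                "rec_path": os.path.join(out_dir, f"{pid}_rec.nii.gz"),
            }
            write_volume(image, paths["image_path"])
            write_mask(gtv, paths["gtv_path"])
            write_mask(rec, paths["rec_path"])
            row.update(paths)
        else:
            row.update({"image": image, "gtv": gtv, "rec": rec})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
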