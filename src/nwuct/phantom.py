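"""Synthetic NCCT head phantoms with known ground-truth NWU.

A phantom is a desk-scale digital head: an ellipsoidal bone-density skull
shell, a thin CSF margin, brain parenchyma around 35 HU with a smooth,
bilaterally symmetric gray/white-like texture, paired CSF-density ventricles,
and optionally one unilateral hypodense ellipsoidal lesion whose voxel values
are scaled by (1 - w/100) relative to the symmetric pre-lesion image.  By
construction the mirrored contralateral region of the lesion has exactly the
pre-lesion values (in the noise-free, symmetric case), so the ground-truth
net water uptake of the lesion is exactly w percent.

Additive Gaussian HU noise and a smooth random hemispheric deformation
("asymmetry") can be layered on top to emulate acquisition noise and normal
anatomical asymmetry.  Everything is deterministic per seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core_io import BinaryMask, CTVolume
from .errors import PhantomGeometryError


@dataclass
class PhantomSpec:
    """Parameterization of one synthetic head case.

    Lengths in mm (world coordinates centred on the head), HU for densities,
    ``uptake_percent`` is the implanted ground-truth NWU w with 0 <= w <= 30.
    """

    shape: tuple[int, int, int] = (110, 140, 90)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # head geometry (ellipsoid semi-axes; axis 0 = left-right)
    skull_outer: tuple[float, float, float] = (52.0, 66.0, 42.0)
    skull_thickness: float = 4.0
    skull_hu: float = 1200.0
    csf_margin: float = 2.0
    csf_hu: float = 8.0
    background_hu: float = -1000.0
    # parenchyma
    parenchyma_hu: float = 35.0
    texture_amplitude: float = 0.05      # multiplicative, fraction of HU
    texture_scale_mm: float = 12.0       # correlation length of the texture
    # ventricles (one per hemisphere, mirrored)
    ventricle_center: tuple[float, float, float] = (10.0, -8.0, 5.0)
    ventricle_radii: tuple[float, float, float] = (5.0, 16.0, 9.0)
    # lesion
    lesion_center: tuple[float, float, float] | None = None
    lesion_radii: tuple[float, float, float] | None = None
    uptake_percent: float = 0.0
    edge_blur_mm: float = 0.0            # optional soft lesion boundary
    # degradations
    noise_sigma: float = 0.0             # additive Gaussian HU noise
    asymmetry_mm: float = 0.0            # smooth random deformation amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake_percent <= 30.0:
            raise PhantomGeometryError(
                f"uptake must be in [0, 30] percent, got {self.uptake_percent}")
        if self.noise_sigma < 0:
            raise PhantomGeometryError("noise sigma must be non-negative")
        if (self.lesion_center is None) != (self.lesion_radii is None):
            raise PhantomGeometryError("lesion_center and lesion_radii go together")

    @property
    def has_lesion(self) -> bool:
        return self.lesion_center is not None and self.uptake_percent > 0


@dataclass
class PhantomCase:
    """A realized phantom: CT volume, ground-truth mask and NWU, spec echo."""

    ct: CTVolume
    gt_mask: BinaryMask
    gt_nwu: float
    spec: PhantomSpec


def _world_coords(spec: PhantomSpec):
    """Open-grid world coordinates centred on the volume (mirror-symmetric in
    x for even axis sizes)."""
    axes = []
    for n, s in zip(spec.shape, spec.spacing):
        axes.append(((np.arange(n) - (n - 1) / 2.0) * s))
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    return x, y, z


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2) <= 1.0


def _symmetric_texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative texture field, exactly mirror-symmetric in x."""
    if spec.texture_amplitude <= 0:
        return np.ones(spec.shape)
    noise = rng.standard_normal(spec.shape)
    sigma = [spec.texture_scale_mm / s for s in spec.spacing]
    f = ndi.gaussian_filter(noise, sigma=sigma)
    f = 0.5 * (f + f[::-1])              # enforce left-right symmetry
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak * spec.texture_amplitude
    return 1.0 + f


def _smooth_vector_field(shape, spacing, amplitude_mm, scale_mm, rng) -> np.ndarray:
    """Random smooth displacement field with max magnitude ``amplitude_mm``."""
    field = np.stack([ndi.gaussian_filter(rng.standard_normal(shape),
                                          sigma=[scale_mm / s for s in spacing])
                      for _ in range(3)], axis=-1)
    mag = np.linalg.norm(field, axis=-1)
    peak = mag.max()
    if peak > 0:
        field *= amplitude_mm / peak
    return field


def _warp_scalar(values: np.ndarray, disp_mm: np.ndarray, spacing) -> np.ndarray:
    """Pull-back warp of a scalar array by a voxel-space displacement field."""
    idx = np.indices(values.shape, dtype=np.float64)
    coords = [idx[a] + disp_mm[..., a] / spacing[a] for a in range(3)]
    return ndi.map_coordinates(values, coords, order=1, mode="nearest")


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Realize a :class:`PhantomCase` from its spec (deterministic per seed)."""
    ss = np.random.SeedSequence(spec.seed)
    rng_texture, rng_noise, rng_asym = (np.random.default_rng(s) for s in ss.spawn(3))

    x, y, z = _world_coords(spec)
    t = spec.skull_thickness
    m = spec.csf_margin
    outer = _ellipsoid(x, y, z, (0, 0, 0), spec.skull_outer)
    inner = _ellipsoid(x, y, z, (0, 0, 0),
                       tuple(r - t for r in spec.skull_outer))
    brain = _ellipsoid(x, y, z, (0, 0, 0),
                       tuple(r - t - m for r in spec.skull_outer))

    vc = spec.ventricle_center
    ventricles = (_ellipsoid(x, y, z, vc, spec.ventricle_radii)
                  | _ellipsoid(x, y, z, (-vc[0], vc[1], vc[2]), spec.ventricle_radii))
    ventricles &= brain

    vol = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    vol[outer] = spec.skull_hu
    vol[inner] = spec.csf_hu
    texture = _symmetric_texture(spec, rng_texture)
    parenchyma = brain & ~ventricles
    vol[parenchyma] = spec.parenchyma_hu * texture[parenchyma]
    vol[ventricles] = spec.csf_hu

    if spec.asymmetry_mm > 0:
        disp = _smooth_vector_field(spec.shape, spec.spacing, spec.asymmetry_mm,
                                    2 * spec.texture_scale_mm, rng_asym)
        taper = ndi.gaussian_filter(brain.astype(np.float64),
                                    sigma=[6.0 / s for s in spec.spacing])
        disp = disp * taper[..., None]
        tissue = vol.copy()
        warped = _warp_scalar(tissue, disp, spec.spacing)
        vol[brain] = warped[brain]        # skull stays symmetric

    gt_mask = np.zeros(spec.shape, dtype=bool)
    if spec.has_lesion:
        ell = _ellipsoid(x, y, z, spec.lesion_center, spec.lesion_radii)
        gt_mask = ell & parenchyma
        if not gt_mask.any():
            raise PhantomGeometryError("lesion lies outside the parenchyma")
        xs = np.broadcast_to(x, spec.shape)[gt_mask]
        if xs.min() < 0 < xs.max():
            raise PhantomGeometryError("lesion crosses the midsagittal plane")
        w = spec.uptake_percent / 100.0
        if spec.edge_blur_mm > 0:
            soft = ndi.gaussian_filter(gt_mask.astype(np.float64),
                                       sigma=[spec.edge_blur_mm / s
                                              for s in spec.spacing])
            vol *= (1.0 - w * soft)
        else:
            vol[gt_mask] *= (1.0 - w)

    if spec.noise_sigma > 0:
        vol = vol + rng_noise.normal(0.0, spec.noise_sigma, size=spec.shape)

    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing))
    ct = CTVolume(vol.astype(np.float32), spec.spacing, origin)
    mask = BinaryMask(gt_mask.astype(np.uint8), spec.spacing, origin)
    return PhantomCase(ct=ct, gt_mask=mask,
                       gt_nwu=float(spec.uptake_percent if spec.has_lesion else 0.0),
                       spec=spec)


def default_template(shape=(110, 140, 90), spacing=(1.0, 1.0, 1.0)) -> CTVolume:
    """Noise-free, texture-free, exactly symmetric phantom: the default
    registration template standing in for a population CT atlas."""
    spec = PhantomSpec(shape=tuple(shape), spacing=tuple(spacing),
                       texture_amplitude=0.0, noise_sigma=0.0,
                       asymmetry_mm=0.0, uptake_percent=0.0, seed=0)
    return generate_phantom(spec).ct


# ---------------------------------------------------------------------------
# Lesion placement and suites
# ---------------------------------------------------------------------------

#: fixed lesion ellipsoid shape ratios (left-right, antero-posterior, axial)
_LESION_SHAPE = np.array([0.75, 1.15, 1.0])


def lesion_radii_for_volume(volume_ml: float) -> tuple[float, float, float]:
    """Ellipsoid radii (mm) with the module's shape ratios realizing a target
    volume in mL."""
    r3 = volume_ml * 1000.0 / (4.0 / 3.0 * np.pi * np.prod(_LESION_SHAPE))
    r = float(np.cbrt(r3))
    return tuple(_LESION_SHAPE * r)


def _place_lesion(spec: PhantomSpec, volume_ml: float, side: str,
                  rng: np.random.Generator, max_tries: int = 40,
                  min_containment: float = 0.98) -> PhantomSpec:
    """Sample an admissible lesion centre for the requested volume and side.

    Retries until at most ``1 - min_containment`` of the lesion ellipsoid is
    clipped by the brain boundary.  Overlap with the ventricles is tolerated:
    the realized ground-truth mask excludes CSF voxels by construction, so it
    only trims the realized volume slightly below the request.
    """
    radii = lesion_radii_for_volume(volume_ml)
    sign = -1.0 if side == "left" else 1.0
    x, y, z = _world_coords(spec)
    t, m = spec.skull_thickness, spec.csf_margin
    brain = _ellipsoid(x, y, z, (0, 0, 0), tuple(r - t - m for r in spec.skull_outer))
    for _ in range(max_tries):
        cx = sign * (radii[0] + 4.0 + rng.uniform(0.0, 3.0))
        cy = rng.uniform(-10.0, 10.0)
        cz = rng.uniform(-6.0, 6.0)
        ell = _ellipsoid(x, y, z, (cx, cy, cz), radii)
        n_ell = int(ell.sum())
        if n_ell == 0:
            continue
        inside = int((ell & brain).sum())
        xs = np.broadcast_to(x, spec.shape)[ell & brain]
        if xs.size and (xs.min() < 0 < xs.max()):
            continue
        if inside / n_ell >= min_containment:
            return replace(spec, lesion_center=(cx, cy, cz),
                           lesion_radii=tuple(radii))
    raise PhantomGeometryError(
        f"no admissible placement for a {volume_ml} mL lesion after {max_tries} tries")


def phantom_suite(n: int = 20, uptakes=(5.0, 10.0, 15.0, 20.0),
                  volume_range_ml=(10.0, 60.0), noise_sigmas=(0.0, 1.0, 2.0, 3.0, 4.0),
                  seed: int = 0, base_spec: PhantomSpec | None = None
                  ) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Reproducible suite of lesion phantoms spanning uptake, volume and noise.

    Cases cycle through the uptake grid, sweep lesion volumes linearly across
    ``volume_range_ml``, cycle through the noise levels, and alternate sides.
    Returns the cases plus a spec table (one row per case).
    """
    if n < 1:
        raise ValueError("suite needs n >= 1")
    base = base_spec or PhantomSpec()
    n_vol = max(1, int(np.ceil(n / len(uptakes))))
    volumes = np.linspace(volume_range_ml[0], volume_range_ml[1], n_vol)
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
    place_rng = np.random.default_rng(ss.spawn(1)[0])

    cases: list[PhantomCase] = []
    rows = []
    for i in range(n):
        uptake = float(uptakes[i % len(uptakes)])
        volume = float(volumes[(i // len(uptakes)) % n_vol])
        sigma = float(noise_sigmas[i % len(noise_sigmas)])
        side = "left" if i % 2 == 0 else "right"
        spec = replace(base, uptake_percent=uptake, noise_sigma=sigma,
                       seed=case_seeds[i])
        spec = _place_lesion(spec, volume, side, place_rng)
        case = generate_phantom(spec)
        cases.append(case)
        rows.append({
            "case_id": f"case{i:03d}",
            "uptake_percent": uptake,
            "requested_volume_ml": volume,
            "gt_volume_ml": case.gt_mask.volume_ml,
            "noise_sigma": sigma,
            "side": side,
            "lesion_absent": not spec.has_lesion,
            "seed": spec.seed,
        })
    return cases, pd.DataFrame(rows)


def export_suite(cases: list[PhantomCase], table: pd.DataFrame, out_dir) -> None:
    """Write a suite as NIfTI pairs plus the CSV spec table."""
    import os

    from .core_io import write_volume

    os.makedirs(out_dir, exist_ok=True)
    for row, case in zip(table.itertuples(), cases):
        stem = f"{row.case_id}_seed{case.spec.seed}"
        write_volume(case.ct, os.path.join(out_dir, f"{stem}_ct.nii.gz"))
        write_volume(case.gt_mask, os.path.join(out_dir, f"{stem}_mask.nii.gz"))
    table.to_csv(os.path.join(out_dir, "suite.csv"), index=False)
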