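"""Voxel-wise net water uptake: parenchyma masking, masked average pooling,
and the NWU map.

Net water uptake of a region A relative to its contralateral counterpart B is

    NWU = (1 - mean(HU_A) / mean(HU_B)) * 100   [percent]

Instead of a predefined lesion mask, the map variant evaluates this ratio for
every voxel over an 11x11x11 mm sliding window restricted to the parenchyma
mask, so each voxel carries the NWU of its surrounding tissue.  Windows with
fewer than 10% of the nominal kernel volume inside the mask (133 voxels for an
11 mm kernel at 1 mm spacing) are marked invalid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import DisjointValidityError, EmptyMaskError, KernelError, NWUDomainError


def nwu_scalar(mean_a: float, mean_b: float) -> float:
    """Net water uptake (percent) of region A against contralateral region B.

    Raises :class:`NWUDomainError` if the denominator mean is not positive.
    """
    if mean_b <= 0:
        raise NWUDomainError(f"contralateral mean HU must be positive, got {mean_b}")
    return (1.0 - mean_a / mean_b) * 100.0


# ---------------------------------------------------------------------------
# Parenchyma mask
# ---------------------------------------------------------------------------

@dataclass
class ParenchymaMask:
    """Hemisphere brain-parenchyma mask plus per-rule exclusion counts."""

    values: np.ndarray                    # bool (nx, ny, nz)
    removed: dict = field(default_factory=dict)   # rule -> voxels excluded


def sobel_magnitude(values: np.ndarray) -> np.ndarray:
    """3D Sobel gradient magnitude (HU per voxel, unnormalized kernels)."""
    v = np.asarray(values, dtype=np.float64)
    g2 = np.zeros_like(v)
    for axis in range(3):
        g = ndi.sobel(v, axis=axis, mode="nearest")
        g2 += g * g
    return np.sqrt(g2)


def parenchyma_mask(values: np.ndarray, csf_hu: float = 14.0, bone_hu: float = 60.0,
                    edge_threshold: float = 120.0) -> ParenchymaMask:
    """Brain-parenchyma mask for one hemisphere.

    Keeps voxels that are (a) positive HU, (b) inside the open parenchyma band
    ``(csf_hu, bone_hu)`` excluding CSF below and bone above, and (c) not on a
    strong Sobel edge (gradient magnitude below ``edge_threshold``), which
    removes skull margins and partial-volume interfaces.
    """
    v = np.asarray(values)
    positive = v > 0
    band = (v > csf_hu) & (v < bone_hu)
    edges_ok = sobel_magnitude(v) < edge_threshold
    mask = positive & band & edges_ok
    if not mask.any():
        raise EmptyMaskError("no parenchyma voxels survive the mask rules")
    n = v.size
    removed = {
        "non_positive": int(n - positive.sum()),
        "hu_band": int((positive & ~band).sum()),
        "edge": int((positive & band & ~edges_ok).sum()),
    }
    return ParenchymaMask(values=mask, removed=removed)


# ---------------------------------------------------------------------------
# Masked average pooling
# ---------------------------------------------------------------------------

def kernel_voxels(kernel_mm, spacing) -> tuple[int, int, int]:
    """Kernel size in voxels (forced odd) for a physical kernel size in mm."""
    out = []
    for k_mm, s in zip(kernel_mm, spacing):
        k = max(1, int(round(k_mm / s)))
        if k % 2 == 0:
            k += 1
        out.append(k)
    return tuple(out)


def coverage_min_count(kernel_vox, min_fraction: float) -> int:
    """Coverage rule: minimum in-mask voxels per window, as a fraction of the
    nominal kernel volume (floor(0.10 * 11^3) = 133 at 1 mm spacing)."""
    return int(np.floor(min_fraction * int(np.prod(kernel_vox))))


@dataclass
class PooledField:
    """Windowed mean HU plus the coverage-rule validity mask."""

    values: np.ndarray   # float64; NaN where the window holds no mask voxel
    valid: np.ndarray    # bool; in-mask window count >= min_count
    counts: np.ndarray   # int64 in-mask voxels per window
    min_count: int


def masked_average_pool(values: np.ndarray, mask: np.ndarray,
                        kernel_vox=(11, 11, 11), min_count: int = 133) -> PooledField:
    """Sliding-window mean of ``values`` restricted to ``mask``.

    Windows are centred on each voxel and truncated at the volume border;
    voxels outside the volume count as out-of-mask, and the coverage rule is
    applied against the full nominal kernel volume.
    """
    v = np.asarray(values, dtype=np.float64)
    m = np.asarray(mask).astype(np.float64)
    if v.shape != m.shape:
        raise ValueError("volume and mask shapes differ")
    kernel_vox = tuple(int(k) for k in kernel_vox)
    for k, n in zip(kernel_vox, v.shape):
        if k % 2 == 0:
            raise KernelError(f"kernel size must be odd in voxels, got {kernel_vox}")
        if k > n:
            raise KernelError(f"kernel {kernel_vox} larger than volume {v.shape}")
    nominal = int(np.prod(kernel_vox))
    sums = ndi.uniform_filter(v * m, size=kernel_vox, mode="constant", cval=0.0) * nominal
    cnts = ndi.uniform_filter(m, size=kernel_vox, mode="constant", cval=0.0) * nominal
    counts = np.rint(cnts).astype(np.int64)
    counts[counts < 0] = 0
    pooled = np.full(v.shape, np.nan)
    nz = counts > 0
    pooled[nz] = sums[nz] / counts[nz]
    valid = counts >= int(min_count)
    return PooledField(values=pooled, valid=valid, counts=counts,
                       min_count=int(min_count))


# ---------------------------------------------------------------------------
# NWU map
# ---------------------------------------------------------------------------

@dataclass
class NWUMap:
    """Voxel-wise NWU (percent) with validity mask.

    ``values`` holds NaN outside ``valid``.  The sign convention is recorded
    in ``side_as_a``: positive values mean the "A" hemisphere is hypodense
    relative to its contralateral counterpart.
    """

    values: np.ndarray
    valid: np.ndarray
    side_as_a: str = "left"
    clip: tuple[float, float] = (-30.0, 30.0)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def compute_nwu_map(pooled_a: PooledField, pooled_b: PooledField,
                    side_as_a: str = "left",
                    clip: tuple[float, float] = (-30.0, 30.0)) -> NWUMap:
    """Voxel-wise NWU of hemisphere A against contralateral hemisphere B.

    Valid voxels require both pooled windows valid and a positive denominator
    window mean; values are clipped to ``clip`` to suppress pathological
    ratios at the mask boundary.
    """
    if pooled_a.values.shape != pooled_b.values.shape:
        raise ValueError("pooled fields must share a grid")
    valid = pooled_a.valid & pooled_b.valid & (pooled_b.values > 0)
    if not valid.any():
        raise DisjointValidityError("pooled hemisphere fields share no valid voxel")
    out = np.full(pooled_a.values.shape, np.nan)
    out[valid] = (1.0 - pooled_a.values[valid] / pooled_b.values[valid]) * 100.0
    np.clip(out, clip[0], clip[1], out=out)
    return NWUMap(values=out, valid=valid, side_as_a=side_as_a, clip=tuple(clip))
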