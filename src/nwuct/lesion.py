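"""Lesion extraction from the NWU map and the final lesion report.

The NWU map separates into a near-zero background (symmetric tissue) and a
high-value foreground (the hypodense lesion).  Otsu's method finds the split;
a lower cutoff guards against runs where no lesion exists and the histogram
is pure background noise.  The supra-threshold candidate is reduced to its
largest connected component, refined by a volume-preserving morphological
opening (erosion then dilation with equal radii) plus cavity fill, and the
total NWU of the final mask is computed by the scalar NWU formula against the
deformably-matched contralateral tissue.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from .config import RunConfig
from .errors import DegenerateHistogramError, EmptyMaskError
from .nwu import NWUMap, nwu_scalar


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(values, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold over a ``nbins`` histogram.

    Candidate thresholds are the interior bin edges; the returned edge
    maximizes  sigma_b^2(t) = w0 w1 (mu0 - mu1)^2  with class statistics taken
    from bin centres.  When several edges tie (the variance is flat across an
    empty gap between modes), the midpoint of the maximizing plateau is
    returned, as in Otsu's original tie rule.  Depends on counts only through
    proportions, so duplicating the sample leaves the threshold unchanged.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or v.min() == v.max():
        raise DegenerateHistogramError("Otsu needs at least two distinct values")
    hist, edges = np.histogram(v, bins=nbins)
    p = hist.astype(np.float64) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]                    # class 0 weight at edges[1..nbins-1]
    m0 = np.cumsum(p * centers)[:-1]
    mu_total = float(np.sum(p * centers))
    w1 = 1.0 - w0
    ok = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(nbins - 1, -np.inf)
    mu0 = np.where(ok, m0 / np.where(ok, w0, 1.0), 0.0)
    mu1 = np.where(ok, (mu_total - m0) / np.where(ok, w1, 1.0), 0.0)
    sigma_b[ok] = (w0 * w1 * (mu0 - mu1) ** 2)[ok]
    smax = sigma_b.max()
    plateau = np.flatnonzero(sigma_b >= smax - 1e-9 * abs(smax))
    k = int(plateau[len(plateau) // 2])       # midpoint of the maximizing plateau
    return float(edges[k + 1])


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def largest_connected_component(mask: np.ndarray, connectivity: int = 26
                                ) -> tuple[np.ndarray, int]:
    """Largest connected component of a binary mask and the component count.

    Empty input yields an empty output.  Size ties resolve to the component
    containing the smallest linear voxel index (deterministic).
    """
    m = np.asarray(mask).astype(bool)
    labels, n = ndi.label(m, structure=_structure(connectivity))
    if n == 0:
        return np.zeros_like(m), 0
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.max())
    candidates = np.flatnonzero(sizes == best)
    if candidates.size > 1:
        labs, first = np.unique(labels.ravel(), return_index=True)
        first_of = dict(zip(labs.tolist(), first.tolist()))
        winner = min(candidates, key=lambda lab: first_of[int(lab)])
    else:
        winner = candidates[0]
    return labels == winner, n


# ---------------------------------------------------------------------------
# Lesion mask extraction
# ---------------------------------------------------------------------------

def extract_lesion_mask(nwu: NWUMap, cfg: RunConfig | None = None,
                        threshold: float | None = None
                        ) -> tuple[np.ndarray, dict]:
    """Binary lesion mask from an NWU map.

    candidate = valid voxels with NWU >= max(Otsu threshold, lower cutoff);
    then largest connected component, erosion, dilation, cavity flood fill,
    and a final largest-component pass so the output is one component or
    empty.  An empty mask is a valid outcome (no lesion), never an error.

    If ``threshold`` is given (e.g. an Otsu level pooled over both sign
    conventions), it replaces the map-local Otsu computation.
    """
    cfg = cfg or RunConfig()
    info: dict = {"otsu_threshold": None}
    vals = nwu.valid_values
    if vals.size == 0:
        raise EmptyMaskError("NWU map has no valid voxel")
    if threshold is None:
        pos = vals[vals > 0]
        try:
            threshold = otsu_threshold(pos)
            info["otsu_threshold"] = float(threshold)
        except DegenerateHistogramError:
            threshold = -np.inf    # nothing above noise; the cutoff decides
    else:
        info["otsu_threshold"] = float(threshold)
    thr = max(float(threshold), cfg.lower_cutoff)
    info["threshold_used"] = thr

    candidate = nwu.valid & (np.nan_to_num(nwu.values, nan=-np.inf) >= thr)
    info["candidate_voxels"] = int(candidate.sum())
    if not candidate.any():
        return np.zeros_like(candidate), info

    mask, n_components = largest_connected_component(candidate, cfg.connectivity)
    info["component_count"] = n_components
    if cfg.erosion_radius > 0:
        mask = ndi.binary_erosion(mask, structure=ball(cfg.erosion_radius))
    if mask.any() and cfg.dilation_radius > 0:
        mask = ndi.binary_dilation(mask, structure=ball(cfg.dilation_radius))
    if mask.any():
        mask = ndi.binary_fill_holes(mask)
        mask, _ = largest_connected_component(mask, cfg.connectivity)
    return mask.astype(bool), info


# ---------------------------------------------------------------------------
# Lesion report
# ---------------------------------------------------------------------------

@dataclass
class LesionResult:
    """Final per-case lesion readout.

    ``nwu_total`` is the scalar NWU of the mask against its contralateral
    correspondence; ``None`` when no lesion was found.
    """

    lesion_mask: np.ndarray          # bool, full aligned grid
    side: str                        # "left" | "right" | "none"
    volume_ml: float
    nwu_total: float | None
    otsu_threshold: float | None
    component_count: int
    mask_hemi: np.ndarray | None = None   # bool, hemisphere grid (shared frame)

    def to_report(self) -> dict:
        return {
            "side": self.side,
            "volume_ml": round(float(self.volume_ml), 4),
            "nwu_total": None if self.nwu_total is None else round(float(self.nwu_total), 4),
            "otsu_threshold": None if self.otsu_threshold is None
            else round(float(self.otsu_threshold), 4),
            "component_count": int(self.component_count),
        }


def lesion_nwu(aligned_values: np.ndarray, lesion_mask: np.ndarray,
               csf_hu: float = 14.0, bone_hu: float = 60.0,
               mirror_axis: int = 0) -> float:
    """Total NWU of a lesion mask via the scalar NWU formula.

    A is the mean HU inside the mask and B the mean HU inside its mirrored
    contralateral region, both on the template-aligned volume whose midplane
    is the central slice along ``mirror_axis`` (the standard mirrored-ROI
    contralateral definition).  Each mean is restricted to voxels inside the
    parenchyma HU band ``(csf_hu, bone_hu)``, so CSF and bone do not
    contaminate the regional means (hypodense lesion tissue stays above the
    CSF bound for uptakes up to ~30% of normal parenchyma).
    """
    m = np.asarray(lesion_mask).astype(bool)
    contra = np.flip(m, axis=mirror_axis)
    v = np.asarray(aligned_values)
    les = m & (v > csf_hu) & (v < bone_hu)
    ref = contra & (v > csf_hu) & (v < bone_hu)
    if not les.any() or not ref.any():
        raise EmptyMaskError("lesion or mirrored contralateral region empty "
                             "after parenchyma-band filtering")
    return nwu_scalar(float(v[les].mean()), float(v[ref].mean()))
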