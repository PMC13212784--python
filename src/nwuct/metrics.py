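"""Evaluation metrics: Dice, bounding-box IoU, detection, mAP, NWU error stats.

Conventions for the degenerate both-empty case: two empty masks agree
perfectly on the absence of a lesion, so Dice = 1, detected = True and
bounding-box IoU = 1.  The detection threshold for the mAP-style metric is
0.5^(3/2) ~ 0.3536, the 2D half-overlap convention extended to 3D.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: bounding-box IoU above which a case counts as a correct detection
DETECTION_IOU_THRESHOLD = 0.5 ** 1.5


def _as_bool(mask) -> np.ndarray:
    m = np.asarray(getattr(mask, "values", mask))
    return m.astype(bool)


def _check_grids(a, b) -> tuple[np.ndarray, np.ndarray]:
    ma, mb = _as_bool(a), _as_bool(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask grids differ: {ma.shape} vs {mb.shape}")
    return ma, mb


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 if both empty."""
    ma, mb = _check_grids(a, b)
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def detected(computed, reference) -> bool:
    """Any-voxel overlap detection criterion; True if both masks are empty."""
    mc, mr = _check_grids(computed, reference)
    if not mc.any() and not mr.any():
        return True
    return bool((mc & mr).any())


def _bbox(mask: np.ndarray) -> np.ndarray | None:
    idx = np.argwhere(mask)
    if idx.size == 0:
        return None
    return np.concatenate([idx.min(axis=0), idx.max(axis=0)])  # inclusive


def bounding_box_iou(a, b) -> float:
    """IoU of the axis-aligned voxel bounding boxes of two masks.

    1.0 if both masks are empty, 0.0 if exactly one is.
    """
    ma, mb = _check_grids(a, b)
    ba, bb = _bbox(ma), _bbox(mb)
    if ba is None and bb is None:
        return 1.0
    if ba is None or bb is None:
        return 0.0
    lo = np.maximum(ba[:3], bb[:3])
    hi = np.minimum(ba[3:], bb[3:])
    inter = np.prod(np.maximum(hi - lo + 1, 0))
    va = np.prod(ba[3:] - ba[:3] + 1)
    vb = np.prod(bb[3:] - bb[:3] + 1)
    union = va + vb - inter
    return float(inter / union)


def mean_average_precision(bbox_ious, iou_threshold: float = DETECTION_IOU_THRESHOLD
                           ) -> float:
    """Fraction of cases whose bounding-box IoU strictly exceeds the threshold.

    In this single-detection-per-case pipeline there is no confidence ranking,
    so mAP reduces to the per-case hit fraction at the fixed IoU threshold.
    """
    ious = np.asarray(list(bbox_ious), dtype=float)
    if ious.size == 0:
        raise ValueError("mean_average_precision needs at least one case")
    return float(np.mean(ious > iou_threshold))


def nwu_error_stats(pairs) -> dict:
    """NWU error panel over (computed, reference) percent pairs.

    Returns MAE +- SD, ME +- SD, median AE with IQR, and n.  Errors are
    computed - reference, so a positive ME means systematic overestimation.
    """
    arr = np.asarray([(c, r) for c, r in pairs], dtype=float)
    if arr.size == 0:
        raise ValueError("nwu_error_stats needs at least one pair")
    err = arr[:, 0] - arr[:, 1]
    ae = np.abs(err)
    q1, med, q3 = np.percentile(ae, [25, 50, 75])
    return {
        "n": int(err.size),
        "mae": float(ae.mean()),
        "mae_sd": float(ae.std(ddof=1)) if err.size > 1 else 0.0,
        "me": float(err.mean()),
        "me_sd": float(err.std(ddof=1)) if err.size > 1 else 0.0,
        "median_ae": float(med),
        "ae_iqr": (float(q1), float(q3)),
    }


@dataclass
class CaseMetrics:
    """Per-case comparison of a computed lesion against the reference."""

    case_id: str
    dice: float
    detected: bool
    bbox_iou: float
    nwu_computed: float | None
    nwu_reference: float | None
    volume_computed_ml: float
    volume_reference_ml: float
    extra: dict = field(default_factory=dict)

    @property
    def nwu_error(self) -> float | None:
        if self.nwu_computed is None or self.nwu_reference is None:
            return None
        return self.nwu_computed - self.nwu_reference


def summarize_cases(cases, iou_threshold: float = DETECTION_IOU_THRESHOLD) -> dict:
    """Cohort summary over a list of :class:`CaseMetrics` (Table-style panel)."""
    cases = list(cases)
    if not cases:
        raise ValueError("no cases to summarize")
    dices = np.asarray([c.dice for c in cases], dtype=float)
    d_q1, d_med, d_q3 = np.percentile(dices, [25, 50, 75])
    pairs = [(c.nwu_computed, c.nwu_reference) for c in cases
             if c.nwu_computed is not None and c.nwu_reference is not None]
    summary = {
        "n": len(cases),
        "detection_rate": float(np.mean([c.detected for c in cases])),
        "map_at_threshold": mean_average_precision(
            [c.bbox_iou for c in cases], iou_threshold),
        "iou_threshold": float(iou_threshold),
        "dice_median": float(d_med),
        "dice_iqr": (float(d_q1), float(d_q3)),
    }
    if pairs:
        summary.update(nwu_error_stats(pairs))
    return summary
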