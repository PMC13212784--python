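"""Run configuration: every tunable of the pipeline in one serializable object.

All thresholds the pipeline applies (HU bands, edge threshold, pooling kernel
and coverage fraction, NWU cutoffs, morphology radii, registration settings,
seeds) live here so that a run report can embed the exact configuration and a
content hash, and so no threshold is hard-coded in a stage.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml


@dataclass
class RunConfig:
    # --- grid -------------------------------------------------------------
    target_spacing: float = 1.0          # mm; isotropic working resolution

    # --- affine alignment to the symmetric template -----------------------
    affine_metric: str = "mi"            # "mi" (Mattes mutual information) or "mse"
    affine_levels: int = 3               # multi-resolution pyramid depth
    affine_iterations: int = 200         # optimizer iterations per level
    affine_sampling_fraction: float = 0.05
    affine_mi_bins: int = 32
    affine_restarts: int = 3             # rigid-stage multi-starts (sampling seeds)

    # --- deformable hemisphere registration (diffeomorphic demons) --------
    demons_iterations: tuple[int, ...] = (40, 20)   # per level, coarse to fine
    demons_shrinks: tuple[int, ...] = (2, 1)        # shrink factor per level
    demons_sigma_mm: float = 2.0         # Gaussian field regularization
    demons_tolerance: float = 1e-4       # relative metric-change stopping tol
    max_displacement_mm: float = 10.0    # cap on displacement magnitude
    pair_by_mirror_only: bool = False    # ablation: skip deformable pairing

    # --- parenchyma mask ---------------------------------------------------
    csf_hu: float = 14.0                 # voxels at or below: CSF, excluded
    bone_hu: float = 60.0                # voxels at or above: bone, excluded
    edge_threshold: float = 120.0        # Sobel gradient magnitude cutoff (HU/voxel)
    hu_rescale: tuple[float, float] | None = None   # optional (slope, intercept)

    # --- masked average pooling / NWU map ----------------------------------
    kernel_mm: tuple[float, float, float] = (11.0, 11.0, 11.0)
    min_fraction: float = 0.10           # coverage rule: fraction of kernel volume
    nwu_clip: tuple[float, float] = (-30.0, 30.0)   # percent

    # --- lesion extraction --------------------------------------------------
    lower_cutoff: float = 2.5            # percent NWU; floor under the Otsu threshold
    erosion_radius: int = 2              # voxels, ball structuring element
    dilation_radius: int = 2
    connectivity: int = 26               # 6 or 26
    min_lesion_ml: float = 1.0           # below: report "no lesion"

    # --- evaluation ---------------------------------------------------------
    iou_threshold: float = 0.5 ** 1.5    # bounding-box IoU detection threshold

    # --- reproducibility ----------------------------------------------------
    seed: int = 0                        # fans out to stage-specific seeds

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        self.demons_iterations = tuple(int(i) for i in self.demons_iterations)
        self.demons_shrinks = tuple(int(s) for s in self.demons_shrinks)
        self.kernel_mm = tuple(float(k) for k in self.kernel_mm)
        self.nwu_clip = tuple(float(c) for c in self.nwu_clip)
        if self.hu_rescale is not None:
            self.hu_rescale = tuple(float(v) for v in self.hu_rescale)

    # stage-specific seeds derived from the single global seed
    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
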