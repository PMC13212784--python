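# nwuct — automated net water uptake quantification from non-contrast CT

Ischemic brain edema draws water into infarcted tissue and lowers its CT
attenuation. **Net water uptake (NWU)** quantifies this as the relative
density deficit of the lesion against its mirrored contralateral counterpart,

```
NWU = (1 − HU(A) / HU(B)) × 100  [%]
```

where `HU(A)` is the mean attenuation of the ischemic region A and `HU(B)`
that of the corresponding healthy region B in the opposite hemisphere. NWU is
a validated edema biomarker for acute ischemic stroke, but the usual workflow
needs a lesion mask drawn on CT perfusion or diffusion MRI. `nwuct`
implements a fully automated, deep-learning-free pipeline that needs nothing
but a single non-contrast CT (NCCT) volume:

1. **Spatial normalization** — resample to 1 mm isotropic, align to a
   left–right symmetric head template (rigid then affine, multi-resolution
   mutual information), split at the midsagittal plane, mirror one
   hemisphere, and register the hemispheres deformably (multi-scale
   symmetric-forces demons) for voxel-wise contralateral correspondence.
2. **NWU map** — keep parenchyma only (HU > 0, CSF/bone band thresholds,
   Sobel edge exclusion), apply masked 3D average pooling with an
   11×11×11 mm kernel (windows covering < 10% of the kernel — 133 voxels —
   are invalid), and evaluate the NWU formula window-by-window, in both sign
   conventions.
3. **Lesion extraction** — Otsu threshold over the pooled positive NWU
   values with a lower cutoff, largest connected component,
   erosion/dilation, cavity fill; the total NWU of the final mask is
   computed against its mirrored contralateral region.

The package also ships the evaluation panel used to score such pipelines
(Dice, any-voxel detection rate, bounding-box IoU with the 0.5^(3/2)
threshold, NWU error statistics) and a **synthetic head-phantom generator**:
digital skull/CSF/parenchyma/ventricle heads with one implanted hypodense
lesion whose ground-truth NWU is exact by construction, so the whole pipeline
is testable without clinical data.

Intended users: stroke-imaging researchers who want a transparent,
reproducible NWU baseline, and method developers who need a controlled test
bed with known ground truth.

## Worked example

Generate a two-case phantom suite and run the pipeline on the first case
(a left-sided 8 mL lesion with 5% implanted uptake):

```bash
nwu phantom --n 2 --seed 11 --out suite/
nwu run --input suite/case000_seed213907198_ct.nii.gz --out out/
```

prints

```json
{
  "side": "left",
  "volume_ml": 6.715,
  "nwu_total": 5.0,
  "otsu_threshold": 1.7775,
  "component_count": 1
}
```

The pipeline found a single lesion component in the left hemisphere of
6.7 mL whose mean attenuation is 5.0% below the mirrored contralateral
tissue — matching the implanted ground-truth uptake of 5%. `out/` contains
the lesion mask as NIfTI and a JSON report embedding the full configuration
and its content hash; `--save-intermediates` additionally writes the aligned
CT, the voxel-wise NWU maps and their validity masks. Benchmarking a suite
against its reference masks:

```bash
nwu bench --cases suite/ --out report/
```

writes a per-case CSV and a cohort summary (detection rate, NWU MAE/ME and
median AE, Dice median with IQR, and the fixed-threshold mAP).

All thresholds (HU bands, Sobel edge threshold, kernel size, coverage
fraction, NWU cutoff, morphology radii, registration settings, seeds) live
in a YAML config (`--config`); defaults are in `nwuct.RunConfig`.

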