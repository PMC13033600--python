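# tilscope

Automated quantification of tumor-infiltrating lymphocytes (TILs) in
H&E-stained histology images, built for computational-pathology work on
lung adenocarcinoma. The density and distribution of lymphocytes in the
tumor stroma is prognostic, but manual counting across high-power fields
(HPFs) is slow and rater-dependent. `tilscope` chains three analysis
stages and then asks the statistical question that matters clinically:
*do the machine's counts agree with pathologists'?*

1. **Tissue contour** — deterministic segmentation of the tissue region on
   a 2.5x thumbnail: Roberts edges → Otsu → iterated morphological
   closing, intersected with an HSV pink/purple gate
   (H 18–180, S 9–255, V 0–255 on the OpenCV-style scales) plus a median
   filter.
2. **Tumor parenchyma** — a lightweight nested-U segmentation network
   (residual U-blocks with dilated convolutions, side-output fusion,
   **1.13 M parameters**) trained with the composite loss
   `L = α·L_WBCE + β·L_Dice`, AdamW and a cosine schedule; tiled inference
   at 5x-equivalent resolution. Stroma = tissue ∧ ¬parenchyma.
3. **Lymphocyte detection** — a compact single-stage anchor-based detector
   (feature pyramid P3–P5, decoupled heads) trained with BCE
   classification + BCE objectness + Complete-IoU box regression

       L_CIoU = 1 − IoU + ρ²(b, b_gt)/c² + α·v,

   followed by confidence thresholding, greedy NMS and stromal gating.
4. **Quantification & agreement** — per-HPF counts in seeded 0.237 mm²
   fields, grading at <100 / 100–300 / >300 cells per HPF, and the full
   inter-rater battery: ICC(A,1) (two-way random effects, absolute
   agreement, F-based CI), Cohen's and Fleiss' kappa with bootstrap CIs,
   and Bland–Altman limits of agreement.

The neural stages run on a small numpy reverse-mode autodiff core
(`tilscope.nn`) — no deep-learning framework required — and every stage is
exercised end-to-end on a built-in seeded synthetic-scene generator with
exact ground truth (white glass, textured pink stroma, darker parenchyma,
dark lymphocyte discs at controllable density), so the whole pipeline is
testable on a laptop CPU. See `docs/methods.md` for the models,
parameters and limitations.

## Worked example

```python
import numpy as np
from tilscope import (SceneSpec, generate_scene, segment_tissue,
                      dice_coefficient, agreement_report, RatingsMatrix)

# a seeded synthetic H&E scene with exact truth
scene = generate_scene(SceneSpec(width=256, height=256, seed=42,
                                 lymphocyte_density=400))
mask, polygons = segment_tissue(scene.image)
print(f"tissue Dice vs truth: {dice_coefficient(mask, scene.tissue_truth):.3f}")
print(f"lymphocytes drawn: {len(scene.lymphocyte_truth)} "
      f"({scene.density_realized:.0f} cells/mm^2 of stroma)")

# agreement between two raters and a pipeline column of per-slide counts
rng = np.random.default_rng(0)
per_slide = rng.normal(180, 90, 10).clip(5)
counts = np.column_stack([per_slide + rng.normal(0, 12, 10) for _ in range(2)]
                         + [per_slide + rng.normal(-8, 15, 10)]).round()
rep = agreement_report(RatingsMatrix(counts, ["expert1", "expert2", "pipeline"]))
print(f"ICC(A,1) = {rep.icc.estimate:.3f} "
      f"(95% CI {rep.icc.ci_low:.3f}-{rep.icc.ci_high:.3f}, {rep.icc.strength})")
ba = rep.bland_altman[("expert1", "pipeline")]
print(f"Bland-Altman bias expert1-pipeline = {ba.bias:.1f} cells "
      f"(LoA {ba.loa_low:.1f} to {ba.loa_high:.1f})")
```

Output:

```
tissue Dice vs truth: 0.988
lymphocytes drawn: 38 (446 cells/mm^2 of stroma)
ICC(A,1) = 0.981 (95% CI 0.948-0.995, excellent)
Bland-Altman bias expert1-pipeline = 0.9 cells (LoA -19.7 to 21.5)
```

The tissue stage recovers 98.8% of the true tissue area (Dice) on this
scene; the agreement block says the simulated pipeline's counts correlate
with the experts' at ICC 0.981 ("excellent" per Cicchetti) and undercount
by 0.9 cells per slide on average.

## Command line

`tilscope` installs a CLI mirroring the library stages:

```sh
tilscope synth --out scenes/ --n 10 --seed 1      # synthetic scenes + truth
tilscope tissue --in slide.png --mag 20 --out-mask tissue.png
tilscope seg-train --data scenes/ --out seg.npz
tilscope det-train --data scenes/ --out det.npz
tilscope run --in slide.png --config pipeline.yaml --out outdir/
tilscope agree --counts counts.csv --out report.json
```

`run` writes `tissue.png`, `parenchyma.png`, `stroma.png`,
`boxes.geojson`, `counts.csv`, `report.json` and a `manifest.json` with
input hashes, config and seed, so runs are reproducible byte-for-byte.
Annotations use QuPath-dialect GeoJSON
(`properties.classification.name`), so expert polygon/point files import
directly and pipeline outputs open in QuPath.

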