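# mscstage

Image-based staging of early mesenchymal stem cell (MSC) differentiation,
plus chromatin-mobility and heterochromatin-intensity analysis.

## The problem

MSCs expanded in culture must stay "stem-like"; once adipogenic
differentiation starts, classical markers (lipid droplets, surface
antigens, gross morphology) only report it weeks later. Nuclear texture
changes much earlier. This package implements, as a tested and reusable
pipeline, the computational side of detecting those early changes:

1. **Segmentation** — widefield fields are converted 16-bit to 8-bit by a
   per-image min-max scaler, nuclei segmented on the DNA-stain channel by
   Otsu thresholding, regions with bounding boxes outside 50-100 px
   discarded, and fixed-size multi-channel frames cut around each
   nucleus.
2. **Augmentation and splits** — 4x expansion by right-angle rotations;
   repeated random train/test divisions grouped at the microscope-field
   level so no field leaks across folds.
3. **Staging models** — a compact 4-layer CNN (classification over the
   five timepoints {0, 6, 24, 48, 72} h, or regression of hours since
   induction), beside a Haralick-texture random forest, a nuclear-area
   baseline, and the uniform-random reference (20% for five balanced
   classes).
4. **Chromatin mobility** — rigid nuclear motion removal (2D Procrustes),
   LoG puncta detection and greedy linking, the chromatin displacement
   CD(tau) = ⟨(X_{t+tau}−X_t)² + (Y_{t+tau}−Y_t)²⟩, and the power-law fit
   CD = D_eff·tau^beta (log-log OLS), with rank-sum condition
   comparisons.
5. **Intensity quantitation** — mean fluorescent intensity of
   heterochromatin markers in nuclear ROIs, compared across timepoints by
   Kruskal-Wallis/Dunn or ANOVA/Tukey with star coding.

A synthetic microscopy generator (elliptical nuclei whose interior
texture grain drifts monotonically with differentiation time; exact
fractional-Brownian puncta trajectories with CD = d_eff·tau^beta by
construction) makes every stage verifiable without any image download.
See `docs/methods.md` for the models, assumptions, and design choices.

## Worked example

```python
import numpy as np
from mscstage import (
    StageParams, generate_stage_dataset, segment_dataset, make_splits,
    ModelSpec, SmallCNNClassifier, evaluate_on_split,
    TrajectoryParams, generate_trajectories, compute_cd, ensemble_cd,
    fit_power_law,
)

# ~1000 nucleus crops across 5 stages (20 synthetic fields per stage)
fields, truth = generate_stage_dataset(
    n_fields_per_stage=20, base_params=StageParams(n_nuclei=10), seed=7)
crops = segment_dataset(fields)
split = make_splits(crops, n_splits=1, test_fraction=0.25, seed=7)[0]

spec = ModelSpec(task="classification", input_channels=("nucleus",), seed=7)
report = evaluate_on_split(SmallCNNClassifier(epochs=25, random_state=7),
                           crops, split, spec)
print(f"{len(crops)} crops, test accuracy {report.accuracy:.3f}")

# chromatin mobility: recover the power law from simulated puncta
trajs = generate_trajectories(
    TrajectoryParams(d_eff=0.01, beta=0.5, n_trajectories=500, seed=2))
fit = fit_power_law(ensemble_cd([compute_cd(t) for t in trajs]))
print(f"fitted D_eff={fit.d_eff:.4f} um^2/s^b, beta={fit.beta:.3f}")
```

Output:

```
1000 crops, test accuracy 0.836
fitted D_eff=0.0101 um^2/s^b, beta=0.497
```

The classifier separates the five stages far above the 20% random
reference because interior GLCM contrast falls monotonically with stage;
the mobility fit recovers the generating parameters (d_eff = 0.01,
beta = 0.5) from the ensemble CD curve.

## Command line

```
mscstage simulate --what fields --seed 0 --out-dir sim
mscstage segment --input-dir sim --out-dir crops
mscstage split --manifest crops/crops.csv --n-splits 100 --seed 0
mscstage train --manifest crops/crops.csv --splits splits.csv --channels nucleus,actin
mscstage mobility --input trajectories.csv --pixel-size 0.293
mscstage quantify --measurements mfi.csv --test kruskal_wallis
mscstage run-all --out-dir run --seed 0
```

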