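# renalseg

Two-stage ("coarse-to-fine") kidney and kidney-stone segmentation for
unenhanced abdominal CT, with replaceable 3D segmentation backbones and a
built-in synthetic phantom generator so the entire pipeline is trainable
and testable on a laptop with no data download.

**Stage 1** segments kidney-vs-background on a downsized volume
(HU window −135…215, z-spacing harmonized to 1.25 mm, min–max
normalization, in-plane resize, center crop, overlapping z-cube tiling).
**Stage 2** derives one region of interest per kidney from the stage-1
mask (26-connected component analysis), crops it at full in-plane
resolution and segments kidney + stone (3 classes) inside each ROI.
ROI predictions are overlaid with label precedence stone > kidney >
background and mapped back to the original grid. A one-stage baseline
(direct 3-class segmentation) is included for comparison experiments.

The neural-network engine is pure NumPy (`renalseg.nn`): explicit
forward/backward layers (3×3×3 convolutions lowered to shifted BLAS
GEMMs, batch norm, max-pool, nearest upsampling), a combined soft-Dice +
cross-entropy loss with analytic gradients, AdamW, and reduce-on-plateau
scheduling. Reference backbones: a compact 3D U-Net and a residual-unit
Res U-Net; external scorers can be registered through the backbone
registry.

## CLI

```bash
# generate a labeled phantom cohort (NIfTI pairs + stone truth CSV)
renalseg simulate --out-dir cohort/ --n-cases 10 --seed 1

# train the two-stage bundle (desk profile; use --profile paper for the
# full-scale recipe: 200 epochs, batch 8, 96/48 + 64/32 cube geometry)
renalseg train --out-dir run/ --n-cases 12 --seed 1
renalseg train --out-dir run/ --data-dir cohort/ --backbone resunet3d

# apply a trained bundle and evaluate
renalseg infer --bundle-dir run/ --data-dir cohort/ --out-dir pred/
renalseg evaluate --pred-dir pred/ --truth-dir cohort/ --out-dir eval/

# seeded two-stage vs one-stage comparison
renalseg experiment-dependent-vs-independent --out-dir cmp/ --n-seeds 3
```

Configuration uses named profiles (`desk` for CPU-sized runs, `paper`
for the full-scale defaults) plus YAML overrides; every run directory
receives the resolved config, seed and config hash. Unknown config keys
are rejected by name.

## Layout

| module | role |
| --- | --- |
| `renalseg.phantom` | seeded synthetic CT phantoms + ground truth |
| `renalseg.nifti` | NIfTI read/write (canonical orientation, spacing) |
| `renalseg.preprocess` | HU window, z-resample, normalize, resize, label merge |
| `renalseg.patchwork` | center crop, z-cube clipping, overlap stitching, ROIs |
| `renalseg.augment` | hflip / random-affine cube augmentation |
| `renalseg.nn` | NumPy layers, losses, optimizers |
| `renalseg.models` | backbone registry: 3D U-Net, Res U-Net, constant |
| `renalseg.trainer` | case-level splits, training loop, checkpointing |
| `renalseg.pipeline` | two-stage and one-stage inference |
| `renalseg.evaluation` | Dice/specificity/sensitivity/accuracy, success rate, stone-size-stratified reporting |
| `renalseg.experiments` | seeded phantom recovery + dependent-vs-independent |
| `renalseg.cli` / `renalseg.config` | entry point, profiles, YAML config |
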