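# sweetdot

Tools for studying how the surface arrangement of a sweetener changes taste
perception in surface-structured chocolate: dot-pattern design under a
constant-tastant-load constraint, bitmap-to-valve-schedule inkjet
rasterization, image-based dot geometry reconstruction, biomimetic
tongue-surface synthesis with a tastant smear model, and the accompanying
sensory-panel statistics. A synthetic-data module generates panel ratings,
dot image pairs and stained-tongue images with known ground truth, so the
entire pipeline is testable offline.

## Modules

| module | purpose |
| --- | --- |
| `sweetdot.patterns` | ink formulations (A–D), canonical dot-pattern designs (Bulk, Homogeneous, Spaced Full/Half/Quarter, Centered, Periphery, Layer), spacing metrics, micro/meso classification, tastant-load ledger, bitmap/JSON export |
| `sweetdot.raster` | bitmap → serpentine peak-and-hold valve-event schedule with drop-deflection correction, mass ledger, jittered deposition simulation |
| `sweetdot.dotrecon` | binarization, top-view equivalent radius, side-view contour + parabola fit with 95 % t-intervals, closed-form paraboloid lateral area, pattern stimulus size A·C |
| `sweetdot.tongue` | papillae segmentation and placement, paraboloid papilla height field, OBJ mesh export, oscillatory-shear smear exposure map and anterior/posterior split |
| `sweetdot.sensory` | mixed two-way ANOVA (sample × timepoint fixed; assessor, session random blocks), Tukey HSD per timepoint, percent amplification vs a reference, stimulus-size linear model with confidence band |
| `sweetdot.synth` | seeded generators for panel ratings, dot image pairs and stained-tongue images with ground truth |

## CLI

```bash
sweetdot design --name sp_quarter --out pattern.json --bitmap pattern.png
sweetdot print --bitmap pattern.png --out schedule.csv
sweetdot reconstruct --top top.png --side side.png --scale 0.01 --out dots.csv
sweetdot tongue --bbox 30x20 --seed 7 --obj tongue.obj
sweetdot smear --pattern pattern.json --half-amplitude 5 --out exposure.csv
sweetdot sensory --ratings ratings.csv --reference Bulk --out results/
sweetdot simulate ratings --part micro --seed 42 --out ratings.csv
sweetdot simulate dot --a 0.8 --h 0.32 --out dot/
```

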