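# kymoquant

Quantitative analysis of single-molecule optical-tweezers/confocal
experiments on DNA-compacting proteins, built around the assay in which a
fluorescently labelled tetrameric DNA-bridging protein (four dyes per
tetramer, one DNA-binding domain at each end) interacts with a λ-DNA tether
held between two trapped beads.  It is intended for single-molecule
biophysicists who record kymographs (repeated confocal line scans along the
DNA), force–distance curves, and flow-cell images, and who need calibrated,
reproducible numbers out of them.

The package provides:

* **Synthetic data generation** with full ground truth — Brownian sliding of
  tetramers on the tether, cluster formation upon transient relaxation
  (16 µm → 8 µm → 16 µm at 0.6 µm/s with a ~5.5 s hold), Poisson photon
  statistics (Gaussian profiles of sd *s* = 100 nm at *d* = 75 nm pixels),
  exponential photobleaching with quadratic laser-power dependence,
  worm-like-chain mechanics, and bridged-DNA flow images.
* **Photometry** — scan-line Gaussian fitting, photobleaching-*step*
  calibration of the single-fluorophore yield *A* (photons/scan line),
  bleaching correction I<sub>total,0</sub>/I<sub>total,t</sub>, and cluster
  stoichiometry N = amplitude · correction / (4A).
* **Tracking** — sub-pixel peak localization and nearest-neighbour linking,
  with static/diffusive classification.
* **Diffusion** — time-averaged MSD(τ) = 2Dτ + c fitting, plus a
  rotation-coupled-sliding calculator
  D = k<sub>B</sub>T e<sup>−ε</sup> / [6πηR + (2π/b)²(8πηR³ + 6πηR·R<sub>OC</sub>²)].
* **Footprints** — two independent per-binding-domain footprint estimators:
  f = (ΔL − n<sub>clusters</sub>·P) / (2·N<sub>tetramers</sub>) from
  force–distance compaction at 25 pN (P = 50 nm), and
  footprint = box length / N with N = (I<sub>box</sub> − I<sub>bg</sub>)/(4·I<sub>ref</sub>),
  I<sub>ref</sub> = A·2π(s/d)², from flow-stretched bridged DNA.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Every estimator can be exercised against the generator's ground truth
through `kymoquant.recovery`:

```python
from kymoquant.recovery import (
    recover_step_calibration, recover_cluster_mean,
    recover_diffusion_constant, recover_compaction_footprint,
    recover_flow_footprint)

print(recover_step_calibration(seed=1))
# {'photons_per_fluor': 1.577..., 'photons_per_tetramer': 6.308..., 'n_steps': 39}
print(recover_cluster_mean(seed=1))
# {'mean_tetramers': 68.27..., 'true_mean_tetramers': 68.46, 'configured_mean': 67.0, 'n_clusters': 50}
print(recover_diffusion_constant(seed=1))
# {'D_mean': 0.1538..., 'D_sd': 0.0221..., 'D_true': 0.16, 'n': 8}
print(recover_compaction_footprint(seed=1))
# {'footprint_nm': 2.610..., 'sd_nm': 0.004..., 'planted_nm': 2.7, 'n_molecules': 3}
print(recover_flow_footprint(seed=1))
# {'footprint_nm': 3.618..., 'sd_nm': 0.035..., 'planted_nm': 3.6, 'n_boxes': 16}
```

Reading the output: 39 photobleaching steps detected across 10 synthetic
molecules average 1.58 photons against a true single-dye yield of 1.5
(hence 6.3 photons per 4-dye tetramer); bleaching-corrected photometry on
50 clusters recovers a mean of 68.3 tetramers against a drawn truth of
68.5 (distribution mean 67, range 20–160); MSD fits on 8 trajectories give
D = 0.154 ± 0.022 µm²/s at a true 0.16; and the two footprint estimators
recover 2.61 nm and 3.62 nm against planted values of 2.7 nm and 3.6 nm.

The same stages are available as a CLI:

```sh
kymoquant simulate --seed 2 --out kymo.tif     # kymograph + ground truth
kymoquant track kymo.tif --out trajectories.csv
kymoquant clusters kymo.tif
kymoquant diffusion kymo.tif
kymoquant rotation-model                       # model calculator
kymoquant run --seed 2 --out results_dir       # full pipeline, JSON bundle
```

`kymoquant rotation-model` prints, with the default parameters (b = 3.4 nm,
ε = 1.33 k<sub>B</sub>T, R = 10 nm, R<sub>OC</sub> = 11 nm):

```
barrier form: exp (factor 0.2645)
D_rotation-coupled = 0.006639 um^2/s
D_translational    = 5.773 um^2/s
ratio D_trans/D_rot = 870
```

The calculator reports its value transparently; see `docs/methods.md` for
why variant readings of the underlying friction model give different
magnitudes.

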