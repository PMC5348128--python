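# Methods

`kymoquant` quantifies single-molecule optical-tweezers/confocal experiments
in which a fluorescently labelled, tetrameric DNA-bridging protein (four
Alexa555-class labels per tetramer, one DNA-binding domain at each end of the
coiled-coil strut) binds a λ-DNA tether held between two trapped beads.  The
package contains both the estimators and a synthetic generator that emulates
the experiment with full ground truth, so every estimator is validated by
recovery rather than by fiat.

## The synthetic experiment

**Scenario.**  The default protocol holds the tether extended at 16 µm
(~5 pN), moves one bead at 0.6 µm/s to an 8 µm separation, holds ~5.5 s while
DNA-bridging clusters nucleate, and re-extends at 0.6 µm/s.  An observation
window of 10 s (configurable) is prepended and appended so that diffusive and
static behaviour can both be measured at constant separation.

**Tetramer motion.**  Mobile tetramers perform 1D Brownian motion with
per-line step variance 2·D·Δt (default D = 0.16 µm²/s, Δt = 20 ms) and
reflecting boundaries at the beads.  While a bead moves, all positions advect
affinely with the separation (material points of the tether spread
proportionally); static cluster members therefore appear static at constant
separation and move ballistically during pulling, as real kymographs show.
The line period is not part of the emulated instrument's published
description; 20 ms is a typical confocal line-scan period and every estimator
takes the period from the data, not from a constant.

**Cluster formation** is phenomenological: at the start of the hold each
tetramer independently converts to a cluster member with probability
`cluster_conversion_probability` (default 0.9); converted tetramers are
partitioned into clusters whose sizes follow a truncated lognormal (fixed log
sd 0.45, location solved so the truncated mean equals the configured mean —
default mean 67, range 20–160 tetramers).  No binding/unbinding kinetics are
modelled; the visualisation phase assumes zero dissociation, matching the
assumption built into the bleaching correction.

**Rendering.**  `photons_per_fluor_per_line` (default 1.5 photons) is the
*peak amplitude* of the Gaussian profile (sd 100 nm, sampled at 75 nm pixels)
a single fluorophore contributes per scan line, because that is how the
calibration value is defined photometrically.  Emission scales linearly with
laser power; the photobleaching rate scales *quadratically*
(two-photon-mediated bleaching under pulsed excitation), with per-fluorophore
bleach times drawn exponentially.  Pixel values are Poisson draws of
signal + background (default background 0.2 photons/pixel/line, a typical
confocal dark/scatter level).  Because the point-spread sd (100 nm) exceeds
the pixel size (75 nm), point-sampling the Gaussian at pixel centres differs
from per-pixel integration by <1%; the point-sampled form is used throughout
so the renderer and the fitting model agree exactly.

**Mechanics.**  Force–extension follows the Marko–Siggia worm-like-chain
interpolation with persistence length 50 nm; enthalpic stretching is ignored
below 30 pN.  λ DNA's contour length defaults to 16.4 µm (48,502 bp ×
0.338 nm/bp); the free curve reaches ~15.3 µm at 5 pN, consistent with the
"near 16 µm" working extension of the assay.  A compacted tether has
effective contour length L − (sequestered DNA) − (one 50 nm loop allowance
per cluster), so its force–distance curve lies strictly above the free one.

**Flow images** place tetramers along bridged segments at linear density
1/footprint — each tetramer engages one binding domain on each duplex of a
bridged parallel pair, so consecutive tetramers advance one footprint — with
4 labels each, rendered as 2D Gaussians with Poisson noise.

All randomness flows through one `numpy` Generator per operation, seeded
explicitly; identical seeds give bit-identical outputs.

## Estimators

**Scan-line photometry.**  Amplitudes are least-squares Gaussian+constant
fits.  For dim single emitters (a few photons/line) the width is pinned to
the known 100 nm point-spread sd: with a free width the fit latches onto
shot-noise spikes and overestimates the amplitude substantially.  Bright
cluster profiles are fitted with a free width.  Non-convergent fits are
flagged, never silently dropped.

**Photobleaching steps.**  Changepoints are located on the summed
photons-per-line trace by penalized least-squares optimal partitioning
(L2 cost, penalty 2·σ²·ln n with σ estimated from first differences —
the classical model-selection penalty; a larger factor was found to merge
near-threshold single-fluorophore steps).  Within each plateau the scan
lines are averaged and one Gaussian fitted; step sizes are the decreases in
fitted amplitude between consecutive plateaus.  The mean step size is the
single-fluorophore yield; four labels per tetramer give the per-tetramer
amplitude (the 4× identity holds exactly by construction).  The calibration
cascades are generated with a bleach rate of 0.1 s⁻¹ so that a complete
4-fluorophore cascade fits in a ~1200-line trace; the recovered *step size*
is independent of this rate.

**Bleaching correction.**  The correction factor is I_total(0)/I_total(t),
with I_total summed over the DNA length and averaged over a 10-line band at
each endpoint to tame shot noise.  It assumes all intensity loss is
photobleaching (no dissociation); that assumption is inherited, not tested.

**Cluster size** = fitted amplitude × correction ÷ (4 × single-fluorophore
yield), exactly linear in both factors.

**Bleach rate** is a single-exponential least-squares fit to the integrated
intensity.  At the nominal 5·10⁻⁵ s⁻¹ a ≥20% decay needs thousands of
seconds, so the recovery experiment samples the decay with a 10 s line
period over 10⁴ s (equivalent to analysing a temporally binned trace).  The
power-law exponent of rate vs power is the log–log slope across three
powers; each power level averages several molecules because a finite
fluorophore pool makes single-molecule rate estimates noisy.

**Tracking** detects per-line Gaussian peaks above a threshold (default
2 × single-fluorophore yield = 3 photons over background) and links them
greedily to the nearest active trajectory end, with a maximum jump of
3 pixels/line (≈3 sd of the Brownian step at default D and line period), a
3-line gap tolerance, and ties broken by smallest displacement then larger
amplitude.  Trajectories shorter than 10 detections are dropped.  A
trajectory is *static* when its positional sd stays below 1.5 pixels in
every 20-sample window, *diffusive* otherwise, *ambiguous* under 10 samples.

**Diffusion.**  The time-averaged MSD uses all ordered pairs at each lag
(verified bit-level against an O(n²) enumeration).  D comes from a weighted
linear fit MSD = 2Dτ + c over lag indices 2–10: lag 1 is excluded as
localization-noise dominated and the intercept absorbs the remaining static
noise.  MSD requires uniform sampling, so gapped trajectories are split into
gap-free runs first.

**Rotation-coupled sliding.**  The calculator evaluates
D = k_BT·exp(−ε) / [6πηR + (2π/b)²·(8πηR³ + 6πηR·R_OC²)] with defaults
b = 3.4 nm/turn, ε = 1.33 k_BT, R = 10 nm, R_OC = R + R_DNA = 11 nm,
η = 10⁻³ Pa·s, T = 298 K (η and T are conventional choices, configurable).
With these defaults it returns ≈6.6·10⁻³ µm²/s and a translational/rotational
ratio ≈870.  Published variants of this model differ in how the barrier and
the rotational friction enter; the rough-landscape barrier exp(−ε²) is
available behind `barrier_form="rough"`, and every output states which form
was used.  The calculator's output is reported, never asserted against a
measured diffusion constant.

**Footprints.**  The compaction estimator reads both curves at 25 pN by
linear interpolation of the bracketing samples and applies
f = (ΔL − n_clusters·50 nm)/(2·N_tetramers).  Note a small, understood bias:
lengths at 25 pN are fractional extensions (z ≈ 0.971) of the contour
difference, so the estimator recovers ≈0.97× the planted footprint.  The
flow-box estimator uses N = (I_box − I_bg)/(4·I_ref), I_ref = A·2π(s/d)²
(= 16.8 photons at A = 1.5, s = 100 nm, d = 75 nm), and
footprint = box length/N; boxes are tiled along the segment with a ±300 nm
band (3 point-spread sds), an equal-size background box offset
perpendicular to the DNA, and a 500 nm end margin against spill-over.  The
factor 4 assumes full labelling; partial labelling inflates the apparent
footprint proportionally and is supported only in the generator for
robustness studies.

## What the generator does not emulate

Real kymographs contain protein dissociation and rebinding, blinking,
instrument drift, bead-position noise, non-Gaussian tails of the confocal
point-spread function, and spatially structured background — none of which
are modelled.  Clusters are rendered as point-like (all member tetramers at
the anchor); extended clusters would bias Gaussian-amplitude photometry low.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every instrumental artefact.

## Problem sizes

Recovery experiments default to 10 bleach cascades (~40 steps), 50–120
rendered clusters, 8 trajectories of 600 lines for the headline diffusion
number (50 per condition for the sweep over D), 3 molecules for the
compaction footprint and ≥13 flow boxes — matching the scale of the
emulated study where it states one, and otherwise sized so that sampling
error is comfortably below each estimator's tolerance.

## Known limitations

* Changepoint segmentation merges bleach steps separated by fewer than ~5
  lines; at high bleach rates the step count is underestimated.
* The greedy nearest-neighbour linker does not disambiguate crossing
  trajectories.
* The bleaching correction is exact only under zero dissociation.
* The compaction footprint carries the ≈3% fractional-extension bias noted
  above; it is well inside the estimator's quoted tolerance and left
  uncorrected to keep the formula in its standard form.
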