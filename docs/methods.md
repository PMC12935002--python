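# Methods

## The two-state spectral model

roGFP2 is modeled as a two-state sensor. The fully oxidized and fully
reduced forms have fixed excitation spectra S_ox(λ) and S_red(λ); a
population with oxidation fraction OxD emits proportionally to the linear
mixture `OxD·S_ox + (1−OxD)·S_red`. The endmember curves are synthetic
smooth shapes chosen to match the qualitative spectroscopy of the sensor:
S_ox is a two-Gaussian curve with its dominant peak at 395 nm (σ = 25 nm,
amplitude 1.0) and a minor shoulder at 470 nm (σ = 20 nm, amplitude 0.30);
S_red is a single Gaussian peaked at 470 nm (σ = 20 nm, amplitude 1.0).
The imaging-side efficiencies are these curves evaluated at the 395 and
470 nm excitation lines, so the bulk-assay and imaging models agree exactly:
for the same OxD, the noise-free bulk ratio equals the imaging true ratio.
With these defaults the true ratio runs from ≈0.0009 (fully reduced) to
≈3.22 (fully oxidized) and is strictly increasing in OxD — the package's
core invariant, tested property-style.

The measured quantity is always

    R395/470 = max(I395 − b395, 0) / max(I470 − b470, 0)

with backgrounds b estimated as the mean intensity of probe-free wild-type
objects (global per condition by default; per-frame available). Negative
subtracted values are clipped to zero; a zero denominator makes the ratio
undefined, and undefined objects are excluded from all aggregates and
counted in the QC funnel rather than coerced to 0 or ∞. The ratio is
exactly invariant under common rescaling of intensities and backgrounds
(concentration independence).

## Synthetic scenes

The generator emulates rod-shaped cells on an agar pad imaged every 20 min
in four channels. Cells are capsules (default width 11 px, tip-to-tip
length 26 ± 3 px) placed by rejection sampling with a 3-px minimum gap; a
scene that cannot be placed within the retry budget raises an explicit
error. Channels: ex-395 and ex-470 carry camera background (100 counts),
cellular autofluorescence (+50 counts inside cells) and the probe signal
`gain·probe·(OxD·s_ox + (1−OxD)·s_red)` on probe pixels (whole cell for
cytosolic strains, default probe level 1000; puncta only for
carboxysome/procarboxysome strains); the chlorophyll channel marks all
cells (800 counts); brightfield renders cells bright (1000) on a dim
pad (200). Default noise is Poisson shot noise plus Gaussian read noise
(σ = 3 counts), matching an sCMOS-style camera without modeling its
specifics; an optional Gaussian blur stands in for the PSF and is off by
default.

Puncta are grown as 4-connected pixel regions from seeds spaced along the
cell axis, with a 1-px exclusion ring between puncta of the same cell so
distinct carboxysomes never touch; growth is capped by the available cell
area, which guarantees puncta ⊆ cell and keeps each punctum a single
connected component (an invariant of the emitted label maps).

Oxidation dynamics: each object draws a per-condition target OxD from a
Gaussian (sd 0.04) around its strain's condition mean and relaxes toward
the current target with first-order kinetics (τ = 60 min) whenever the CO2
schedule switches — the minimal kinetic law consistent with shifts that
play out over hours. A +0.10 OxD transient decaying with the same τ
emulates the initial equilibration to the imaging environment; analyses
exclude a 3 h burn-in (the upper end of the observed 2–3 h adjustment) and
a 3 h settling window after each condition switch. An optional per-strain
persistent offset after a high→air return generates hysteresis.

Default study population (absolute OxD values are modeling choices — the
biology constrains only orderings and shifts): cytosol 0.35 (air) / 0.20
(3% CO2); procarboxysome 0.40 / 0.25; carboxysome 0.80 / 0.60, with 40% of
carboxysomes dropping to a procarboxysome-like reduced mode at OxD 0.25
under 3% CO2 (Ashman D ≈ 7 in ratio space between the two modes).
Division (probability 0.03/frame, off for the air-inviable procarboxysome
mutant) replaces a mother with two daughters holding fresh object ids; no
lineage tracking. The default study images 100 cells per strain (four
strains including WT) on a 1024×1024 grid for 30 frames with the air→3%
switch at frame 15.

## Segmentation

Cells: per-frame Otsu threshold (fixed threshold available) on
brightfield, connected components (8-connectivity), then a watershed on
the smoothed distance transform with seeds from `peak_local_max`
(min distance 25 px, at least one seed forced per component). On
non-touching objects this reduces exactly to connected-component labeling
(tested as an oracle equivalence). Objects under 100 px and objects
touching the border are dropped. Curation removes objects whose mean
chlorophyll falls below 30% of the frame's median object chlorophyll
("dead") or whose solidity is below 0.85 / area above a cap ("overlap");
removals are logged with reasons. Puncta: Otsu over in-cell pixels of the
GFP signal, 4-connected components, parent = cell containing the centroid
(majority overlap as fallback, ties to the lower label, logged). Puncta
smaller than 62 px are excluded for the procarboxysome strain class by
default (configurable per strain); a punctum of exactly 62 px is retained.

## Population statistics

Time series report per-group, per-frame mean ± SEM (sd/√n, undefined for
n < 2) with n varying as cells divide. Bimodality is decided by fitting 1-
and 2-component Gaussian mixtures (k-means initialization, fixed seed,
reg_covar 1e-6) and declaring two modes only when ΔBIC = BIC₁ − BIC₂ > 10,
the components are separated by Ashman D ≥ 2, and both components carry at
least 5% of the mass. The weight floor exists because a component tracking
a handful of outliers is a degeneracy of the mixture fit, not a
subpopulation. The pipeline feeds the detector one value per object — the
terminal frame of each condition window — because pooling frames repeats
every (untracked) object many times, and those near-duplicate atoms
violate the independence the mixture model assumes; pooled sampling
remains available. On unimodal Gaussian samples the detector's
false-positive rate is ≈0 (Monte-Carlo tested at ≤5%).

Group comparisons use the classical unpaired two-tailed equal-variance
t-test, with stars at p < 0.05 (*), < 0.001 (**), < 0.0001 (***); the
star ladder is configurable. No multiple-testing correction is applied by
default. Hysteresis compares the pre-shift steady state against an
equal-length window ending the series after the return, via a two-tailed
Welch test over per-frame means (window variances differ by construction);
the sign convention is pre − post, positive meaning more oxidized before
the shift.

## Bulk assay

Chlorophyll a is quantified from methanol-extract absorbance as
Chl a [µg/mL] = 16.29 × A665, with the dilution factor to the 3 µg/mL
assay target. Spectra span 350–480 nm at 1-nm steps (131 points, emission
510 nm). Ratios are computed per replicate against WT mean backgrounds at
395/470 nm and then averaged (mean-of-ratios; ratio-of-means available);
replicates with non-positive denominators are excluded and counted.
Wavelengths other than 395/470 nm are carried for plotting only. The
treatment panel compares DTT- and H2O2-treated replicates against the
untreated baseline with the same t-test.

## What the generator does and does not emulate

Passing tests demonstrate that the analysis chain recovers known
ground truth under the stated imaging model: uniform-intensity rods,
shot + read noise, no photobleaching, no focus drift, no illumination
gradients, no 3-D optics, hard-edged objects unless blur is enabled. Real
data add texture, PSF mixing between adjacent structures, and segmentation
errors the curation rules only partially model, so quantitative error
bounds measured here (noise-free recovery to 1e-9; median absolute ratio
error ≤ 0.02 at default noise) should be read as upper bounds on algorithmic
error, not instrument error. Strain identity comes from ground-truth labels
in simulation mode; on real data it must be supplied per cell.

## Numerical and design notes

- Problem sizes: the default study (100 cells/strain, 30 frames,
  1024×1024) and a 768×768 single-frame recovery scene (~210 objects) were
  chosen to give stable population statistics while keeping a full run in
  tens of seconds.
- Determinism: one `numpy` Generator seeded from the scene/config seed
  drives placement, kinetics and noise; identical configs give bit-identical
  stacks, truth tables and summaries.
- Degenerate inputs: constant image under Otsu → explicit error; no WT
  objects → explicit error (never a silent zero background); two constant
  equal groups → p = 1 by convention with a warning; samples below the
  bimodality minimum n → explicit insufficient-data result.
- The ratiometric overlay clips to configurable limits, (0, 0.3) for
  timelapse views and (0, 0.5) for puncta close-ups, rendering undefined
  objects in a sentinel gray on a black background (viridis by default).
- Known limitations: no lineage tracking; no flat-field correction; no
  absolute redox-potential (Nernst) calibration; the bulk assay's 510 nm
  vs the microscope's 520 nm emission setting is treated as instrument
  metadata, with no correction attempted.
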