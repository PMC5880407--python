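# Methods

`spindlequant` models and quantifies the single-cell readouts of budding-yeast
mitosis obtained by live-cell fluorescence microscopy: the 3D distance between
spindle pole bodies (SPBs) as a proxy for spindle length, rule-based
classification of spindle-elongation phenotypes, sister-chromatid separation
and segregation statistics from a lacO/lacI-GFP dot assay, and region-based
quantification of the pericentric Cohesin "barrel". This note documents the
models, the defaults and their units, the numerical choices, and what the
synthetic data do and do not establish about real recordings.

## Kinetic model of spindle elongation

All trajectories are formation-anchored: t = 0 is the frame at which two SPB
foci first resolve (SPB separation), and all intervals are measured from it.
The frame grid is the acquisition grid — by default 61 frames at 1-min
intervals. Three phenotype classes are generated as piecewise-linear kinetics
plus Gaussian measurement noise on length (default sd 0.1 μm, emulating
localization error; camera shot noise is modelled separately at the pixel
level in rendered stacks):

* **normal** — the spindle forms at `formation_length_mean` (1.0 μm) and
  drifts at `metaphase_drift_rate` (0.05 μm/min, i.e. ~1 → 2 μm over 20 min)
  for a metaphase duration drawn from a truncated normal (mean 22.4 min, the
  wild-type average; sd 4 min), then elongates at `anaphase_rate` (1 μm/min)
  to a plateau of 8 μm. The plateau value is a typical final anaphase-B
  spindle length in budding yeast; some terminal length is needed to end the
  ramp, and the classification rules are insensitive to its exact value.
* **immediate** — continuous elongation from formation at a rate drawn
  uniformly from `immediate_rate_range` (0.2–0.6 μm/min), constrained to lie
  strictly between the metaphase drift rate and the anaphase rate, matching
  the observation that these cells elongate faster than a metaphase drift but
  slower than anaphase. Transient shortening events occur as a Poisson
  process (0.05 events/min within 8–50 min, thinned to ≥ 5 min apart so dips
  never stack); each event drops the length by `shortening_depth` (0.5 μm)
  with an exponential recovery over 2–4 min. The event shape is a modelling
  choice: the phenomenon is described qualitatively in the literature with no
  kinetics, and the thinning keeps the class-conditional guarantee (an
  immediate cell at rate ≥ 0.2 μm/min always trips both early rules) exact.
* **failed** — slow drift capped at `failed_max_length` (4 μm), kept well
  below the 6 μm threshold so that measurement noise cannot push a failed
  cell across it.

The metaphase-duration sd and the immediate-rate distribution are free
parameters: no dispersion values exist for them in the literature this
emulates, so the defaults are declared configuration, not facts.

Sister-chromatid behaviour: the separation time is normal with mean
`separation_offset_mean` (6.71 min, the Securin-depleted `cdc55Δ` condition)
and sd 3 min, and **may be negative** — separation before SPB separation is a
real, observed event and is preserved with its sign in the generator; the
0-floor is applied only by the timing statistic. Fate is a Bernoulli draw:
with probability `missegregation_prob` (0.3) both sisters end at one pole
("failed" segregation) and the cell is excluded from timing statistics and
tallied separately.

## Rendering model

Each focus (SPB, lacO dot) is an anisotropic 3D Gaussian (default σ_xy =
0.10 μm, σ_z = 0.35 μm) integrated per voxel with error functions, so the
rendered counts equal the requested integrated counts up to field-of-view
truncation (≤ 1%). Two acquisition geometries are provided: the trajectory
assay (17 z-slices at 0.5 μm, 0.107 μm pixels, 61 × 1-min frames) and the
Cohesin assay (`OpticsParams.cohesin()`: 5 planes at 200 nm, 0.0645 μm
pixels). The Cohesin channel renders a nuclear sphere (radius 0.9 μm,
200 counts/voxel) containing a cylindrical barrel (radius 0.35 μm) between
the SPBs whose intensity is `barrel_ratio_true` × the nuclear level, over a
uniform camera background. Noise is Poisson by default (shot noise
dominates); Gaussian and noiseless variants exist for testing. Spindles are
oriented with a random azimuth and a z-tilt within ±20°, reflecting that
anaphase spindles lie close to the focal plane; the generator does not model
photobleaching, stage drift, cell-to-cell background variation, or nuclear
envelope deformation, so passing tests demonstrate estimator correctness
under the stated optical model, not robustness to those artifacts.

## Focus localization and spindle length

Foci are local maxima above an adaptive threshold (frame median + 6 × MAD;
the raw MAD is used, not the normal-consistent scaling — the factor is
configurable and only sets the detection floor), separated by ≥ 2 voxels,
refined by an intensity-weighted centroid over a 7×7×5 voxel window after
median subtraction, and reported brightest-first in physical μm (0-based
pixel centers at integer coordinates). Spindle length is the Euclidean
distance between the two brightest SPB detections of a frame; staging uses
one focus → pre-mitotic, two foci < 2 μm → short spindle, ≥ 2 μm → long
spindle. On synthetic 17-slice stacks at SNR ≥ 10 the centroid estimator
recovers 3D length within 0.1 μm in > 95% of draws (measured over 200
stacks); a Gaussian fit would be the next refinement if sub-0.02 μm accuracy
were needed.

## Region quantification (5×5 / 6×6)

Integrated fluorescence at a point of interest is measured in a 5×5 pixel
box; an enclosing 6×6 box provides an 11-pixel background ring whose sum,
scaled by the inner/ring area ratio 25/11, is subtracted from the inner sum.
A 6×6 box cannot share the exact center of a 5×5 box; the convention here is
inner [c−2, c+2]², outer [c−2, c+3]² (one pixel toward +row/+col), logged in
output so the asymmetry is auditable. Any fixed placement preserves the two
invariants the tests enforce: exact linearity, and exact cancellation on a
uniform plane. Boxes clipped by the image border are an error, not a silent
shrink.

## Barrel / nuclear fluorescence ratio

The pericentric Cohesin enrichment is the maximal fluorescence between the
SPBs over the nuclear (chromosome-arm) fluorescence, with 1 meaning no
enrichment. Implementation choices, made where the measurement was
genuinely underdetermined:

* **z-handling** — the shallow 5-plane stack is reduced by averaging the
  three central planes. A maximum-intensity projection was considered and
  rejected: the per-pixel maximum of noisy planes is upward-biased by an
  amount that differs between barrel and nuclear regions, which both biases
  the ratio and breaks its anchoring at 1.
* **numerator** — 5×5 region means sampled at every pixel along the
  inter-SPB segment, maximum taken. The ring-subtracted region signal is
  *not* used here: the barrel (diameter ~0.7 μm) is wider than the 6×6 ring,
  so ring subtraction would remove the structure being measured.
* **denominator** — the *same* max-along-segment statistic evaluated on
  copies of the segment shifted perpendicular to the spindle axis into the
  nuclear reference region, averaged. A plain nuclear mean would leave the
  numerator's max-of-noise bias uncancelled (~2% at the default SNR, enough
  to keep every no-enrichment measurement above 1); the matched statistic
  cancels it, so at `barrel_ratio_true` = 1 the estimates straddle 1.
* the camera offset (median of the plane; valid because the nucleus occupies
  a minority of the field) is subtracted from both sides, making the ratio
  exactly invariant to multiplicative gain changes.

Measured recovery on 50 noiseless-kinetics cells per level: 1.00, 1.48, 1.96
at true ratios 1.0, 1.5, 2.0 (the residual −2% at 2.0 is barrel-edge
dilution of the outermost axis samples). Pre-mitotic cells (single SPB) are
measured in the 7×7-pixel region adjacent to the focus with the same control
construction.

## Trajectory classification

Three rules, evaluated on raw (unsmoothed) lengths at the sampled frames,
intervals half-open (0, T] so the formation frame itself is excluded:

| rule | definition |
| --- | --- |
| r10 | length > 2 μm at any sample in (0, 10] min (strict, "more than") |
| r15 | length > 2.5 μm at any sample in (0, 15] min (strict) |
| reach6 | length ≥ 6 μm at any sample in (0, 60] min (inclusive, "to 6 μm") |

Precedence: `not reach6` → **failed** (the three categories are mutually
exclusive and failure is tabulated regardless of early kinetics); r10 = r15
→ **immediate**/**normal** directly; disagreement is a conflict curated as
follows. For r10 ∧ ¬r15 ("immediate/normal"): a single-time-point crossing
of 2 μm together with a clear anaphase inflection → normal; no clear
inflection plus spindle shortening (a frame-to-frame drop ≥ 0.2 μm, 2× the
default length noise) within [10, 15] min → immediate. For ¬r10 ∧ r15
("normal/immediate"): a clear inflection with breakpoint in [10, 15] min →
normal; no clear inflection plus slow continuous elongation (positive median
frame-to-frame increment over (0, 30]) → immediate. "Crossed in a single
time point" is ambiguous between a transient one-frame excursion and a
one-step jump ≥ 1 μm; both readings are implemented behind
`crossing_mode`, default transient. A conflict neither clause resolves falls
back to the verdict of the longer-horizon 15-min rule and is flagged
`unresolved`; every result carries its curation identifier so provenance is
auditable.

The anaphase-onset inflection is the best continuous two-segment (hinge)
least-squares fit: the trace is median-smoothed (window 3 — smoothing is
applied *only* here, never before rule evaluation, because the thresholds
are defined on measured lengths), truncated three frames after it first
comes within 5% of its maximum (so the hinge tracks elongation onset rather
than the terminal plateau, with a floor of 12 samples so noise-only traces
are not over-truncated), and every interior sample is tried as the hinge.
"Clear" requires post-slope ≥ 3 × max(pre-slope, 0.05 μm/min) and ≥ 50%
SSE reduction over a single line; these thresholds operationalize a visual
criterion and are declared configuration. On pure-noise traces (sd 0.1 μm)
the false-"clear" rate is below 5%.

Useful structural properties, all under test: the classifier is
deterministic; adding a constant to a trace can never turn an immediate call
into a normal one; on noiseless class-conditional simulations with metaphase
duration > 15 min and immediate rates ≥ 0.2 μm/min, recovery of the
generating class is exact.

## Population statistics

Separation timing = max(0, separation time): separation preceding spindle
formation is recorded as 0. Failed-fate cells are excluded from timing and
reported as fate fractions over exactly the scored n; censored cells (no
separation within the window) are excluded from means and tallied, since no
convention for them is defined by the assay — survival-style handling is out
of scope. Metaphase duration is the inflection breakpoint of cells
classified normal with a clear inflection; it is undefined (and the cell
excluded) otherwise. Dispersion: SD with the n−1 denominator,
SEM = SD/√n. Two-sample comparisons use Welch's t-test by default — the
pooled-variance Student variant is available, since which one the legend
convention refers to is ambiguous — and no multiple-testing correction is
applied; raw p-values are reported together with the number of comparisons.
The floored-normal mean E[max(0, X)] = μΦ(μ/σ) + σφ(μ/σ) is provided in
closed form as an independent check of the Monte-Carlo oracle used in
calibration tests.

## Determinism and problem sizes

All randomness flows from `numpy.random.Generator`; populations spawn
per-cell generators from a `SeedSequence`, so a master seed reproduces every
table byte-identically (under test). The calibration suite and
`scripts/acceptance.py` use 10,000 trajectories for the rule-scan agreement,
3 × 200 cells per recovery condition, 200 rendered 17-slice stacks for
length accuracy, 50 cells per barrel level, 100 replicate populations of 200
cells for timing coverage, and 2,000 null simulations for t-test
calibration — sizes at which every binomial check has comfortable power
while a full run stays within a few tens of seconds on one CPU.

## Known limitations

* One cell per stack; no segmentation, drift correction or deconvolution.
* The kinetic generator is piecewise-linear; real traces show curvature at
  anaphase onset that the hinge model absorbs into the breakpoint estimate
  (≈ ±1 frame).
* The barrel is a hard cylinder; the real pericentric Cohesin distribution
  is bi-lobed and partial, so absolute enrichment in real data will sit
  below the geometric ideal.
* The 2×SEM timing-coverage check is itself a ~95%-coverage statistic: a
  single honest replicate set can land at 92–94/100 without indicating a
  defect.
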