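# Methods

## The measurement problem

Interproximal caries lesions sit at the contact between adjacent posterior
teeth, where radiography misses early mineral loss and underestimates depth.
The optical alternatives analyzed here exploit enamel's SWIR transparency:
in reflectance frames lesions scatter strongly and appear bright; in
transillumination frames they attenuate the transmitted light and appear
dark; in CP-OCT b-scans they appear as a zone of elevated backscatter below
the surface echo. The package implements the quantitative chain from raw
frame to per-surface detection call, lesion contrast and lesion depth, and
the study-level statistics comparing methods over a paired design (each
contact contributes a restored and an opposing surface, both treated as
lesion-positive sites).

## SWIR segmentation

Contrast is computed per pixel against the mean intensity `i_s` of a
manually chosen sound-enamel ROI adjacent to the contact:
`(I_t − i_s)/I_t` for reflectance, `(i_s − I_t)/i_s` for both
transillumination geometries. The reflectance form is bounded above by 1
and diverges for `I_t → 0`; zero-intensity pixels are flagged invalid and
excluded from masks. The detection threshold is 0.1 and the boundary is
kept (only contrast *strictly below* 0.1 is removed). Components of the
thresholded mask are labeled 8-connected, and a component belongs to the
lesion iff any of its pixels is 8-adjacent to the contact ROI; all
adjoining components are merged (one lesion per surface), everything else
is discarded as artifact. `i_s` uses the arithmetic mean (median available
via `contrast_map_with`); connectivity is configurable.

**Lesion depth in 2-D.** No standard definition exists for "depth" on a
projection image. We use the extent of the segmented component along the
direction perpendicular to the contact line (max − min projection + 1 px,
converted by the pixel pitch), with the contact direction taken as the
principal axis of the contact ROI pixels. This measures penetration away
from the proximal surface and is applied identically across SWIR
modalities, so cross-method depth comparisons are well defined. It is a
stated convention of this package, not a published procedure.

## CP-OCT depth

B-scans are stored with rows as axial *optical* distance. Processing:
kernel-3 median despeckling (edge pixels use clipped neighborhoods), enamel
surface detected per column as the first rise above 50% of the column
maximum, surface line least-squares fit over a ±10-px lateral window, and a
ruler marched from the surface along the inward normal in 10-µm steps. At
each step the profile value is the mean of bilinearly interpolated
intensities over a transverse segment 100 µm wide (the in-plane section of
the 100-µm disk). After a 3-sample moving average, local minima are
collected (plateaus resolved at their midpoint) and the two with the lowest
intensities are taken to flank the lesion. Depth is their separation along
the ruler divided by the refractive index (default 1.6); a 7-mm in-air scan
range therefore reaches only 4.4 mm of enamel, and `max_physical_range`
reports this bound (half-up rounding to one decimal).

Two interpretive choices matter. First, "distance between the two lowest
minima" is a length; an intensity difference has no depth units, so the
minima are located on the distance axis. Second, the guard against
birefringence banding — the profile must rise between the two minima by at
least 10% of the profile's *dynamic range* above both of them — is relative
rather than absolute, which makes the measurement exactly invariant under
global intensity rescaling of the scan. Sound enamel's band maxima decay
with depth and fail this guard; a lesion's reflectivity peak passes it.

## Phantoms

The generator produces the statistical structure the pipelines assume, not
a light-transport simulation.

* SWIR frames are uniform at `sound_intensity` with a half-ellipse lesion
  clipped at the (vertical) contact line, so the contact-adjacency rule is
  exercised by construction. Lesion pixels are placed at `I_s/(1 − c)`
  (reflectance) or `I_s·(1 − c)` (transillumination) so the contrast
  transform returns the target `c` exactly at zero noise. Reflectance
  frames get specular spots and transillumination frames saturated bleed
  margins, both ≥ 10 px from the contact so ground truth is unambiguous.
  Additive Gaussian noise (default σ = 0.005, see below) is clipped to
  [0, 1]; frames are written as 16-bit TIFF to preserve contrast resolution
  at the 0.1 threshold.
* OCT b-scans have a bright surface echo, exponential decay with optical
  depth (default 0.8 mm⁻¹) modulated by sinusoidal birefringence banding
  (period 0.35 mm, amplitude 0.18), and, in lesion columns, a
  piecewise-linear A-line whose two flanking minima sit at a separation of
  `true_depth · n` optical pixels. The minima get 3-px flat bottoms — the
  dark zones flanking a real lesion have finite thickness, and a
  single-pixel minimum would not survive the kernel-3 median filter. The
  banding is tapered inside the lesion span (demineralization depolarizes
  and washes out the bands), keeping the ground-truth minima unambiguous.
  Speckle is multiplicative Gaussian noise; the study pipeline uses
  σ = 0.10 as its "moderate speckle" condition. Requested depths are
  realized on the axial pixel grid (≤ half-pixel quantization) and the
  realized value is stored in the ground truth.

**Noise defaults.** No intensity histograms of clinical frames are
available, so the SWIR noise σ was fixed once at 0.005 such that the 0.1
threshold behaves as a sharp classifier on phantoms: segmentation succeeds
deterministically at c = 0.2 (sound pixels sit ~11σ below threshold) and
fails at c = 0.05 (lesion pixels ~6σ below threshold). This is a chosen
operating point, not a derived one; real SWIR video frames are noisier, and
passing tests at this σ demonstrate correctness of the chain, not clinical
detectability limits.

## Statistics

Detection rates are k/n per method and surface group with missing calls
excluded from both counts, rounded half-up to two decimals for report
parity. Rate comparisons use the two-sided Fisher exact test (sum of
hypergeometric probabilities ≤ that of the observed table; delegated to
scipy, with an exhaustive enumeration oracle in the tests). Contrast and
depth are compared by one-way repeated-measures ANOVA computed from the
sum-of-squares decomposition after complete-case removal (subjects =
contact-surface pairs), with Tukey pairwise comparisons on the
repeated-measures error term — `q = |Δmean|/√(MS_err/n)` against the
studentized range with (n−1)(k−1) df, matching the common
repeated-measures multiple-comparison default; Bonferroni-adjusted paired t
is available by flag since no specific correction is prescribed for this
design. The compact letter display uses insert-and-absorb clique cover:
methods share a letter iff no pair within the letter's group is
significant. A random-intercept mixed model (statsmodels MixedLM, Wald
pairwise tests) serves as an independent cross-check that tolerates missing
values.

## The synthetic study (`run_all`)

29 contacts × 2 surfaces are generated, with per-method, per-surface lesion
visibility drawn from the study's condition rates; visible SWIR lesions
receive a contrast from that method's (mean, SD) distribution and a size
from its depth distribution and are processed by the real segmentation
pipeline (invisible lesions yield zero-contrast frames, so negatives arise
from the pipeline, not by fiat); visible OCT lesions are measured by the
real ruler pipeline on speckled b-scans; radiograph and visual calls are
examiner-style labels, with radiographic contrast measured by the
radiograph module on a generated frame. The restored-surface radiograph
visibility is set to 0.86, the value consistent with the all-surface and
opposing-surface rates of the emulated study (whose printed restored entry
is internally ambiguous). The report bundle (detection table CSV, rates
CSV, lesion-overlay PNGs, JSON summary) is byte-identical across reruns
with the same config and seed.

## Problem sizes and numerical notes

The default study uses 29 contacts; phantom frames are 192 × 256 px at
0.03 mm/px and b-scans 192 rows over 7 mm optical (36.5 µm axial pitch,
i.e. 22.8 µm of enamel per pixel at n = 1.6). Depth-recovery suites use 100
lesion and 100 lesion-free scans; the letter-pattern simulation uses 500
replicate studies of n = 26 complete cases. Studentized-range critical
values are cached per (α, k, df); the replicate simulation compares q
statistics against the cached critical value instead of computing 500 × 6
tail probabilities. Ties in plateau minima are broken at the plateau
midpoint; zero residual variance in the ANOVA yields p = 1 for identical
means and separation otherwise.

## Known limitations

* Phantoms are geometric, not physical: no beam hardening, no partial-volume
  blur at lesion boundaries, no correlated speckle, uniform sound enamel.
  Passing closure tests shows the transforms and selection logic are
  correct, not that the 0.1 threshold is optimal on clinical frames.
* The 2-D SWIR depth convention and the OCT ruler start point (detected
  surface) are package conventions where the published procedures are
  underspecified.
* Whether published OCT depths are optical or index-corrected is not
  stated; this package corrects by n = 1.6 and exposes the index as a
  parameter.
* The letter-pattern simulation with a common within-subject SD of 0.03
  places the SWIR-R/SWIR-OT mean gap (0.02) at the significance boundary,
  so the published a/b/b/c grouping is recovered in only ~57% of
  replicates; the published per-method SDs for SWIR-OT/PT (0.010/0.013)
  are far smaller than a common 0.03, and under heteroscedasticity that
  mild the grouping would be stable.
* Radiographic lesion detection has no contrast threshold (by design);
  radiographic calls are examiner labels, and in the synthetic study they
  are Bernoulli draws at the condition rates.
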