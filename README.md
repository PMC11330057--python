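# swirseg

Image analysis for the detection of interproximal (between-teeth) caries
lesions with short-wavelength infrared (SWIR) imaging and cross-polarization
optical coherence tomography (CP-OCT), for researchers comparing optical
caries diagnostics against radiography.

Dental enamel is highly transparent between 1000 and 2300 nm, so early
lesions — which scatter SWIR light strongly — can be imaged without ionizing
radiation: bright against sound enamel in reflectance (SWIR-R), dark in
occlusal and proximal transillumination (SWIR-OT, SWIR-PT). This package
implements the semi-automatic analysis chain used in clinical studies of
these modalities:

* **Contrast-map segmentation (SWIR).** A frame is transformed to per-pixel
  contrast against a manually selected sound-enamel reference *I*<sub>s</sub>:
  (*I*<sub>t</sub> − *I*<sub>s</sub>)/*I*<sub>t</sub> for reflectance and
  (*I*<sub>s</sub> − *I*<sub>t</sub>)/*I*<sub>s</sub> for transillumination.
  Pixels with contrast below 0.1 are removed; mask components adjoining the
  proximal contact are the lesion (components away from the contact —
  specular highlights, direct-light bleed — are discarded). A non-empty
  lesion is a positive detection, and lesion area, mean contrast and depth
  are computed from it.
* **Cylindrical-ruler depth (CP-OCT).** A b-scan is despeckled with a 3×3
  median filter; a ruler is dropped perpendicular to the detected enamel
  surface; the intensity along it is averaged inside a 100-µm disk; lesion
  depth is the axial distance between the two lowest local minima of that
  profile (the dark zones flanking the lesion's elevated reflectivity),
  divided by the enamel refractive index *n* = 1.6 to convert optical to
  physical distance. A prominence guard rejects birefringence-band maxima.
* **Radiographic contrast.** (*I*<sub>S</sub> − *I*<sub>L</sub>)/*I*<sub>S</sub>
  from examiner-drawn lesion and sound ROIs in the same column band, with
  the millimetre scale transferred from calibrated SWIR frames via matched
  mesial–distal spans.
* **Detection statistics.** Per-method detection rates over contacts × 2
  surfaces, Fisher's exact test against radiography, one-way
  repeated-measures ANOVA (complete-case) with Tukey pairwise comparisons on
  the repeated-measures error term, and a compact letter display (methods
  sharing a letter are statistically similar at α = 0.05).
* **Phantom generator.** Synthetic SWIR frames and CP-OCT b-scans with known
  ground truth (lesion mask, true contrast, true depth), since clinical
  frames are not publicly deposited. Phantoms are built so the contrast
  transforms recover the target contrast exactly in the noise-free limit and
  the OCT flanking minima sit at a known separation.

## Worked example

Segment a transillumination phantom with a target lesion contrast of 0.27:

```python
from swirseg import PhantomConfig, make_swir_phantom, segment_lesion
from swirseg.pipeline import default_swir_rois

cfg = PhantomConfig(modality="occlusal_trans", lesion_contrast_true=0.27,
                    sound_intensity=0.8, seed=7)
frame, truth = make_swir_phantom(cfg)
cm, seg = segment_lesion(frame, default_swir_rois(cfg))
print(f"detected={seg.detected} area_px={seg.area_px} "
      f"mean_contrast={seg.mean_contrast:.3f} depth_mm={seg.depth_mm:.2f}")
```

```
detected=True area_px=1609 mean_contrast=0.270 depth_mm=1.11
```

The segmentation recovers the generated lesion exactly: 1609 px matches the
ground-truth area, the mean contrast equals the 0.27 target (the default
noise level perturbs it below the printed precision), and the 1.11 mm depth
is the half-ellipse's extent perpendicular to the contact line.

Run a full synthetic study (29 contacts × 2 surfaces = 58 lesion surfaces)
and compare the methods:

```python
from swirseg.pipeline import PipelineConfig, run_all

report = run_all(PipelineConfig(), out_dir="study/")
print(report.rates[report.rates.group == "opposing"].to_string(index=False))
print(report.contrast_anova.letters)
```

```
       method  n  k_detected  rate
   radiograph 29           8  0.28
          oct 29          22  0.76
visual_before 29           0  0.00
 visual_after 29          24  0.83
       swir_r 29          26  0.90
      swir_ot 29          24  0.83
      swir_pt 29          25  0.86
{'radiograph': 'a', 'swir_r': 'b', 'swir_ot': 'c', 'swir_pt': 'b'}
```

Every SWIR method detects far more of the opposing-surface lesions than
radiography (Fisher's exact p < 0.01 for each), and the letter display
separates radiographic lesion contrast (letter a) from the SWIR methods —
the structure such a study is designed to show. `study/` receives the
detection table, rates, per-frame lesion overlays and a JSON summary.

The same operations are available from the shell:

```sh
swirseg simulate --modality reflectance --out frames/ --seed 7
swirseg segment --image frames/phantom.tif --roi roi.json \
        --modality reflectance --threshold 0.1 --mm-per-px 0.03
swirseg oct-depth --bscan scan.tif --header scan.json
swirseg stats --table calls.csv --alpha 0.05
swirseg run-all --out study/ --seed 7
```

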