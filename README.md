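# octmargin

Residual-tumor detection at the brain resection margin from intraoperative
optical coherence tomography (OCT), as a tested, reusable analysis
pipeline. The package is aimed at researchers working on OCT-based tissue
differentiation during neurosurgery who need the full chain — from raw
volume to diagnostic metrics — runnable, inspectable and testable without
access to clinical scan data.

## What it does

Tumor infiltration degrades the myelin that makes healthy white matter a
strong scatterer. The package quantifies this through the single-scattering
model of the depth-resolved OCT signal,

```
A²(z) = I · exp(−2 µ z)
```

where µ (mm⁻¹) is the attenuation coefficient, I the peak backscattered
intensity and z the depth from the tissue surface. Fitting a least-squares
line to the logarithmized, laterally averaged A-scan of each image patch
yields µ = −slope/2 and I = exp(intercept); the fit's r² serves as a
homogeneity measure. Healthy white matter shows high µ, high I and high r²;
infiltration lowers all three.

Around this core the package provides:

* **`octmargin.simulate`** — a physics-based synthetic cohort generator
  (exponential decay per tissue class, speckle, roll-off/focus sensitivity,
  surface topography, heterogeneity, shadowing microstructures, fold-over
  and dropout artifacts), fully reproducible from one seed;
* **`octmargin.preprocess`** — depth compensation, surface detection and
  flattening, en-face projection, subvolume/patch extraction, scan QC;
* **`octmargin.optics`** — the (µ, I, r²) fit with the 300 µm window
  starting 20 µm after the A-scan maximum, plus group statistics
  (Shapiro–Wilk, pairwise rank tests with significance stars);
* **`octmargin.visual`** — the five-criterion qualitative grading
  (intensity, homogeneity, penetration > 500 µm, uniformity,
  microstructures) and the flowchart classifier mapping them to five
  classes from *white matter* to *tumorous*, with Cohen's-kappa observer
  agreement;
* **`octmargin.evaluate`** — task definitions (I: healthy vs pathological
  over all six histology labels; II: white matter vs infiltrated white
  matter; III: extreme grades only), leave-one-patient-out linear SVM
  (cost 0.1) on the optical properties, exact diagnostic-metric
  arithmetic, and the clinical comparator worked examples
  (fluorescence-guided assessment, early post-operative MRI);
* **`octmargin.neural`** — the patch-classifier training protocols
  (leave-one-patient-out; autoencoder features + classifier on a 30%
  held-out split) over configurable small networks.

## Worked example

Simulate speckled patches of three tissue classes, run them through the
preprocessing chain and fit the optical properties:

```python
import numpy as np
from octmargin.params import TissueLabel, default_system, default_tissue_params
from octmargin.pipeline import simulate_normalized_patches
from octmargin.optics import fit_patch_table

system = default_system()
params = default_tissue_params()
for label in (TissueLabel.WM0, TissueLabel.GM0, TissueLabel.WM60plus):
    rng = np.random.default_rng(42)
    patches = simulate_normalized_patches(params[label], system, 50, rng)
    t = fit_patch_table(patches)
    print(f"{label.value:6s}  mu={t.mu.median():.2f} mm^-1  "
          f"I={t.intensity_db.median():.1f} dB  r2={t.r2.median():.3f}")
```

prints

```
WM0     mu=6.00 mm^-1  I=67.0 dB  r2=0.994
GM0     mu=2.60 mm^-1  I=53.0 dB  r2=0.965
WM>60   mu=1.73 mm^-1  I=50.1 dB  r2=0.755
```

Healthy white matter (WM0) is recovered at its true attenuation with a
near-perfect exponential fit; gray matter (GM0) comes out ~56% lower in µ —
the contrast that makes gray matter hard to tell from tumor — and heavily
infiltrated white matter (WM>60) shows the lowest attenuation, intensity
and homogeneity. The same objects drive the rule-based visual classifier
(`octmargin.visual.grade_criteria` → `classify_visual`) and the
leave-one-patient-out SVM evaluation (`octmargin.evaluate.loo_svm_evaluate`).

A command-line interface covers the same steps on directories of
TIFF+JSON volumes:

```
octmargin simulate --config cohort.yaml --out data/ --seed 1
octmargin preprocess --in data/volumes --out work/
octmargin fit --in work/normalized --labels data/scans.csv --out props.csv
octmargin evaluate --properties props.csv --task II --out report.json
octmargin worked-examples
```

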