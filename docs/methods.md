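# Methods

## Scope and model

`octmargin` implements the analysis chain used to decide, from an
intraoperative OCT scan of a brain resection margin, whether the imaged
tissue is healthy white matter, gray matter, edema, or white matter with
some grade of tumor infiltration. The core physical model is single
backscattering with exponential depth decay: below the tissue surface the
detected intensity is

    A²(z) = I · exp(−2 µ z),

with µ the attenuation coefficient (mm⁻¹), I the peak backscattered
intensity, and z the depth from the surface in mm. Myelinated white matter
scatters strongly (high µ, high I); tumor infiltration degrades myelin and
lowers both. Taking the natural log makes the model exactly linear in z, so
µ and I come from an ordinary least-squares line fit (µ = −slope/2,
I = exp(intercept)), and the fit's coefficient of determination r² doubles
as a homogeneity measure: tissue whose depth profile deviates from a clean
exponential (cysts, vessels, heterogeneous infiltration) fits worse.

The in vivo volumes behind this kind of study are not public, so the
package ships a first-class synthetic generator that reproduces the
statistical structure the analysis assumes, and every downstream stage is
developed and tested against it.

## Synthetic data generator

A scan is a subvolume of B-scans (default 40) of `lateral × depth` pixels
(default 160 × 256 at 15 µm and 6 µm per pixel). Each tissue class has
generative parameters (`TissueParams`): µ, peak intensity in dB,
heterogeneity, surface roughness, microstructure shadow rate, and a
specular surface-reflection boost. The signal chain per A-scan is

1. exponential decay below a per-column surface index (lateral-correlated
   Gaussian topography with the class's roughness);
2. a +4 dB specular peak over the first 12 µm below the surface — the
   index-mismatch reflection at the tissue interface. This anchors the
   profile maximum at the surface and is the physical reason the fit window
   starts 20 µm *after* the maximum;
3. a multiplicative heterogeneity field: spatially smooth log-normal noise
   (correlation lengths 12 lateral × 6 axial pixels, standard deviation =
   the class's `heterogeneity`), plus a correlated per-column jitter of µ
   (±0.5·h relative). This one knob produces the three signatures of
   infiltrated tissue at once: en-face intensity variation, non-uniform
   penetration depth, and reduced fit r²;
4. Poisson-placed microstructure shadows (count ~ `microstructure_rate`
   per B-scan): 1–3 adjacent columns attenuated ×0.05 below an onset 60–150
   µm under the surface, emulating occluding vessels/calcifications;
5. multiplicative unit-mean exponential speckle (fully developed speckle,
   the standard statistical model for coherent imaging);
6. system sensitivity: roll-off (default 6 dB exponential loss over the
   depth range) × focus function (Gaussian, waist at one-third depth,
   floor 0.7) — both strictly positive per-pixel profiles, configurable;
7. an additive detector noise floor (default 28 dB) with its own speckle.

Volumes are stored in dB (dB = 10·log₁₀ linear). Two artifact types can be
injected at cohort level: **fold-over** (below-surface signal mirrored into
the empty rows above the surface, as zero-delay wrap-around produces) and
**dropout** (a contiguous half of the lateral columns replaced by noise
floor).

### Default class parameters

Absolute attenuation at 830 nm is system-dependent, so healthy white matter
is fixed at µ = 6.0 mm⁻¹ (configurable) and the other classes follow the
relative differences reported for this contrast: gray matter 56% lower
(ratio 0.44), edematous white matter ~40% lower (ratio 0.60), and a
monotone decrease with infiltration grade, all infiltrated classes below
edema (0.50 / 0.43 / 0.33 of the white-matter value). Peak intensities span
the 40–70 dB display range (white matter 67 dB "deep red"; all other
classes 50–54 dB), heterogeneity rises with infiltration grade
(0.05 for white matter, 0.10 for gray matter/edema, 0.35–0.50 for the
infiltration grades), and only infiltrated classes carry microstructure
shadows (2–4 per B-scan). Intensities and attenuations were chosen jointly
so the qualitative archetypes hold: white matter is bright; edema is dim,
shallow (< 500 µm to the 40 dB visibility floor) and uniform; gray matter
is dim but deep and homogeneous; infiltrated tissue is dim, deep,
heterogeneous, non-uniform and shadowed.

### Cohort structure

The default cohort mirrors the study design: 21 patients × 5 scans
(an optional extra tumor-surface scan per patient is off by default),
six-class label mix (WM0 25%, WM>60 20%, GM0/WM0–30/WME 15%, WM30–60 10%),
and 60% of scans carrying an injected artifact, matching the reported scan
attrition. All randomness flows through per-scan child seeds of the cohort
seed, so any scan regenerates bit-identically on demand and the whole
dataset is reproducible from one integer.

### What the generator does *not* emulate

Real beam geometry (refraction, angle-dependent coupling), multiple
scattering and the resulting depth-dependent deviation from single-
exponential decay, blood/CSF pooling, arachnoid-layer mis-detection on
cortex, motion during the scan, and graded (rather than binary-injected)
artifact severity. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under the stated model, not classifier
performance on clinical data.

## Preprocessing

* **Depth compensation** divides roll-off × focus out of the linear
  intensity; it is the exact inverse of the acquisition weighting
  (round-trip < 1e-9 relative on noiseless data) and idempotent for flat
  profiles.
* **Surface detection** takes the first depth index whose 5-column
  lateral-median-smoothed dB exceeds noise floor + 10 dB; columns that
  never cross are "missing". The floor is taken from configuration, or
  estimated from the top rows of a raw volume.
* **Surface normalization** shifts each A-scan so its surface sits at
  row 0, pads vacated deep rows with the floor, flags missing columns
  invalid, and fails QC when fewer than half the columns have a surface.
* **Patch extraction** tiles surface-normalized B-scans (every 2nd B-scan
  by default) into 144 lateral × 56 axial patches and keeps those that
  overlap no invalid column and have ≥ 80% of pixels 3 dB above the floor.
  On the default cohort this yields on the order of 900 valid patches —
  the scale at which the per-patch statistics are meant to operate.
* **Scan QC** flags fold-over (> 20% of columns with signal 12 dB above
  floor in the top 5 rows, i.e. above the tissue surface) and dropout
  (> 30% of columns with no detectable surface).

Pixel pitch: 6 µm/pixel axially. This is the value jointly consistent with
a 56-pixel patch height and a fit window of 20 µm offset + 300 µm length
(20 + 300 = 320 µm ≤ 56 × 6 = 336 µm); at 4 µm the window could never fit
inside a patch. Depth is converted to physical units through a refractive-
index configuration scalar (default 1.0, i.e. optical path in air).

## Optical-property fitting

Patches are averaged laterally in **linear** units (the linear mean of
unit-mean speckle is unbiased; averaging logs would bias the intercept by
the Euler–Mascheroni constant) and then log-transformed. The fit window
starts ⌈20 µm / pitch⌉ samples after the profile maximum (ties break to the
shallowest sample) and spans ⌊300 µm / pitch⌋ samples, half-open. OLS gives
(µ, I, r²); a window with zero intensity variance returns µ = 0 and an
undefined-r² flag. Profiles whose maximum sits too deep for the window are
skipped and counted (about 0–3% of heterogeneous-class patches). The
additive noise floor is kept ~20 dB below the weakest class's window-end
signal so floor contamination biases µ by ≲ 3%; combined with the Jensen
effect of the per-column µ jitter, the worst-case median bias on the
default classes stays under 5%.

Group statistics are Shapiro–Wilk normality per class and pairwise
rank-based location tests with star coding (*, **, *** at strict
p < 0.05 / 0.01 / 0.001). The tissue groups are unpaired, so the rank-sum
(Mann–Whitney) variant of the Wilcoxon test is used.

## Visual grading and flowchart

The five criteria are: (1) signal intensity high/low, (2) homogeneity,
(3) penetration depth > 500 µm, (4) uniformity of penetration,
(5) microstructure shadows. The flowchart is total on the 32-point domain:
high intensity ⇒ *white matter* (16 combinations); among the 16
low-intensity ones, homogeneous+shallow+uniform+shadow-free ⇒ *rather not
tumorous* (1), homogeneous+deep+uniform+shadow-free ⇒ *rather tumorous /
gray matter* (1), heterogeneous+deep+non-uniform+shadowed ⇒ *tumorous* (1),
and every other combination ⇒ *rather tumorous* (13).

The automated grading surrogate exists to make the flowchart testable end
to end; it is not a model of human perception. Its thresholds are plain
configuration: intensity at 55 dB (midpoint of the 70/40 dB display
anchors), measured as the median per-column linear-mean over 18–66 µm below
the surface (below the specular peak); penetration against the 40 dB
*visibility* floor (the display anchor for "signal fades out"), not the
detector noise floor, on a laterally (9 px) and axially (5 px) smoothed
linear volume; homogeneity as the coefficient of variation of the 5×5-
smoothed linear en-face image over the first 300 µm, threshold 0.10 (the
smoothing that suppresses speckle also attenuates real heterogeneity, so
the homogeneous classes measure ≈ 0.05 and the heterogeneous ones ≈ 0.15;
0.10 is the separating midpoint); uniformity as the lateral standard
deviation of per-column penetration depth, threshold 100 µm; and
microstructures as any column whose 100–450 µm band mean falls 5 dB below
the local (25-column) lateral median.

The binary collapse maps *white matter* and *rather not tumorous* to
non-tumor and the rest to tumor; whether *rather tumorous / gray matter*
counts as tumor is configurable (default yes, following the class name).
Observer agreement uses Cohen's kappa computed from the 5×5 cross-table
(undefined when chance agreement is exactly 1), cross-checked in the tests
against scikit-learn's implementation.

## Tasks and evaluation

Task I uses all six labels (positives: the three infiltration grades and,
configurably, edema); Task II restricts to white matter vs infiltrated
white matter; Task III to healthy white matter vs > 60% infiltration. The
classifier on (µ, I in dB, r²) is a linear-kernel SVM with regularization
cost 0.1, evaluated leave-one-patient-out: features are z-scored on
training-fold statistics (recorded in the report), one fold per patient,
folds with single-class training data are skipped with a warning, and the
aggregate is the mean per-fold sensitivity and specificity with balanced
accuracy their arithmetic mean — mean-of-folds, not pooled confusion.
Diagnostic metrics are computed in exact rational arithmetic and reported
as floats plus integers rounded half-away-from-zero. On the default
synthetic cohort the white-matter-only tasks are near-perfectly separable
by construction, while Task I is degraded by gray matter and edema sharing
the infiltrated classes' optical signature — the qualitative ordering
(Task II > Task I) is the tested property; absolute synthetic accuracies
are not claims about clinical data.

Patient-level contingency arithmetic (`contingency_from_outcomes`,
`compute_metrics`) reproduces the comparator worked examples bundled with
the package: fluorescence-guided assessment (tp=5, fp=0, tn=9, fn=7 →
sensitivity 42%, accuracy 67%) and early post-operative MRI (tp=9, fp=0,
tn=9, fn=3 → sensitivity 75%), plus balanced accuracies from printed
sensitivity/specificity pairs (observers 82/87%; SVM task II 85%; network
approaches 66–87%). "Residual" at patient level means at least one scan
with an infiltrated label.

## Neural protocols

The two patch-classification protocols are implemented at desk scale over
scikit-learn multilayer perceptrons, with the *protocol* fixed (per-patch
z-scoring, batch size 32, configured epoch count, leave-one-patient-out
for the direct classifier, a random stratified 30% held-out split for the
autoencoder route) and the *architecture* as data-driven configuration: a
hidden-layer list for the classifier and an odd-length mirror-symmetric
layer list for the autoencoder, whose middle entry is the bottleneck.
Bottleneck features are obtained by forward-propagating through the
encoder half (ReLU hidden layers) and feed a fully connected classifier.
Defaults are deliberately small (32–64 unit layers, bottleneck 8); tests
run 40 epochs, while 100 remains the protocol-faithful default. Note that
per-patch z-scoring makes any *pure* exponential decay (a straight ramp in
dB) identical after normalization regardless of rate — class differences
the networks can learn must be nonlinear in depth, which the test fixtures
provide via a layered-structure band.

## Numerical conventions and problem sizes

0-based indices, half-open ranges, depth increasing away from the
objective; dB = 10·log₁₀(linear) throughout; volumes stored as 32-bit
float TIFF pages with a JSON sidecar; tables as CSV written at 17
significant digits and read back with round-trip float parsing. The test
suite and the acceptance script run the full 21-patient cohort
(105 volumes of 40 × 160 × 256) end to end in about a minute on one CPU,
and the parameter-recovery study at 200 patches per class; these sizes
were chosen to exercise the cohort-scale code paths while keeping the
default run interactive.

## Known limitations

* The synthetic cohort is far cleaner than surgical data: QC-passing scans
  always grade into their class archetype, and the optical-property tasks
  are more separable than in vivo measurements would be.
* The grading surrogate's thresholds are calibrated to the generator's
  defaults; on real volumes they are starting points, not validated
  settings.
* Only single-scattering, depth-constant attenuation is fitted; no
  per-pixel attenuation maps, multi-layer or multiple-scattering models.
* The compensation entry point accepts arbitrary positive sensitivity
  profiles but the package provides only parametric defaults; a
  calibration-based profile must be supplied by the user.
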