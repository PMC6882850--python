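# histospec

Quantitative histopathology feature mining and hyperspectral association
analysis for tongue neoplasia.

Wide-field hyperspectral imaging (HSI) records a diffuse-reflectance
spectrum (here 450-900 nm in 5 nm steps, 91 bands) at every pixel of a
tissue surface, and neoplastic tongue tissue reflects differently from
healthy tissue — but *why* it does is a question about microscopic
architecture. `histospec` is a pipeline for asking that question
quantitatively: it mines H&E histology for the architectural changes of
neoplastic progression and correlates them with the spectral signatures of
the same tissue. It is written for researchers in biomedical optics and
computational pathology who want a tested, reusable implementation of each
stage — and a synthetic-data generator that makes the whole pipeline
reproducible without access to any cohort.

## What it computes

1. **Segmentation** — epithelium from the smoothed, Otsu-thresholded red
   channel; nuclei/cytoplasm/background by k-means color clustering with
   role assignment by color semantics; touching nuclei separated by
   repeated k-means splitting (area > 500 px, solidity < 0.9) and
   marker-controlled watershed on the blue-ratio image
   (B/(1+R+G))/(1+R+G+B) (area > 150 px); false detections removed at
   red/blue > 1.2 and > 1.0; survival thresholds 50/25/50 px per stage.
2. **Feature bank** — 712 named features per crop: for each of epithelium,
   cytoplasm and nuclei, 71 color (transformed-RGB and red-blue-difference
   histograms) and 149 texture features (19 GLCM/Haralick from 16 averaged
   co-occurrence matrices, 56 from a 28-filter Gabor bank, 10
   rotation-invariant LBP, 64 from a modified segmentation-based fractal
   texture analysis), plus 44 nuclear morphometry and 8 Delaunay-topology
   features.
3. **Selection and modeling** — minimal-redundancy-maximal-relevance
   (mRMR) ranking, max_S [ sum I(f, c) − (1/|S|) sum I(f_i, f_j) ], and an
   RBF-SVM classifier (normal vs. neoplastic) evaluated by nested
   leave-one-subject-out cross-validation with per-fold selection, grid
   search over (m, c, gamma), and a leakage guarantee.
4. **HSI** — reflectance calibration
   I_ref = (I_raw − I_dark)/(I_white − I_dark), straight-line pathology
   maps, per-class spectral signatures.
5. **Association** — Spearman's rho between selected features and
   signatures per wavelength, two-sided p at alpha = 0.05, green/red/white
   heatmap, row summaries with a |mean rho| >= 0.5 strength flag.

The synthetic generator renders H&E-style crops (blue-purple perturbed
elliptical nuclei on pink cytoplasm in an epithelial band) and matched
hypercubes (class-dependent amplitude, hemoglobin-style 540 nm dip, white
and dark reference cubes) with full ground truth; grade-dependent defaults
make normal → carcinoma increasingly dense, large, irregular and crowded.

## Worked example

```python
from histospec.synthetic import tissue_spec_for_class, generate_he_image
from histospec.segmentation import segment_tissue
from histospec.features import assemble_features

rgb, truth = generate_he_image(tissue_spec_for_class("dysplasia", seed=1))
masks, nuclei = segment_tissue(rgb)
fv = assemble_features(rgb, masks)
print(f"true nuclei: {truth.n_nuclei}, detected: {len(nuclei)}")
print(f"features: {len(fv)}")
print(fv.to_series()[["nuclei.morph.area.mean",
                      "nuclei.topo.perimeter.mean",
                      "epithelium.msfta.b0.edge.fractal_dimension"]])
```

prints

```
true nuclei: 50, detected: 44
features: 712
nuclei.morph.area.mean                        201.795455
nuclei.topo.perimeter.mean                     89.021239
epithelium.msfta.b0.edge.fractal_dimension      1.246953
```

— 44 of 50 nuclei recovered on this crowded dysplastic crop (non-overlapping
configurations recover within 10%), a mean detected nucleus area of ~202 px,
a mean Delaunay-triangle perimeter of ~89 px (this falls as nuclei crowd
with grade), and an epithelial edge fractal dimension of ~1.25 (this rises
with grade). Or run everything end to end:

```bash
histospec run --out runs/demo --seed 1
```

which writes the manifest, feature matrix, mRMR ranking, CV report,
spectral signatures, association matrices and heatmap, and a summary JSON.

## Layout

```
src/histospec/
  synthetic.py     paired H&E crops + hypercubes with ground truth
  hsi.py           calibration, pathology maps, spectral signatures
  segmentation.py  epithelium / nuclei / cytoplasm pipeline
  features/        color, texture (GLCM/Gabor/LBP), mSFTA, morphometry
  selection.py     mutual information + mRMR ranking
  modeling.py      nested leave-one-subject-out CV, SVM-RBF
  association.py   Spearman matrices, heatmap summaries
  pipeline.py      end-to-end orchestration
  cli.py           `histospec` command-line interface
docs/methods.md    model, parameters, design choices, limitations
```
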