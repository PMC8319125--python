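# omiflim

Optical metabolic imaging (OMI) analysis for label-free prediction of
cardiomyocyte differentiation efficiency from fluorescence-lifetime
(FLIM) data — with a synthetic FLIM generator so the full pipeline runs
and is tested without a microscope.

## The problem

Human pluripotent stem cells are differentiated into cardiomyocytes for
regenerative therapy and drug screening, but differentiation efficiency
(the fraction of cTnT+ cells measured by flow cytometry on day 12)
varies strongly between batches, lines, and protocol parameters.
Autofluorescence imaging of the metabolic co-enzymes NAD(P)H and FAD
reads out cell metabolism label-free, and the metabolic state of cells
one day after Wnt activation already separates conditions that will end
up low (< 50 % cTnT+) from those that will end up high (≥ 50 %).

`omiflim` implements that analysis chain for people working with TCSPC
FLIM data of cultured cells:

1. **Decay fitting** (`omiflim.decay`) — per-pixel two-component fits of
   photon-count histograms,

       I(t) = A · (IRF ⊛ [α₁e^(−t/τ₁) + α₂e^(−t/τ₂)]) + C,  α₁ + α₂ = 1,

   by Poisson maximum likelihood with circular IRF convolution over the
   laser period (incomplete-decay correction), sliding-window spatial
   binning (3×3, 5×5), and honest validity/convergence flags. The mean
   lifetime is τ_m = α₁τ₁ + α₂τ₂ (picoseconds everywhere).
2. **Phasor analysis** (`omiflim.phasor`) — normalized Fourier (G, S)
   coordinates per decay or per pixel, IRF calibration by complex
   division; mono-exponentials land on the universal semicircle.
3. **Single-cell features** (`omiflim.cells`) — cytoplasm segmentation
   on the NAD(P)H intensity image (Otsu + distance-transform watershed)
   and aggregation into the 13 OMI variables: optical redox ratio
   (NAD(P)H/FAD intensity) plus intensity, τ₁, τ₂, α₁, α₂, τ_m per
   channel.
4. **Multivariate analysis** (`omiflim.multivariate`) — condition
   z-score tables with average-linkage dendrograms, seeded UMAP
   embeddings, chi-squared variable ranking with accuracy-vs-k curves,
   and low/high-efficiency classification (logistic regression, SVM,
   random forest) with ROC/AUC evaluated on an independent replicate
   dataset. `EfficiencyClassifier` is sklearn-compatible.
5. **Synthetic data** (`omiflim.simulate`) — two-channel scenes of
   disk-shaped cells with known decay parameters, Poisson photon noise
   and condition-dependent metabolic shifts, plus cell-level feature
   tables with controlled class structure; everything seeded and
   byte-reproducible.

I/O covers plain-text ASC matrices (the SPCImage export dialect), HDF5
and multi-page TIFF decay cubes, and 16-bit label / 32-bit float TIFFs.

## Worked example

```python
import omiflim as of
from omiflim.core import NADPH, FAD
from omiflim.simulate import profiles_for_efficiency

irf = of.synth_irf(fwhm_ps=250.0, center_ps=600.0)   # 256 bins, 12.5 ns
scene = of.SceneSpec(shape=(96, 96), n_cells=6, radius_range=(6, 9),
                     profiles=profiles_for_efficiency(65.0),
                     efficiency=65.0, seed=3)
cubes, truth = of.generate_decay_cube(scene, irf)

nadph = of.fit_image(cubes[NADPH], irf, bin_level=1)   # 3x3 binning
fad = of.fit_image(cubes[FAD], irf, bin_level=1)
mask = of.segment_cytoplasm(nadph.intensity)
cells = of.extract_features(mask, nadph, fad,
                            of.ConditionLabel(efficiency=65.0, name="demo"))
print(cells[["nadph_tau_m", "fad_tau_m", "redox_ratio"]].round(2))
```

prints one row per recovered cell (six here), e.g.

```
   nadph_tau_m  fad_tau_m  redox_ratio
0       852.77     939.67         2.01
1       813.73    1021.74         2.37
2       804.15    1013.79         2.35
3       884.26     969.93         3.18
4       799.00    1016.55         2.54
5       911.52    1018.12         2.70
```

— NAD(P)H mean lifetimes around 800–900 ps, FAD around 1000 ps, and
redox ratios of 2–3, each within ~1 % of that cell's generating ground
truth (the simulated high-efficiency profile). The full pipeline
(simulate → fit → extract → classify, two conditions × three fields of
view) runs as

```sh
omiflim run --out runs/demo --seed 7
```

and prints a manifest such as

```json
{
  "config_hash": "1b5c052f2f607842",
  "seed": 7,
  "n_cells": 30,
  "auc": 0.96,
  "validation_accuracy": 1.0
}
```

where `auc` is the cell-level ROC AUC of the logistic-regression
classifier on the held-out replicate dataset. CLI subcommands
`simulate`, `fit`, `phasor`, `classify` and `run` expose the individual
stages; see `docs/methods.md` for models, parameters and limitations.

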