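# Methods

## Scope and model

`omiflim` implements the analysis chain used to predict human
pluripotent-stem-cell → cardiomyocyte differentiation efficiency from
label-free optical metabolic imaging (OMI) taken one day after Wnt
activation: per-pixel bi-exponential fluorescence-lifetime fitting of
NAD(P)H and FAD TCSPC data, phasor representation, single-cell feature
extraction into 13 OMI variables, and multivariate classification of
low (< 50 % cTnT+) vs. high (≥ 50 % cTnT+) efficiency conditions.

The per-pixel photon-count histogram is modeled as

    I(t) = A · (IRF ⊛ [α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂)]) + C,   α₁ + α₂ = 1,

with lifetimes in picoseconds throughout. The mean lifetime is
τ_m = α₁τ₁ + α₂τ₂ and the optical redox ratio is the per-pixel
NAD(P)H/FAD intensity ratio. For NAD(P)H the short component is the free
co-enzyme; for FAD the convention is reversed. The fitter always orders
τ₁ < τ₂; channel semantics are interpretation, not arithmetic.

### Incomplete-decay handling

The laser repetition period defaults to 12.5 ns (80 MHz Ti:sapphire
convention; the repetition rate is an instrument property, configurable).
At that period the long component (τ₂ ≈ 2.4–2.5 ns) has not decayed away
between pulses, so by default each exponential is folded periodically,
e^(−t/τ)/(1 − e^(−T/τ)), and the IRF convolution is circular over the
period. Non-periodic (linear) convolution is available but rejects
lifetimes exceeding the period.

## Fitting

* **Objective.** Poisson negative log-likelihood by default — TCSPC
  counts are Poisson and maximum likelihood is unbiased where
  least-squares weighting is not at low counts. A Neyman weighted
  least-squares objective (weights `max(count, 1)`) is provided for
  comparability with commercial least-squares fitters.
* **Initialization.** Bi-exponential objectives are ill-conditioned with
  long valleys, and single-seed quasi-Newton starts can stall far from
  the optimum. The fitter therefore starts from the best point of a
  deterministic coarse grid over (τ₁, τ₂) (7 × 7 geometric grid inside
  the bounds, pairs with τ₂ ≤ 1.5 τ₁ skipped) where amplitudes and
  offset are obtained by non-negative least squares against the
  IRF-convolved single-exponential basis; the basis depends only on the
  IRF and is computed once per image. The full five-parameter L-BFGS-B
  polish (analytic gradient) runs from that start, and the better of
  {grid start, polished point} under the objective is returned. No
  random restarts; results are deterministic.
* **Bounds.** τ₁ ∈ [50, 1500] ps, τ₂ ∈ [800, 8000] ps, C ≥ 0,
  0 ≤ α₁ ≤ 1. The overlapping τ ranges are resolved by the ordering
  convention (swap + relabel after optimization).
* **Thresholds and flags.** Pixels below 100 total photons (after
  binning) are flagged invalid and never fitted; parameter maps carry
  NaN there, never a silent zero. The convergence flag reports the
  optimizer's own status honestly — a grid-start fallback is marked
  unconverged.
* **Binning.** Spatial binning is a sliding-window sum over
  (2·level + 1)² neighborhoods (level 1 = 3 × 3, level 2 = 5 × 5) with
  truncated neighborhoods at the edges — no photons are fabricated by
  padding. Image dimensions are unchanged and the intensity map is always
  integrated from the unbinned cube.

Measured behavior (reproduced by the test suite): at 5 000 photons/pixel
the median recovered τ_m is within ~1 % of truth; at 10⁵ photons the
mean bias is < 0.1 %; precision improves monotonically with photons.

## Phasor transform

G and S are the normalized cosine/sine moments of the histogram at
ω = 2π·harmonic/period, evaluated at bin centers with periodic sampling.
This keeps noiseless mono-exponentials within 2×10⁻⁴ of the continuous
closed form G = 1/(1+(ωτ)²), S = ωτ/(1+(ωτ)²) at 256 bins, and makes the
transform exactly linear in intensity (mixtures lie on the chord between
component phasors). Supplying an IRF calibrates by complex division;
calibrating the IRF against itself yields (1, 0).

## Segmentation and feature extraction

Cytoplasms are segmented on the NAD(P)H intensity image: global Otsu
threshold (fixed threshold available), speck removal, distance-transform
watershed seeded from smoothed distance maxima to split touching cells,
area filtering, contiguous relabeling. An optional interior
intensity-dip rule excludes dark nuclei. This stands in for the study's
CellProfiler pipeline, whose settings are not public; it is validated
against synthetic ground truth only.

Each of the 13 variables is the arithmetic mean over the cell's valid
cytoplasm pixels (median available). The redox ratio is averaged
ratio-first, per pixel, as the ratio is defined per pixel; the
ratio-of-means is reported alongside as a sensitivity column. Cells with
fewer than 25 jointly-valid pixels (≈ 5 × 5) are dropped with a log
entry. A QC column reports |τ_m − (α₁τ₁ + α₂τ₂)| on the aggregated
values; it is nonzero only because averaging and the τ_m product do not
commute, and stays near zero for homogeneous cells.

## Multivariate analysis

* **Z-scores.** Per variable, condition means are standardized across
  conditions: z = (μ_observed − μ_row)/σ_row. σ_row is the *sample* SD
  (ddof = 1); the convention is not dictated by the z-score definition
  itself, so the choice is flagged here. A constant variable makes the
  z-score undefined and raises an error naming it.
* **Dendrograms.** Average-linkage agglomerative clustering on Euclidean
  distances in z-score space, over both conditions and variables;
  deterministic given input order (SciPy resolves distance ties by
  lowest cluster index).
* **UMAP.** Thin, seeded wrapper (n_neighbors 10, min_dist 0.3,
  euclidean or cosine, 2 components) over standardized features.
  Seeding forces single-threaded layout for exact reproducibility.
* **Chi-squared selection.** Features are min–max scaled to [0, 1]
  (the statistic needs non-negative values — a convention, flagged as a
  deviation risk since the study does not state its preprocessing) and
  scored by the one-way chi-squared statistic between per-class feature
  sums; ties keep the fixed column order. The accuracy-vs-k curve
  retrains the classifier on the top-k variables over 10 seeded
  re-splits of dataset 1 and reports mean ± SD.
* **Classification.** `EfficiencyClassifier` standardizes on training
  statistics and fits L2-regularized logistic regression at unit
  strength (weights on standardized features are therefore comparable
  across variables), an RBF SVM, or a 100-tree random forest. Dataset 1
  is split 80/20 into train/validation; ROC and AUC are computed from
  cell-level scores on the independent dataset 2, with a per-condition
  mean-score AUC as a secondary summary. A leakage guard refuses any
  cell id present in both datasets. No class reweighting by default.

## Synthetic data generator

The generator replaces both the microscope and the biology so every
stage is testable offline. It emulates: two-component decays per pixel
pushed through the same periodic IRF convolution the fitter inverts,
independent Poisson counting, Gaussian IRF broadening (synthesized IRF;
in practice the IRF comes from second-harmonic generation), disk-shaped
cells with per-cell truncated-normal parameter draws (constant within a
cell — the cell is the unit of biology downstream), offset-only
background, and condition-dependent shifts (higher efficiency → larger
free-NAD(P)H fraction, brighter NAD(P)H).

Defaults, chosen once as realistic for cultured-cell autofluorescence
and kept fixed: NAD(P)H α₁ 0.75, τ₁ 400 ps, τ₂ 2500 ps, 5 000
photons/pixel; FAD α₁ 0.65, τ₁ 300 ps, τ₂ 2300 ps, 2 500 photons/pixel;
background 0.01 counts/bin (dark-count level — offset-only pixels then
sit far below the fit threshold even after 3 × 3 binning); per-cell
spreads of a few percent; 256 bins over 12.5 ns. Seeding uses one master
seed with child streams spawned per cell and per channel, so output is
byte-identical for a fixed seed.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: optical blur (cells are hard-edged disks,
so segmentation is easier than in real images), photobleaching, drift,
detector afterpulsing, within-cell parameter heterogeneity, day-to-day
metabolic trajectories, and the real biological overlap between low- and
high-efficiency populations. Classifier AUCs on synthetic tables measure
the machinery, not the biological effect size; the study's reported
AUCs come from real imaging data that this package does not ship.

The cell-level table generator draws 13-variable multivariate normals
per condition, clips to physical ranges, restores α₁ + α₂ = 1 exactly,
splits each condition's cells across two replicate datasets, and labels
classes by the ≥ 50 % efficiency rule.

## Pipeline and problem sizes

`run_pipeline` executes simulate → fit → extract → classify from a
single config; the resolved config, a content hash, and the master seed
are written next to the outputs, and the feature stage is cached by that
hash. The built-in demo uses 2 conditions (15 % and 65 % efficiency) × 3
fields of view of 72 × 72 px with 5 cells each — sizes chosen so a full
demo completes in about a minute on one core while still exercising
every stage; the acceptance checks use a 20-cell 160 × 160 scene and
1 000 cells/class feature tables.

## Known limitations

* Numerical parity with the commercial SPCImage fitter is not claimed
  (its weighting, shift handling and thresholds are proprietary); only
  consistency with the stated decay model is verified.
* The optional IRF↔data time-shift parameter is off by default and the
  synthetic IRF is exactly the one used for fitting; real-instrument
  shift estimation is untested.
* Segmentation parameters are tuned for disk-like synthetic cells.
* Three-component decays, global multi-pixel fitting, and phasor-based
  unmixing are out of scope.
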