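# tmequant

Quantification toolkit for 3D tumor-microenvironment (TME) co-culture
experiments, built around tri-cultures of bone-marrow-derived macrophages
(BMDMs), fibroblasts and melanoma cells embedded in collagen-I gels. It is
aimed at researchers who image such cultures by time-lapse confocal
microscopy and profile them with multiplex secretion assays, and who need
the downstream numbers: how fast the macrophages move, what shape they take,
whether proximity to tumor cells changes their behavior, and how the
secreted cytokine profiles cluster.

## What it computes

**Motility.** From single-particle tracking exports (CSV; both a minimal
`track_id,x,y,z,t` header and the uppercase `TRACK_ID, POSITION_X, …`
export dialect are auto-detected):

- average speed — the mean magnitude of the planar net displacement per
  1 h interval (net displacement, not path length);
- time-averaged mean squared displacement per track, for a track with N
  steps:

  MSD(n) = 1/(N−n+1) · Σᵢ₌₀^(N−n) [(x₍ᵢ₊ₙ₎−xᵢ)² + (y₍ᵢ₊ₙ₎−yᵢ)²]

  and the ensemble mean ± SEM curve per condition. The log-log slope of
  MSD vs lag is 1 for uncorrelated diffusion and 2 for ballistic motion.

**Morphometry.** From projected, segmented label images, per cell:

- compactness = 4π·Area/Perimeter² (1 for a circle, lower for protrusive
  cells),
- circularity = 4π·Area/ConvexPerimeter² (insensitive to concavities),
- elongation = Width/Length of the minimum-area rotated bounding box,

plus a two-bin compactness classification at 0.8 separating round from
protrusive morphologies.

**Proximity.** Each macrophage is paired with its nearest tumor cell by 3D
Euclidean distance at the start of imaging; the 15 closest and 15 farthest
macrophages are compared with a one-tailed Welch t-test on average speed
(alternative: close faster than far).

**Secretion.** Multiplex plate preprocessing — below-range ("OOR<") entries
replaced with the analyte's lowest measured value, natural-log or z-score
transforms — followed by pairwise Pearson sample correlations, hierarchical
clustering (Euclidean, average linkage), and PCA. Single-cell secretion
matrices yield the secretor fraction (≥ 1 analyte above its positivity
threshold) and per-cell polyfunctionality counts.

**Bulk assays.** Caliper tumor volume 0.52·L·W², soluble collagen per mg
tumor, and fibroblast marker area per high-power field.

**Synthetic data.** `tmequant.simulate` generates all of the above with
known ground truth: populations seeded at 2400/600/200 K cells/mL
(12:3:1, 75% macrophages), persistent-random-walk macrophage tracks whose
mean speed depends on initial tumor distance (threshold 100 µm),
parametric disk/spindle/star label images with analytic shape indices,
and log-normal secretion plates with planted group effects, below-LOD
censoring and a planted secretor fraction (default 0.4).

## Worked example

Run the analysis drivers in order (each regenerates its inputs from the
seeded simulation and writes tables under `results/`):

```
$ python analysis/01_simulate_coculture.py
composition: {'macrophage': 240, 'fibroblast': 60, 'tumor': 20} (75% macrophages)

$ python analysis/02_track_motility.py
240 macrophage tracks, mean speed 7.33 µm/h (sd 2.56)
ensemble MSD log-log slope 1.31 (1 = diffusive, 2 = ballistic)

$ python analysis/04_tumor_proximity.py
close mean 11.98 µm/h vs far mean 5.92 µm/h; one-sided Welch p = 5.02e-23
```

The composition check is the seeding arithmetic (2400:600:200 reduces to
12:3:1 with 240/320 = 75% macrophages). The mixed-population mean speed of
7.33 µm/h sits between the configured far (6 µm/h) and close (12 µm/h)
regimes, and the MSD slope of 1.31 reflects a persistent random walk:
super-diffusive at short lags, diffusive at long ones. The proximity
comparison recovers the planted two-fold speed difference with a vanishing
one-sided p-value. `analysis/03_shape_morphometry.py` and
`analysis/05_secretion_profiles.py` do the same for shape indices (median
measured-vs-analytic error ≈ 0.01) and secretion profiles (secretor
fraction 0.36 measured against a planted 0.4 at n = 500 cells).

The same stages are available as a CLI (`tmequant simulate|tracks|motility|
morpho|proximity|secretion|assays|run`); `tmequant run config.yaml` executes
a multi-stage pipeline with a provenance manifest and byte-identical
reruns for a fixed seed.

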