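# Methods

This note records the models, estimators and numerical choices behind
`tmequant`, and what the synthetic data does and does not establish about
real 3D co-culture experiments.

## Motility statistics

**Speed.** A track's average speed is the arithmetic mean of the magnitudes
of its planar (x, y) net displacements over consecutive 1 h intervals, in
µm/h. This is a *net-displacement* speed: sub-interval wiggle does not
count, so it is a lower bound on instantaneous path speed. Spots are
snapped to the nominal interval grid by nearest timestamp; when two spots
fall in one bin the one closer to the grid time wins, and a gap longer than
one interval splits the track into segments so no displacement is computed
across the gap (gap handling is not standardized in the field; this choice
is explicit and local). Single-spot tracks carry no speed and are flagged
rather than dropped silently.

**MSD.** The time-averaged MSD at lag n uses all N−n+1 overlapping windows
of a track with N steps, planar coordinates only (an axial term can be
enabled but projected imaging makes z unreliable). The implementation is a
vectorized lag loop; the test suite keeps an independent brute-force
double-loop oracle and requires agreement to machine precision. Exact
limits used as tests: a straight-line track at speed v gives
MSD(n) = (v·dt·n)² exactly; uncorrelated random walks give an ensemble
log-log slope of 1.

**Ensemble curves.** Per lag, mean and SEM are taken over the tracks that
reach that lag; lags reached by fewer than 50% of usable tracks are
dropped (configurable), because the long-lag tail is otherwise dominated
by a few long tracks. Tracks shorter than 3 spots are excluded from
ensembles. Tracks are not truncated to a common length; the per-lag
contributing count is reported instead.

## Shape indices

Compactness 4πA/P², circularity 4πA/CP² (CP the convex perimeter), and
elongation width/length of the *minimum-area rotated* bounding box. The
rotated box was chosen over an axis-aligned one because cell orientation
in a gel is arbitrary; elongation is thereby rotation-invariant (verified
to within 3% under rectangle rotations).

Estimator choices, which matter more than is usually acknowledged:

- **Perimeter**: the 4-direction Crofton estimate. On the rasterized
  r = 50 px disk it errs by ~0.9%, against ~8–9% for chain-code or
  marching-squares polygon lengths, which would push a perfect circle's
  compactness to ~0.91. The trade-off is a known corner deficit: an
  axis-aligned 40×80 px rectangle measures compactness ≈ 0.784 against the
  continuous-rectangle value π·w·l/(w+l)² ≈ 0.698. Tolerances in the tests
  absorb this, and the synthetic ground truth always stores the analytic
  polygon values so the bias is visible, not hidden.
- **Convex perimeter**: Crofton measured on the rasterized convex-hull
  image, clamped to ≤ the region perimeter (a true convex hull can never
  be longer; discretization can nudge the raw estimate a fraction of a
  percent above on convex shapes). This guarantees circularity ≥
  compactness on every object.
- **Bounding box**: minimum-area rotated rectangle over the ±0.5 px
  corners of boundary pixels, so a w×h-pixel axis-aligned rectangle
  measures exactly w×h (pixel centers would give (w−1)×(h−1)).
- Area is the pixel count. Compactness slightly above 1 from
  discretization is reported as computed, with a QC flag above 1.05.

Discretization tolerance: ≈3% on all indices at linear sizes ≥ 30 px
(≈5% for thin-armed stars), established on the parametric fixtures.

Segmentation of projected images is deliberately plain — Otsu threshold,
8-connected components, small-object removal, maximum-intensity projection
for stacks — because the package's contribution is the measurement, not
the segmentation. Border-touching objects are measured but flagged
truncated.

## Proximity analysis

Distances are 3D Euclidean, computed at the first imaging timepoint only;
the close/far regime is therefore static ground truth even though cells
move. Ranking ties break by macrophage id, nearest-tumor ties by lowest
tumor id, making group membership deterministic. The comparison is a
one-tailed Welch t-test (alternative: close faster), chosen over Student's
because it is safe under unequal variances and reduces to Student's when
variances match. The degenerate zero-variance/equal-means case reports
t = 0, p = 0.5 with a flag. Calibration is tested: under the null the
rejection rate at α = 0.05 is 0.05 ± 0.02 over 2000 simulations; with the
default planted effect (12 vs 6 µm/h, sd 2, n = 15 per group) power
exceeds 0.9.

## Secretion preprocessing

Censoring is below-range only; above-range flags trigger a validation
warning since saturation is not expected in these assays. Imputation
replaces each censored entry with the *minimum uncensored value of that
analyte*, the standard vendor-recommended rule; an analyte with every
entry censored cannot be imputed and is flagged instead. The operation is
idempotent. z-scores use the sample (n−1) standard deviation;
zero-variance analytes are left at 0 with a warning. ln of non-positive
entries requires an explicit pseudo-floor. Clustering defaults to
Euclidean distance with average linkage and scipy's deterministic leaf
order; PCA centers per analyte and reports non-increasing explained
variance fractions. Single-cell positivity thresholds default to a
declared per-analyte constant (the synthetic generator plants them);
against real microwell data they should be set to mean + 2 sd of a
measured background population. "Polyfunctional" is defined here as ≥ 2
analytes above threshold — a convention, configurable.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study conditions, not
their biology:

- **Population**: uniform random placement at the 2400/600/200 K/mL
  seeding ratio (12:3:1; 75% macrophages), desk-scale default 320 cells in
  a 1000×1000×300 µm domain.
- **Trajectories**: a planar persistent random walk. Headings follow a
  wrapped normal around the previous heading with σ = √(−2·ln p) so the
  mean resultant length equals the persistence p (default 0.6); p ∈ [0, 1]
  with 1 meaning the deterministic ballistic limit. Step lengths are
  gamma-distributed with mean speed·dt and CV 0.3 (CV 0 is deterministic).
  Mean speed per cell is set once from the initial 3D distance to the
  nearest tumor cell: 12 µm/h within 100 µm, 6 µm/h beyond. The imaged
  study reports the close-versus-far effect only graphically, so these
  speeds are illustrative defaults sized to a clearly detectable two-fold
  effect, not calibrated values. Boundaries reflect (folding preserves
  step lengths except on the rare boundary-crossing step). Fibroblasts
  and tumor cells get 0.2 µm Gaussian jitter.
- **Label images**: non-overlapping disks, rotated rectangles and 5-armed
  stars with ±20% size jitter; ground truth is the analytic polygon
  geometry.
- **Plates**: per-analyte log-normal concentrations (log-means spanning
  ~3–6.5, log-sd 0.6) over two groups of 6 samples, with co-culture
  doubling a subset of analytes; LOD 15 pg/mL censors a few percent of
  entries, concentrated in the low-abundance analytes.
- **Single cells**: secretor probability 0.4 (matching the observed ~60%
  non-secreting fraction); secretors draw one of three planted profiles
  with profile analytes strictly above threshold, non-secretors stay
  strictly below every threshold.

What passing tests show: the estimators implement their definitions
correctly, recover planted effects at the configured sizes, and are
deterministic and calibrated. What they do not show: anything about real
optical artifacts (segmentation merge/split errors, z-projection overlap),
real motility models (no cell–cell interaction, division, death or
time-varying speed), assay chemistry (no 4PL curve fits, no plate drift),
or the actual magnitudes of biological effects.

## Determinism and problem sizes

Every stochastic stage draws from `numpy` generators seeded as
(seed, stream) pairs, one stream per modality, so outputs are bit-identical
for a fixed config and all modalities are independently reproducible. The
pipeline writes CSV with a fixed `%.9g` float format; reruns are
byte-identical, verified by file comparison. Default desk-scale sizes
(320 cells, 48 hourly steps, 18 mask objects, 12×12 plates, 500–1000
single cells, 500/2000 resampling replicates for power/null checks) keep
the full test suite and the acceptance script in the seconds-to-minutes
range while leaving sampling error well inside every stated tolerance.

## Known limitations

- The boundary-centroid versus area-centroid distinction for irregular
  cells is not implemented; centroids are not used by any shipped index.
- Crofton's corner deficit biases compactness upward for near-axis-aligned
  rectangles (see above); cross-study comparisons should fix one estimator.
- The close/far split operates per input table; pooling across replicate
  fields of view is the caller's decision.
- Proximity uses initial distance only; no time-resolved contact analysis.
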