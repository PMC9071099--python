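# Methods

This note documents the models, algorithms and design choices behind
`ddrquant`, in the order data flows through the package.

## Scope and data model

The package analyses fluorescent DDR reporter screens: HepG2 lines carrying
GFP fusions of p53, p21 (CDKN1A) or BTG2, cultured as 2D monolayers or 3D
spheroids in four model/medium combinations, exposed to genotoxicants over
8-point geometric concentration series with three biological replicates and
solvent-control wells, and imaged in three channels (Hoechst 33342 for
nuclei, GFP for reporter activity, propidium iodide for dead cells).
Images arrive as single planes (2D) or z-stacks of ~9–11 planes at 30 µm
spacing (3D); well-level measurements travel as a tidy table with columns
`model, reporter, compound, concentration_uM, duration, replicate,
well_type{treated,solvent}, readout{gfp,atp,pi_fraction}, value`.

## 2D single-cell quantification

**Nuclei segmentation** (`segment_nuclei`). The Hoechst image is Gaussian
smoothed (σ = 2 px), masked by the AND of a local-mean adaptive threshold
(block 51 px) and half the global Otsu level — the Otsu floor prevents the
local threshold from promoting empty background to foreground — and
partitioned by a seeded watershed on the inverted smoothed intensity.
Seeds are the regional intensity maxima (minimum separation 6 px);
distance-transform maxima are added as auxiliary seeds where a close pair of
nuclei blurs into a single intensity peak, deduplicated against the
intensity peaks. Objects below `min_area` (40 px) are removed and labels
made consecutive. Objects touching the border are kept by default
(`exclude_border=True` drops them). Correctness is defined against synthetic
ground truth — the original screen's in-house segmentation macro is not
available, so no attempt is made to reproduce it operation for operation.

**Cytoplasm rings** (`segment_cytoplasm`). Each nucleus is expanded by 6 px
of Euclidean distance and the nuclear area subtracted, leaving a ring per
cell. Contested pixels go to the nearest nucleus; exact ties go to the lower
label, which makes the output deterministic and independent of processing
order. The ring map carries exactly the label set of its input; a fully
enclosed nucleus can legitimately own an empty ring, which downstream
measurement flags as NaN rather than dropping the cell.

**Measurement** (`measure_cells`). Mean GFP per nuclear and per ring pixel
set; reporter biology dictates which compartment is primary (p53/p21
accumulate in the nucleus, BTG2 signal is cytoplasmic). PI positivity: a
cell is dead when at least 10 % of its *nuclear* area overlaps the
thresholded PI signal — the boundary is inclusive, and the denominator
convention (nuclear area, not PI-object area) is configurable via
`pi_overlap_threshold` plus a custom mask. The PI threshold defaults to Otsu
on the PI channel and can be fixed in configuration.

## 3D spheroid quantification

Z-stacks are reduced by per-pixel maximum projection (order-invariant,
idempotent); GFP and PI are projected with the same operator so all
measurements live on one 2D domain — per-plane volumetric measurement is
deliberately not attempted. Spheroids are connected components of the
supra-threshold Hoechst projection (Otsu by default), hole-filled because
spheroid cores can project dim, with components under 200 px discarded as
debris. Per spheroid: mean GFP and PI-positive area fraction (supra-threshold
PI pixels inside the spheroid / spheroid area). Both per-spheroid records and
the well mean are available, since the aggregation level is an open choice.

## Concentration–response statistics

**Fold change** divides responses and controls by the solvent-control mean
(requires a positive control mean). **Min–max normalisation** rescales a
culture model's value collection onto [0, 1]; constant collections map to
zeros with a degenerate flag rather than raising.

**Point of departure.** Replicate responses (fold change by default) are
smoothed by loess — locally weighted linear regression with tricube weights
— against log₁₀ concentration. The span is 0.5, read from the source
protocol's "2/4" (which could also be a typo for 3/4; the parameter is
exposed, and the recovery study can be re-run at any span). The smoother is
statsmodels' `lowess` with `it=0` (no robustness iterations, matching a
plain Gaussian-family loess); a brute-force tricube weighted-least-squares
oracle in the test suite pins its behaviour. Solvent controls sit at
concentration 0 and are excluded from the fit (log of zero is undefined);
they define the band *mean ± 2·SD* instead, where SD is the sample SD of the
control wells (a residual-SD alternative is behind
`band_from_fit_residuals`). The fitted curve is evaluated on 512 log-spaced
grid points across the tested range; the PoD is the linear-in-log
interpolated first crossing out of the band, in either direction. A curve
already outside the band at the lowest tested concentration yields a
censored PoD at that concentration; no crossing yields *undefined* — never
an extrapolation. The statistic is invariant to affine rescaling applied
jointly to responses and controls, and widening the band can only move the
PoD up or to undefined.

Local-linear smoothing bias matters on steep curves: at span 0.5 a noiseless
Hill curve with slope 1 is reproduced within ~3 % at the design points, but
slope-2 curves deviate up to ~10 % near the inflection. This bias is one
reason PoD recovery is assessed on the dilution-step scale (below) rather
than pointwise.

**Absolute IC50.** Viability (percent of solvent control) is fitted by a
four-parameter log-logistic with the top plateau fixed at 100 %
(`scipy.optimize.curve_fit`, bottom ∈ [0, 100], slope ∈ [0.05, 20], EC50
within two decades of the tested range). The IC50 is the concentration where
the fit equals 50 % of control — the absolute definition. Curves that never
reach 50 % inside the tested range (including flat 100 % viability) are
undefined. A parametric fit is used here, rather than loess, mirroring the
separate procedure viability data conventionally get in dose–response
software.

## Relative expression

`delta_delta_ct` implements fold = 2^−ΔΔCt with ΔCt = Ct(target) −
Ct(housekeeping) per sample (GAPDH default) and ΔΔCt taken against a
reference sample, whose fold is pinned to exactly 1. Technical replicates
are averaged before ΔCt. Undetected wells (NaN Ct) propagate as flagged
missing folds and are never imputed as a cycle ceiling. Folds are invariant
to any global Ct shift.

## Cross-model comparison

GFP responses are min–max normalised *within each culture model*, pivoted to
a profile matrix (conditions × compound/concentration features), compared by
Euclidean distance, and — when clustering culture models — averaged
element-wise over the three reporters. Agglomerative clustering supports
**complete** linkage (default) and **Ward** linkage on the precomputed
distance matrix (as R's `hclust`/`pheatmap` apply it): the source protocol
names complete linkage in its methods text but Ward's distance in its figure
legends, so neither is privileged and both are first-class. PoD profiles are
clustered on the log₁₀ scale with undefined PoDs encoded as a sentinel one
dilution step (10^⅓) above the compound's highest tested concentration, so
insensitive conditions cluster together; sentinel rows carry a
`pod_undefined` flag. Trees serialise to newick plus a merge table.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
optics; there is no PSF, chromatic aberration or photobleaching, so passing
tests demonstrate correctness of the measurement and statistics pipeline,
not robustness to real microscope artefacts.

- **Monolayers**: nuclei are anisotropic Gaussian blobs with half-maximum
  radii 5–9 px on a 512×512 16-bit canvas, placed by rejection sampling with
  a minimum center distance (16 px default; failure after 10 000 attempts is
  a `PackingError`, never silent truncation). The half-maximum contour is
  the ground-truth mask; each pixel belongs to at most one nucleus. GFP is
  painted at a constant level over the cell footprint; PI covers the full
  nuclear mask of the chosen positive cells, or a stated fraction of it
  (row-major pixel order) for exact overlap fixtures. Gaussian read noise
  (default SD 100 on the 0–65535 scale) is added to all channels.
- **Spheroids**: spheres with radii 80–120 µm at 2 µm/px, centers on the
  middle z-plane so the maximum projection equals the equatorial disk;
  per-plane cross-sections follow the sphere geometry at the 30 µm plane
  spacing. PI paints a concentric core covering a stated fraction of the
  projected area. Intensities are hard-edged (no partial-volume softening).
- **Response tables**: mean response = baseline · (1 ± (max_fold_change − 1)
  · hill(c; EC50, slope)) with Gaussian noise, the minus sign for decreasing
  (viability-style) curves, clipped at zero — so max_fold_change = 2 drives
  a viability curve to complete kill. `ResponseModel.from_onset` calibrates
  the EC50 so the noiseless curve crosses baseline ± 2·noise_sd exactly at a
  requested onset concentration: the generator's "true PoD" is then
  analytically the quantity the estimator targets, and recovery error
  measures estimation error alone. The default plate design is 4 culture
  models × 3 reporters × 5 compounds (series endpoints 0.10–21.54,
  0.22–100, 0.0037–0.80 µM) × 3 durations, 3 replicates, 6 solvent wells
  per condition — solvent-well count is a package choice (typical screening
  plates carry several solvent wells per condition; 6 gives a usable SD
  estimate).
- Every generator takes one integer seed and owns one `numpy`
  `default_rng` stream; identical seeds give bitwise-identical outputs.

## Validation studies and problem sizes

`ddrquant.validation` packages the end-to-end studies used by the acceptance
tests and `scripts/acceptance.py`:

- *PoD recovery*: 200 curves, onsets log-uniform over the tested range, fold
  changes 2–5 (matching the ~4.5-fold inductions such reporters show), Hill
  slopes 1–3, noise SD = 10 % of baseline, 3 replicates, 6 controls.
  Median |log₁₀ PoD − log₁₀ onset| is compared to one dilution step
  (⅓ log₁₀ unit); undefined estimates count as infinite error.
- *PoD null*: 200 flat curves (max fold change 1); the fraction returning
  undefined measures the false-positive behaviour of the 2·SD band
  (~92 % across seeds).
- *IC50 recovery*: true IC50 at each of the 8 design concentrations,
  noiseless and at 5 % noise. Estimates at the extreme placements can come
  back undefined under noise because the estimator refuses to report a
  crossing outside the tested range.
- *Segmentation*: 20 images, 100–300 nuclei each at ≥ 1.5×radius spacing,
  noiseless (isolating geometric performance), matched one-to-one to
  ground-truth centers by optimal assignment within one maximum radius.
- *Geometry fixtures*: exact PI-rule classification at 5/9/10/50/100 %
  overlap on 100-px square nuclei; ring width on a disk fixture; single
  sphere projected area vs the analytic equatorial disk πr².
- *Clustering*: planted two-group profiles (between-group separation 10×
  within-group spread) recovered at ARI = 1 under both linkages;
  complete-linkage heights verified against brute-force agglomeration on 8
  leaves.

These sizes keep the full suite and the acceptance script each under a
minute of CPU while leaving the statistical margins wide.

## Known limitations

- The 2D segmentation is tuned for blob-like, moderately dense nuclei; it is
  not expected to handle confluent sheets, strong illumination gradients or
  out-of-focus planes.
- Loess at span 0.5 underestimates steep induction shoulders (see above);
  PoD values on very steep curves inherit that bias, typically toward lower
  concentrations.
- The absolute IC50 model fixes the top plateau at 100 %; screens whose
  controls drift need renormalisation before fitting.
- The synthetic spheroid PI core is concentric, while real spheroid death is
  often peripheral under acute insult; the measured quantity (area fraction)
  is unaffected by the spatial pattern.
- Cell tracking, mitosis detection and time-course dynamics of p53 pathway
  oscillation are out of scope.
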