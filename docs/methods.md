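# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `nanoclust`. Units are nm and nm² throughout unless
stated; areas in µm² are flagged explicitly.

## Coordinate conventions

All continuous coordinates are nm with the origin at the lower-left
corner of the field; images and grids are row-major `values[iy, ix]`
with pixel (0, 0) covering `[0, pixel_size)` in both axes. ROI
membership is half-open (`x0 ≤ x < x0 + width`), so adjacent tiles
partition events without double counting. Localization tables are
event-based: one row per detected blink, several rows per fluorophore.
The pipeline deliberately analyses *events*, not molecule estimates —
no blink correction is attempted, and every detection statistic must be
read as event-level.

## Second-order point statistics

`ripley_k` computes the edge-corrected estimator
K̂(r) = A/(n(n−1)) Σ_i Σ_{j≠i} e_ij 1(d_ij ≤ r) with Ripley's isotropic
correction for a rectangular window: e_ij is the reciprocal of the
fraction of the circle of radius d_ij centred at event i that lies
inside the window (exact arc/corner geometry, valid for
r ≤ min(side)/2, which `ripley_k` enforces). L(r) − r = √(K̂/π) − r is
the variance-stabilised clustering curve. CSR envelopes are pointwise
quantile envelopes over `n_sim` uniform patterns of exactly n points
(default 199 simulations for a 99% envelope, following the
"99 simulations" convention; the pointwise — not simultaneous — reading
is the one commonly used for such envelopes in cluster-mapping work).

`local_l` is the per-event Getis–Franklin statistic
L_i(r₀) = √(A Σ_{j≠i} e_ij 1(d_ij ≤ r₀)/(π(n−1))), with the (n−1)
divisor so a self-pair never counts. A calibration subtlety worth
stating: under CSR the *quadratic mean* of L_i returns r₀ at any
density, but the *median* L_i is 0 whenever the expected neighbour
count λπr₀² is below ~0.7 (at 30 nm and typical SMLM densities of
100–200 events/µm² it is), because most events then have no neighbour
in range. Statements like "CSR gives L_i ≈ r₀" only hold pointwise at
high density; the tests assert both regimes explicitly.

## Cluster maps and nanocluster extraction

The cluster map evaluates the same Getis–Franklin functional at every
grid-pixel centre (default 10-nm grid, r₀ = 30 nm):
L(p) = √(A·w(p)·#{events within r₀ of p}/(πn)), where w(p) is an exact
disc-area edge correction. The exceedance set of this field tracks
where event density is genuinely elevated.

An interpolation variant (per-event L_i values linearly interpolated on
the Delaunay triangulation of the events, zero outside the hull) is
retained as `method="interpolate"` because such surfaces are common in
the literature, but it is not the quantitative default: the height of
an interpolated peak scales with the *peak* L_i, so a tight cluster
with a high peak stays above any fixed threshold far into the
surrounding background, and footprint areas then grow as clusters
shrink. Measured on matched synthetic regimes, interpolated footprints
for 6,000 vs 15,000 nm² true areas came out ~64,000 vs ~34,000 nm² —
inverted ordering — whereas the grid map orders them correctly.

**Threshold calibration.** The binarization threshold is the
`quantile` (default 0.995) of map values pooled over `n_sim` (default
50) CSR simulations at the observed event density, seeded and recorded.
0.995 rather than 0.99 is a multiplicity choice: a 300×300-pixel map
has 9·10⁴ pixels, so a 0.99 pixel quantile admits ~900 chance pixels
per map, which aggregate into dozens of spurious components; at 0.995
with the default `min_area` the CSR pipeline assigns < 1% of events to
clusters (measured over 50–500 events/µm²).

**Components and `min_area`.** Pixels above threshold are labelled with
8-connectivity (diagonal-connected, so round clusters do not fragment).
Components below `min_area` = 1,000 nm² are discarded: chance
exceedance blobs in calibrated CSR maps reach ~1,500 nm² at the default
grid, and the floor removes most of them at the cost of insensitivity
to genuine clusters smaller than ~1,000 nm² (36 nm diameter — below
what a 20-nm localization precision can resolve as a footprint anyway).
Events are assigned to clusters by footprint containment (the event's
pixel is a cluster pixel), not nearest centroid.

**Two area readouts.** Each cluster carries:

* `area` — the binary-footprint area, pixels × grid_step². Because the
  r₀-disc counting kernel smooths the density field, footprints are
  dilated by a roughly constant radial amount of order r₀ relative to
  the underlying cluster extent; with 20-nm localization noise the
  smallest achievable footprint is ~7,500 nm². Footprint areas are
  faithful for comparisons at fixed settings but biased upward as
  absolute sizes, most strongly for small clusters.
* `area_event` — an event-based equivalent-circle area: 4πσ̂², where σ̂²
  is estimated from the mean squared distance of member events to their
  centroid with a truncated-Rayleigh correction for the fact that
  membership is clipped at the footprint boundary (solved by fixed
  point; needs ≥ 5 members). For compact Gaussian-like clusters this
  estimator is unbiased and is the one used for parameter-recovery
  checks; it assumes approximately isotropic clusters.

Cluster statistics per ROI: median/mean area (both readouts),
clusters/µm², percent of events in clusters, relative in-cluster
density (events-in-footprints density over overall density), size-bin
fractions with edges at 5,000 and 15,000 nm² (lower bin closed above:
a 5,000 nm² cluster is "small"), and overall event density. The
equivalent-circle diameter d = 2√(area/π) maps the edges to 80 and
138 nm.

## Co-localization

`pearson_costes` implements Costes auto-thresholding: a symmetric
reduced-major-axis line B = aA + c is fitted over mask pixels, and the
channel-A threshold is bisected down the line until the pixels below
*both* thresholds have Pearson ≤ 0; the reported coefficient is then
computed over mask pixels above threshold in *either* channel
(configurable to all mask pixels via `use_costes=False`). The RMA line
(slope sign(cov)·σ_B/σ_A) rather than total least squares is
deliberate: RMA is equivariant under affine rescaling of either
channel, which makes the thresholded coefficient invariant to detector
gain and offset — total least squares is not, and measurably shifts the
result under a gain change. If the channels are already uncorrelated at
the top of the range, thresholds fall to the channel minima and all
mask pixels are used. Constant channels raise an error rather than
returning a coefficient.

STED-style binary maps use Otsu's threshold within the cell mask by
default (an absolute threshold is available for calibrated synthetic
tests); centroids are intensity-weighted unless disabled. Centroid
distances are nearest-neighbour distances from each channel-A centroid
to the channel-B centroid set.

## Cluster association and the randomization null

Receptor clusters are ranked by footprint area and split into per-cell
tertiles (small/medium/large; remainders go to the lower bins, ties
broken by input order). Each receptor cluster is screened for
signalling clusters; two geometries are provided:

* `mode="edge"` (default): associated iff any signalling-cluster pixel
  lies within `search_radius` R of the receptor cluster's own pixels —
  i.e. the screened region is the footprint dilated by R.
* `mode="centroid"`: a fixed circle of radius R around the centroid.

The default is a genuine design decision, not a convenience: with a
fixed circle around the centroid, the chance that an independently,
uniformly placed partner lands in the screened region does not depend
on receptor size at all, so the size-tertile structure of the null
would be flat. The biology being tested is precisely that *bigger
clusters present more boundary* to independently placed partners; the
footprint-dilation geometry carries that effect (and for point-like
receptor clusters the two modes coincide, which is how the analytic
check below applies to both). The search radius has no canonical value
and defaults to 500 nm; every output records it.

"Nearby signal intensity" sums the signalling image over the screened
region (`intensity_scope="region"`); summing whole associated clusters
is available (`"whole_cluster"`) since either reading of "intensity of
clusters found nearby" is defensible.

The null (`randomize_null`, default 100 replicates; the tertile
acceptance checks use ≥ 200) rigidly translates each signalling
cluster's pixel footprint — with its intensity patch — to a position
drawn uniformly from all placements fully inside the cell mask
(enumerated exactly by mask erosion with the footprint), keeping
receptor clusters fixed. Cluster count and areas are preserved exactly;
randomized clusters may overlap one another, the simplest null
consistent with uniform re-placement (an exclusion model would need an
interaction assumption there is no basis for). Rotations are not
applied. For m point-like signalling clusters in a full-window mask of
area A the per-cluster association probability is
1 − (1 − πR²/A)^m, used as a closed-form oracle. Determinism: a fixed
seed reproduces the null bit-for-bit.

## Synthetic data

`simulate_smlm` draws cluster centres uniformly (with a 200-nm margin
and 400-nm minimum separation so clusters neither straddle the border
nor merge), places Poisson-distributed molecules per cluster as an
isotropic Gaussian of spread σ_c plus a uniform background, gives each
molecule a Geometric(mean μ = 2) number of blink events — memoryless
re-detection is enough to create the multiple-counting that event-based
cluster analysis must tolerate, without a full photophysics state model
— and jitters every event by N(0, σ_loc²) with σ_loc = 20 nm, mirroring
at the window border so event counts are exact. The expected event
count (molecules × μ) is a closed-form oracle.

The *true area* of a generated cluster is defined once as the
equivalent-circle area of the 2σ circle of its event scatter,
A = 4π(σ_c² + σ_loc²) (~86.5% containment). With σ_loc = 20 nm this
puts a hard floor of ~5,000 nm² on realisable event-footprint areas —
smaller nominal clusters are below the resolution of the localization
noise itself.

Size-contrast regimes (`matched_density_regime`) hold the
*within-cluster molecule density* constant (molecules per cluster
proportional to target area, 1 molecule per 375 nm²) and adjust the
cluster count to keep the total molecule budget — hence overall event
density — matched. This matters: with a fixed number of events per
cluster, the two regimes' density profiles cross any fixed calibrated
threshold at different relative radii and no single area convention
describes both. Constant packing density is also the configuration the
in-cluster density ratios of real receptor data suggest. Default
regimes target 6,000 vs 15,000 nm² true median areas at ~120–150
events/µm² total.

`simulate_two_channel` renders disc-shaped spots (default 12 spots of
60-nm radius, ≥ 500 nm apart) inside an elliptical cell mask, blurs
with a Gaussian PSF of 80-nm FWHM at 20-nm pixels, adds a flat
background and Poisson noise. Channel-B discs sit at a configured
offset from their channel-A partners in random directions and inherit
the partner's per-spot brightness (scaled), so offset 0 without noise
is the exact positive control. `make_cell_mask` builds the ellipse with
optional low-order boundary roughness (kept small so the mask stays
simply connected).

What the generators do *not* emulate: camera noise models (EMCCD gain,
read noise), realistic photoswitching kinetics and drift,
molecule-density gradients across the cell, irregular (non-Gaussian,
non-disc) cluster shapes, and 3-D structure. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to every artefact of real acquisitions.

## Group statistics

Mann–Whitney U uses the exact null when both n ≤ 8 without ties, else
the tie-corrected normal approximation; two identical samples return
p = 1 rather than erroring. Kruskal–Wallis (≥ 3 groups; two groups are
redirected to Mann–Whitney) and the row-matched Friedman test take
their omnibus statistics from scipy; Dunn's pairwise post-tests are
computed on pooled-rank means (tie-corrected variance) or within-row
rank sums (z = (R_i − R_j)/√(nk(k+1)/6)) respectively, with Bonferroni
adjustment over all pairs — the conventional reading of "Dunn's
post-test". Calibration is verified empirically: 2,000 null
simulations per test give rejection rates within [0.035, 0.065] at
α = 0.05.

## Problem sizes and determinism

Analyses are deterministic given their seeds; pipeline outputs embed
the full configuration and package version, and repeated runs are
byte-identical. The verification suite works at the scale of single
3 × 3 µm ROIs with ~10³ events (maps of 300 × 300 pixels), 20-seed
specificity and recovery sweeps, 200–400 null replicates for the
association geometry, 20-seed co-localization contrasts, and 2,000-rep
type-I calibrations — sizes chosen so each property is measured with
meaningful Monte-Carlo resolution while a complete run of tests plus
the acceptance script stays within a few minutes on one CPU.

## Known limitations

* Absolute footprint areas are dilated by the r₀ kernel (see above);
  cross-condition *contrasts* at fixed settings are the robust readout,
  absolute values are indicative. The event-based area corrects this
  under a Gaussian cluster model only.
* Quantification is sensitive to r₀, grid step, calibration quantile
  and `min_area`; all are recorded in every output, and none should be
  compared across differing settings.
* The association screen treats the cell as 2-D and the null ignores
  topography and membrane heterogeneity; its verdicts are relative to
  uniform re-placement within the mask.
* Tertile boundaries are per cell, so "large" is not a fixed size
  across cells.
* No drift correction or multi-emitter handling: tables are taken as
  delivered by the upstream localization software.
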