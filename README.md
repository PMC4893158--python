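# nanoclust

Quantitative nanocluster analysis for super-resolution microscopy of
membrane receptors.

Immune receptors such as the killer-cell Ig-like receptors (KIR) are not
spread uniformly over the cell surface: they sit in nanometre-scale
clusters whose size and spatial relationships to signalling molecules
(adaptors like DAP12, kinases like ZAP-70, phosphatases like SHP-1)
shape how the cell integrates activating and inhibitory signals.
`nanoclust` implements the analysis chain used to quantify that
organisation from two kinds of data:

* **Single-molecule localization microscopy (SMLM / GSDIM)** tables —
  one row per detected blink event, nm coordinates — analysed with
  Ripley's K function, Getis–Franklin local L(r) cluster maps, and
  CSR-calibrated binarization into nanoclusters with per-region
  statistics (median area, clusters/µm², percent of events in clusters,
  relative in-cluster density, size-bin fractions).
* **Two-channel STED-style images** — Pearson co-localization with the
  Costes auto-threshold, binary cluster maps, nearest-centroid
  distances, and a cluster-association statistic: each receptor cluster
  is screened for signalling clusters within a search radius,
  conditioned on receptor-cluster size tertiles, and compared against a
  null in which signalling-cluster footprints are re-placed uniformly at
  random inside the cell mask.

A first-class synthetic-data module generates localization tables
(Gaussian nanoclusters over a CSR background, geometric re-blinking,
localization noise) and paired spot images with controllable
inter-channel offsets inside cell-shaped masks, so the entire pipeline
is testable against known ground truth.

## The statistics at the core

For n events in a window of area A, the edge-corrected Ripley estimator
is

    K̂(r) = A / (n(n−1)) · Σ_i Σ_{j≠i} e_ij · 1(d_ij ≤ r),

with isotropic edge weights e_ij, and L(r) − r = √(K̂(r)/π) − r is ~0
under complete spatial randomness (CSR) and > 0 at scales where the
pattern clusters. The per-location Getis–Franklin statistic

    L(p; r₀) = √( A · w(p) · #{events within r₀ of p} / (π n) ),

evaluated on a 10-nm grid with r₀ = 30 nm, forms the cluster map; the
binarization threshold is the 0.995 quantile of map values pooled over
CSR simulations at the same event density, so that surviving structure
is clustered beyond chance. 8-connected components of the binary map are
the nanoclusters; areas convert to equivalent-circle diameters via
d = 2√(area/π) (5,000 nm² ↔ 80 nm, 15,000 nm² ↔ 138 nm).

For the association statistic, a receptor cluster is "associated" when
any signalling-cluster pixel lies within the search radius R of its
footprint, and the null distribution re-places each signalling cluster's
rigid footprint uniformly inside the cell mask over many replicates.
For point-like clusters in a full window this null has the closed form
P(associated) = 1 − (1 − πR²/A)^m for m signalling clusters, which the
test suite checks by Monte Carlo.

## Worked example

```python
import numpy as np
from nanoclust import (
    RegionOfInterest, simulate_smlm, analyze_gsd_cell, AnalysisConfig,
)

roi = RegionOfInterest(0, 0, 3000, 3000)          # one 3 x 3 um region
table, truth = simulate_smlm(window=roi, sigma_c=20.0, seed=1)
res = analyze_gsd_cell(table, [roi], AnalysisConfig(threshold_n_sim=20))
for k, v in res.per_cell.items():
    print(f"{k}: {v:.3g}")
```

prints

```
median_area: 1.08e+04
median_area_event: 9.82e+03
mean_area: 9.3e+03
clusters_per_um2: 2.78
percent_events_in_clusters: 72.4
relative_density: 28
event_density: 137
```

i.e. this simulated membrane patch carries ~2.8 nanoclusters/µm² with a
median footprint of ~10,800 nm² (event-scatter estimate ~9,800 nm²),
72% of detected events inside clusters, and events packed 28-fold
denser inside clusters than the membrane average of 137 events/µm².
The same workflow runs from the shell:

```bash
nanoclust simulate smlm --seed 1 --out sim/
nanoclust gsd --localizations sim/localizations.csv --rois rois.json --out out/
nanoclust sted --channel-a a.tif --channel-b b.tif --mask mask.tif --pixel-size 20 --out out/
```

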