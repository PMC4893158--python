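"""Ground-truth generators for localization tables and two-channel images.

Two regimes are emulated:

* SMLM ("GSDIM-like") localization tables: fluorophores sit either in
  tight Gaussian nanoclusters or in a uniform (CSR) background; each
  fluorophore re-blinks a Geometric number of times, and every blink is
  reported with isotropic Gaussian localization noise.  Multiple
  re-detections per molecule are deliberate: event-based cluster analysis
  must tolerate that inflation.

* Paired "STED-like" images: disc-shaped nanoclusters rendered inside a
  cell-shaped mask, blurred with a Gaussian PSF and corrupted by Poisson
  noise; channel-B discs are displaced from their channel-A partners by a
  configurable centroid offset (0 for a perfectly co-localized positive
  control, ~150-300 nm for juxtaposed/segregated regimes).

Every generator takes an explicit seed and records it in its truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import CellMask, LocalizationTable, PixelImage, RegionOfInterest

__all__ = [
    "SMLMTruth",
    "TwoChannelTruth",
    "simulate_smlm",
    "simulate_two_channel",
    "make_cell_mask",
    "cluster_event_area",
    "sigma_for_cluster_area",
    "matched_density_regime",
]

#: Fraction of a cluster's event distribution counted as the cluster
#: footprint when converting a Gaussian spread to an equivalent-circle
#: area (2-sigma radius of the event scatter, ~86.5% of events).
AREA_CONTAINMENT_FACTOR = 4.0 * np.pi  # area = factor * sigma_events^2


def cluster_event_area(sigma_c: float, sigma_loc: float) -> float:
    """Equivalent-circle area (nm^2) of a cluster's event footprint.

    Events around a cluster centre scatter with total standard deviation
    sqrt(sigma_c^2 + sigma_loc^2) (molecular spread plus localization
    noise); the footprint is the circle of twice that radius, containing
    ~86.5% of events.
    """
    return AREA_CONTAINMENT_FACTOR * (sigma_c**2 + sigma_loc**2)


def sigma_for_cluster_area(area: float, sigma_loc: float) -> float:
    """Molecular spread sigma_c (nm) whose event footprint has ``area`` nm^2."""
    var = area / AREA_CONTAINMENT_FACTOR - sigma_loc**2
    if var <= 0:
        raise ValueError(
            f"target area {area} nm^2 is below the localization-noise floor "
            f"({AREA_CONTAINMENT_FACTOR * sigma_loc**2:.0f} nm^2 at sigma_loc={sigma_loc} nm)"
        )
    return float(np.sqrt(var))


def matched_density_regime(
    target_median_area: float,
    sigma_loc: float = 20.0,
    molecules_per_nm2: float = 1.0 / 375.0,
    total_cluster_molecules: float = 400.0,
    n_background_molecules: int = 150,
) -> dict:
    """simulate_smlm keyword arguments for a given true median cluster area.

    Regimes built this way hold the *within-cluster* molecule surface
    density constant (molecules per cluster proportional to cluster area)
    and adjust the number of clusters so the total molecule budget -- and
    hence the overall event density -- is matched across regimes.  This is
    how receptor nanoclusters of different sizes coexist at similar
    packing density, and it keeps cluster detectability comparable when
    contrasting a small-cluster and a large-cluster condition.
    """
    sigma_c = sigma_for_cluster_area(target_median_area, sigma_loc)
    mol = molecules_per_nm2 * target_median_area
    n_clusters = max(3, int(round(total_cluster_molecules / mol)))
    return {
        "n_clusters": n_clusters,
        "mean_molecules_per_cluster": mol,
        "sigma_c": sigma_c,
        "sigma_loc": sigma_loc,
        "n_background_molecules": n_background_molecules,
    }


@dataclass
class SMLMTruth:
    """Latent geometry and parameters behind a simulated localization table."""

    cluster_centers: np.ndarray  # (k, 2) nm
    cluster_sigmas: np.ndarray  # (k,) nm, molecular spread per cluster
    molecules_per_cluster: np.ndarray  # (k,) realized counts
    n_background_molecules: int
    mean_redetections: float
    sigma_loc: float
    window: RegionOfInterest
    seed: object
    event_cluster_id: np.ndarray = field(default=None)  # -1 = background

    @property
    def expected_events(self) -> float:
        """Expected event count given the realized molecule numbers."""
        n_mol = self.molecules_per_cluster.sum() + self.n_background_molecules
        return float(n_mol * self.mean_redetections)

    @property
    def cluster_areas(self) -> np.ndarray:
        """True equivalent-circle event-footprint areas (nm^2) per cluster."""
        return np.array(
            [cluster_event_area(s, self.sigma_loc) for s in self.cluster_sigmas]
        )


def _sample_centers(rng, n, window, margin, min_separation, max_tries=10000):
    centers = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        cand = np.array(
            [
                window.x0 + margin + rng.random() * (window.width - 2 * margin),
                window.y0 + margin + rng.random() * (window.height - 2 * margin),
            ]
        )
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise ValueError(
            f"window too small: placed {len(centers)}/{n} clusters at "
            f"min separation {min_separation} nm"
        )
    return np.array(centers)


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mirror coordinates back into [lo, hi) (localization jitter at borders)."""
    span = hi - lo
    v = np.mod(values - lo, 2 * span)
    v = np.where(v >= span, 2 * span - v, v)
    return lo + np.clip(v, 0.0, span * (1 - 1e-12))


def simulate_smlm(
    window: RegionOfInterest | None = None,
    n_clusters: int = 20,
    mean_molecules_per_cluster: float = 25.0,
    sigma_c: float = 20.0,
    sigma_c_spread: float = 0.0,
    n_background_molecules: int = 150,
    mean_redetections: float = 2.0,
    sigma_loc: float = 20.0,
    margin: float = 200.0,
    min_separation: float = 400.0,
    seed=None,
) -> tuple:
    """Simulate a clustered localization table with known truth.

    Molecules are drawn from ``n_clusters`` isotropic Gaussians of spread
    ``sigma_c`` (optionally log-normally scattered across clusters with
    log-sd ``sigma_c_spread``; the median stays ``sigma_c``) plus a uniform
    background.  Each molecule emits Geometric(mean ``mean_redetections``)
    blink events, each jittered by N(0, sigma_loc^2) and mirrored at the
    window border so the event count is preserved.  Frames are a random
    permutation of 0..n-1.

    Returns ``(LocalizationTable, SMLMTruth)``.
    """
    window = window if window is not None else RegionOfInterest(0.0, 0.0)
    if sigma_loc < 0 or sigma_c < 0 or mean_redetections < 1:
        raise ValueError("sigma_c, sigma_loc must be >= 0 and mean_redetections >= 1")
    rng = np.random.default_rng(seed)
    centers = (
        _sample_centers(rng, n_clusters, window, margin, min_separation)
        if n_clusters
        else np.empty((0, 2))
    )
    if sigma_c_spread > 0:
        sigmas = sigma_c * np.exp(rng.normal(0.0, sigma_c_spread, n_clusters))
    else:
        sigmas = np.full(n_clusters, float(sigma_c))

    mol_pos, mol_cluster = [], []
    n_per = rng.poisson(mean_molecules_per_cluster, n_clusters)
    for k in range(n_clusters):
        mol_pos.append(centers[k] + rng.normal(0.0, sigmas[k], (n_per[k], 2)))
        mol_cluster.append(np.full(n_per[k], k))
    bg = np.column_stack(
        (
            window.x0 + rng.random(n_background_molecules) * window.width,
            window.y0 + rng.random(n_background_molecules) * window.height,
        )
    )
    mol_pos.append(bg)
    mol_cluster.append(np.full(n_background_molecules, -1))
    mol_pos = np.concatenate(mol_pos) if mol_pos else np.empty((0, 2))
    mol_cluster = np.concatenate(mol_cluster).astype(int)

    # Geometric re-detections (support >= 1, mean = mean_redetections)
    p = 1.0 / mean_redetections
    blinks = rng.geometric(p, len(mol_pos))
    ev_pos = np.repeat(mol_pos, blinks, axis=0)
    ev_cluster = np.repeat(mol_cluster, blinks)
    ev_pos = ev_pos + rng.normal(0.0, sigma_loc, ev_pos.shape)
    x = _reflect(ev_pos[:, 0], window.x0, window.x0 + window.width)
    y = _reflect(ev_pos[:, 1], window.y0, window.y0 + window.height)
    frames = rng.permutation(len(x))

    table = LocalizationTable.from_arrays(x, y, frame=frames)
    truth = SMLMTruth(
        cluster_centers=centers,
        cluster_sigmas=sigmas,
        molecules_per_cluster=n_per,
        n_background_molecules=n_background_molecules,
        mean_redetections=float(mean_redetections),
        sigma_loc=float(sigma_loc),
        window=window,
        seed=seed,
        event_cluster_id=ev_cluster,
    )
    return table, truth


def make_cell_mask(
    shape: tuple = (256, 256),
    axes: tuple = (2200.0, 1800.0),
    center: tuple | None = None,
    pixel_size: float = 20.0,
    roughness: float = 0.0,
    seed=None,
) -> CellMask:
    """Filled-ellipse cell mask with optional low-order boundary roughness.

    ``axes`` are the semi-axes in nm.  Roughness perturbs the boundary
    radius by a smooth random factor of relative amplitude ``roughness``
    (keep << 1 so the mask stays a single simply-connected component).
    """
    ax, ay = axes
    if not (ax > 0 and ay > 0):
        raise ValueError("ellipse semi-axes must be positive")
    ny, nx = shape
    if center is None:
        center = (nx * pixel_size / 2.0, ny * pixel_size / 2.0)
    ys = (np.arange(ny) + 0.5) * pixel_size
    xs = (np.arange(nx) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    u = (gx - center[0]) / ax
    v = (gy - center[1]) / ay
    rho = np.sqrt(u**2 + v**2)
    limit = np.ones_like(rho)
    if roughness > 0:
        rng = np.random.default_rng(seed)
        theta = np.arctan2(v, u)
        for k in (2, 3, 5):
            amp = roughness * rng.uniform(0.3, 1.0) / 3
            phase = rng.uniform(0, 2 * np.pi)
            limit += amp * np.cos(k * theta + phase)
    return CellMask(rho <= limit, pixel_size)


@dataclass
class TwoChannelTruth:
    """Latent spot geometry behind a simulated two-channel image pair."""

    centers_a: np.ndarray  # (m, 2) nm
    centers_b: np.ndarray  # (m, 2) nm
    radii_a: np.ndarray  # nm
    radii_b: np.ndarray  # nm
    amplitudes_a: np.ndarray
    amplitudes_b: np.ndarray
    offset: float  # configured centroid offset magnitude, nm
    psf_fwhm: float
    pixel_size: float
    seed: object


def _render_discs(shape, centers, radii, amps, pixel_size):
    ny, nx = shape
    img = np.zeros(shape)
    ys = (np.arange(ny) + 0.5) * pixel_size
    xs = (np.arange(nx) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    for (cx, cy), r, a in zip(centers, radii, amps):
        img += a * ((gx - cx) ** 2 + (gy - cy) ** 2 <= r**2)
    return img


def simulate_two_channel(
    mask: CellMask | None = None,
    n_spots: int = 12,
    spot_radius: float = 60.0,
    offset: float = 0.0,
    amplitude: float = 80.0,
    amplitude_ratio_b: float = 1.0,
    background: float = 2.0,
    psf_fwhm: float = 80.0,
    pixel_size: float = 20.0,
    poisson_noise: bool = True,
    min_separation: float = 500.0,
    seed=None,
) -> tuple:
    """Simulate a paired two-channel image of nanocluster spots.

    Channel-A discs are placed inside the mask (eroded by a safety
    margin); each channel-B disc sits at distance ``offset`` from its
    partner in a random direction.  Discs are blurred with a Gaussian PSF
    of the given FWHM, a constant background is added, and Poisson noise
    applied.  Returns ``(PixelImage A, PixelImage B, CellMask, TwoChannelTruth)``.
    """
    if mask is None:
        mask = make_cell_mask(pixel_size=pixel_size, seed=seed)
    if mask.pixel_size != pixel_size:
        raise ValueError("mask pixel size must match pixel_size")
    rng = np.random.default_rng(seed)
    ny, nx = mask.shape
    margin = spot_radius + offset + psf_fwhm

    # sample spot centres uniformly over mask pixels a margin away from the edge
    from scipy.ndimage import binary_erosion

    erode_px = max(1, int(np.ceil(margin / pixel_size)))
    core = binary_erosion(mask.mask, iterations=erode_px)
    if not core.any():
        raise ValueError("mask too small for the requested spots/offset")
    cand = np.argwhere(core)

    centers_a = []
    for _ in range(20000):
        if len(centers_a) == n_spots:
            break
        iy, ix = cand[rng.integers(len(cand))]
        c = np.array([(ix + 0.5) * pixel_size, (iy + 0.5) * pixel_size])
        if all(np.linalg.norm(c - p) >= min_separation for p in centers_a):
            centers_a.append(c)
    if len(centers_a) < n_spots:
        raise ValueError("could not place all spots inside the mask; reduce n_spots")
    centers_a = np.array(centers_a)
    theta = rng.uniform(0, 2 * np.pi, n_spots)
    centers_b = centers_a + offset * np.column_stack((np.cos(theta), np.sin(theta)))

    radii_a = np.full(n_spots, float(spot_radius))
    radii_b = radii_a.copy()
    # channel B inherits the per-spot brightness of its channel-A partner
    # (scaled), as for two stains of the same structure
    amps_a = amplitude * rng.uniform(0.7, 1.3, n_spots)
    amps_b = amps_a * amplitude_ratio_b

    sigma_px = psf_fwhm / 2.3548 / pixel_size
    imgs = []
    for centers, radii, amps in ((centers_a, radii_a, amps_a), (centers_b, radii_b, amps_b)):
        raw = _render_discs(mask.shape, centers, radii, amps, pixel_size)
        blurred = gaussian_filter(raw, sigma_px) + background
        blurred *= mask.mask
        if poisson_noise:
            blurred = rng.poisson(blurred).astype(float)
        imgs.append(PixelImage(blurred, pixel_size))

    truth = TwoChannelTruth(
        centers_a=centers_a,
        centers_b=centers_b,
        radii_a=radii_a,
        radii_b=radii_b,
        amplitudes_a=amps_a,
        amplitudes_b=amps_b,
        offset=float(offset),
        psf_fwhm=float(psf_fwhm),
        pixel_size=float(pixel_size),
        seed=seed,
    )
    return imgs[0], imgs[1], mask, truth
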