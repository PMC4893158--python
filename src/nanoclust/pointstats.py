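"""Second-order point-pattern statistics for localization data.

Implements the global Ripley K / L(r) - r analysis, Monte-Carlo envelopes
under complete spatial randomness (CSR), and the Getis-Franklin per-event
local L(r) statistic that the cluster maps are built from.

Edge correction is Ripley's isotropic correction for a rectangular window:
each pair (i, j) at distance d is weighted by the reciprocal of the
fraction of the circle of radius d centred at i that lies inside the
window, so pairs near the border are up-weighted to compensate for
unobserved neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import LocalizationTable, RegionOfInterest

__all__ = [
    "InsufficientDataError",
    "RipleyCurve",
    "CSREnvelope",
    "LocalLValues",
    "ripley_k",
    "csr_envelope",
    "local_l",
    "isotropic_weights",
]


class InsufficientDataError(ValueError):
    """Raised when a pattern has too few events for the requested statistic."""


@dataclass
class RipleyCurve:
    """Edge-corrected Ripley K and derived L(r) - r over a set of radii."""

    radii: np.ndarray  # nm
    K: np.ndarray  # nm^2
    n_events: int
    window_area: float  # nm^2

    @property
    def L(self) -> np.ndarray:
        """Variance-stabilized L(r) = sqrt(K(r) / pi), in nm."""
        return np.sqrt(self.K / np.pi)

    @property
    def L_minus_r(self) -> np.ndarray:
        """L(r) - r; ~0 under CSR, > 0 indicates clustering at scale r."""
        return self.L - self.radii

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.radii, "K": self.K, "L": self.L, "L_minus_r": self.L_minus_r}
        )


@dataclass
class CSREnvelope:
    """Pointwise Monte-Carlo envelope of L(r) - r under matched-n CSR."""

    radii: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sim: int
    alpha: float

    def covers(self, curve: RipleyCurve) -> np.ndarray:
        """Per-radius indicator that the curve lies inside the envelope."""
        lmr = curve.L_minus_r
        return (lmr >= self.lower) & (lmr <= self.upper)


@dataclass
class LocalLValues:
    """Per-event Getis-Franklin local L(r0) values, in nm."""

    values: np.ndarray
    r0: float

    def __len__(self) -> int:
        return len(self.values)


def isotropic_weights(centers: np.ndarray, d: np.ndarray, window: RegionOfInterest) -> np.ndarray:
    """Ripley isotropic edge-correction weights for a rectangular window.

    ``centers`` is (m, 2) circle centres (nm), ``d`` the corresponding
    radii.  Returns 1 / (fraction of each circle inside the window).
    Assumes d <= min(window side) / 2, which guarantees a circle can cross
    at most two adjacent borders.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = np.asarray(d, dtype=float)
    dl = centers[:, 0] - window.x0
    dr = window.x0 + window.width - centers[:, 0]
    db = centers[:, 1] - window.y0
    dt = window.y0 + window.height - centers[:, 1]

    with np.errstate(invalid="ignore", divide="ignore"):
        exterior = np.zeros_like(d)
        edge_dists = (dl, dr, db, dt)
        for de in edge_dists:
            ratio = np.clip(de / d, -1.0, 1.0)
            exterior += np.where(de < d, 2.0 * np.arccos(ratio), 0.0)
        # circles poking past a corner have the two edge arcs overlapping
        for d1, d2 in ((dl, db), (dl, dt), (dr, db), (dr, dt)):
            inside_corner = d1**2 + d2**2 < d**2
            r1 = np.clip(d1 / d, -1.0, 1.0)
            r2 = np.clip(d2 / d, -1.0, 1.0)
            overlap = np.pi / 2 - np.arcsin(r1) - np.arcsin(r2)
            exterior -= np.where(inside_corner, overlap, 0.0)
    frac_inside = 1.0 - exterior / (2.0 * np.pi)
    return 1.0 / frac_inside


def _check_window(points: np.ndarray, window: RegionOfInterest) -> None:
    if points.size and not np.all(window.contains(points[:, 0], points[:, 1])):
        raise ValueError("all events must lie inside the analysis window")


def ripley_k(
    points: LocalizationTable | np.ndarray,
    radii,
    window: RegionOfInterest,
) -> RipleyCurve:
    """Edge-corrected Ripley K-hat over ``radii``.

    K-hat(r) = A / (n (n-1)) * sum_i sum_{j != i} e_ij 1(d_ij <= r), with
    isotropic edge weights e_ij.  Requires n >= 2 events and
    max(radii) <= min(window side) / 2.
    """
    xy = points.xy if isinstance(points, LocalizationTable) else np.asarray(points, float)
    radii = np.asarray(radii, dtype=float)
    n = len(xy)
    if n < 2:
        raise InsufficientDataError("Ripley's K requires at least 2 events")
    if radii.ndim != 1 or len(radii) == 0 or np.any(radii <= 0):
        raise ValueError("radii must be a non-empty list of positive values")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly ascending")
    rmax = float(radii[-1])
    if rmax > min(window.width, window.height) / 2:
        raise ValueError("max radius must not exceed half the shorter window side")
    _check_window(xy, window)

    tree = cKDTree(xy)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        # both orientations of the unordered pair: circle centred at i and at j
        w = isotropic_weights(xy[pairs[:, 0]], d, window) + isotropic_weights(
            xy[pairs[:, 1]], d, window
        )
        order = np.argsort(d)
        d, w = d[order], w[order]
        csum = np.concatenate(([0.0], np.cumsum(w)))
        counts = csum[np.searchsorted(d, radii, side="right")]
    else:
        counts = np.zeros_like(radii)
    K = window.area / (n * (n - 1)) * counts
    return RipleyCurve(radii=radii, K=K, n_events=n, window_area=window.area)


def csr_envelope(
    n_events: int,
    window: RegionOfInterest,
    radii,
    n_sim: int = 199,
    alpha: float = 0.01,
    seed=None,
) -> CSREnvelope:
    """Pointwise (1 - alpha) envelope of L(r) - r from CSR simulations.

    Simulates ``n_sim`` uniform patterns of exactly ``n_events`` points in
    the window and takes the alpha/2 and 1 - alpha/2 pointwise quantiles.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    # the "99 simulations for a 99% envelope" convention: need at least
    # ceil(1/alpha) - 1 patterns for the tail quantiles to be estimable
    min_sim = int(np.ceil(1.0 / alpha)) - 1
    if n_sim < min_sim:
        raise ValueError(f"n_sim={n_sim} too small for alpha={alpha}; need >= {min_sim}")
    radii = np.asarray(radii, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(radii)))
    for s in range(n_sim):
        pts = np.column_stack(
            (
                window.x0 + rng.random(n_events) * window.width,
                window.y0 + rng.random(n_events) * window.height,
            )
        )
        sims[s] = ripley_k(pts, radii, window).L_minus_r
    lower = np.quantile(sims, alpha / 2, axis=0)
    upper = np.quantile(sims, 1 - alpha / 2, axis=0)
    return CSREnvelope(radii=radii, lower=lower, upper=upper, n_sim=n_sim, alpha=alpha)


def local_l(
    points: LocalizationTable | np.ndarray,
    r0: float = 30.0,
    window: RegionOfInterest | None = None,
) -> LocalLValues:
    """Getis-Franklin local L_i(r0) for every event.

    L_i(r0) = sqrt( A * sum_{j != i} e_ij 1(d_ij <= r0) / (pi (n - 1)) ).
    Under CSR, E[L_i] ~= r0; events with no neighbour within r0 get 0.
    The (n - 1) divisor excludes the self-pair.
    """
    xy = points.xy if isinstance(points, LocalizationTable) else np.asarray(points, float)
    n = len(xy)
    if n < 2:
        raise InsufficientDataError("local L requires at least 2 events")
    if not r0 > 0:
        raise ValueError("r0 must be positive")
    if window is None:
        raise ValueError("an analysis window is required for edge correction")
    _check_window(xy, window)

    tree = cKDTree(xy)
    pairs = tree.query_pairs(r0, output_type="ndarray")
    counts = np.zeros(n)
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        wi = isotropic_weights(xy[pairs[:, 0]], d, window)
        wj = isotropic_weights(xy[pairs[:, 1]], d, window)
        np.add.at(counts, pairs[:, 0], wi)
        np.add.at(counts, pairs[:, 1], wj)
    values = np.sqrt(window.area * counts / (np.pi * (n - 1)))
    return LocalLValues(values=values, r0=float(r0))
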