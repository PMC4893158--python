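"""End-to-end per-cell analyses tying the modules together.

``analyze_gsd_cell`` runs the SMLM workflow (threshold calibration ->
cluster map -> binarization -> cluster statistics) over a set of 3 x 3 um
ROIs and aggregates per cell; ``analyze_sted_cell`` runs the two-channel
image workflow (binarization, Costes-Pearson, centroid distances, the
tertile association screen and its randomization null).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AssociationConfig,
    assign_tertiles,
    randomize_null,
    screen_association,
    size_effect_summary,
)
from .clustermap import (
    binarize_and_label,
    build_cluster_map,
    calibrate_threshold,
    summarize_clusters,
)
from .coloc import binarize_image_clusters, centroid_distances, pearson_costes
from .io_formats import CellMask, LocalizationTable, PixelImage, RegionOfInterest, crop_region

logger = logging.getLogger("nanoclust")

__all__ = ["AnalysisConfig", "GsdCellResult", "StedCellResult", "analyze_gsd_cell", "analyze_sted_cell", "auto_rois"]


@dataclass
class AnalysisConfig:
    """All tunable parameters of the per-cell analyses (full provenance)."""

    r0: float = 30.0  # Getis-Franklin search radius, nm
    grid_step: float = 10.0  # cluster-map pixel size, nm
    map_method: str = "grid"  # "grid" or "interpolate" cluster maps
    threshold_quantile: float = 0.995
    threshold_n_sim: int = 50
    min_area: float = 1000.0  # nm^2; suppresses chance CSR exceedance blobs
    size_bin_edges: tuple = (5000.0, 15000.0)  # nm^2
    roi_size: float = 3000.0  # nm
    search_radius: float = 500.0  # association screen, nm
    n_null_reps: int = 100
    association_mode: str = "edge"
    sted_binarization: str = "otsu"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_bin_edges"] = list(self.size_bin_edges)
        d["version"] = __version__
        return d

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("version", None)
        if "size_bin_edges" in d:
            d["size_bin_edges"] = tuple(d["size_bin_edges"])
        return cls(**d)

    def association_config(self) -> AssociationConfig:
        return AssociationConfig(
            search_radius=self.search_radius,
            n_null_reps=self.n_null_reps,
            seed=self.seed,
            mode=self.association_mode,
        )


@dataclass
class GsdCellResult:
    """Per-ROI cluster statistics plus the per-cell mean over ROIs."""

    roi_stats: list  # (RegionOfInterest, ClusterStats) pairs
    per_cell: dict  # mean over ROIs of each scalar statistic
    config: AnalysisConfig

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "rois": [
                {"roi": roi.to_dict(), "stats": st.to_dict()} for roi, st in self.roi_stats
            ],
            "per_cell": self.per_cell,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


_SCALARS = (
    "median_area",
    "median_area_event",
    "mean_area",
    "clusters_per_um2",
    "percent_events_in_clusters",
    "relative_density",
    "event_density",
)


def analyze_gsd_cell(
    table: LocalizationTable,
    rois: list,
    cfg: AnalysisConfig | None = None,
) -> GsdCellResult:
    """Full SMLM cluster quantification of one cell over its ROIs.

    For each ROI: crop, calibrate the L(r0) threshold at the ROI's own
    event density, build the cluster map, binarize, summarize.  ROIs with
    fewer than 2 events are skipped with a warning.  The per-cell value of
    each scalar statistic is the mean over analysed ROIs; the
    (density, mean cluster area) pairs per ROI are retained for
    cross-correlation plots.
    """
    cfg = cfg or AnalysisConfig()
    roi_stats = []
    for i, roi in enumerate(rois):
        local = crop_region(table, roi)
        local_roi = RegionOfInterest(0.0, 0.0, roi.width, roi.height)
        if len(local) < 2:
            logger.warning("ROI %d has %d events (<2); skipped", i, len(local))
            continue
        density = len(local) / local_roi.area_um2
        calib = calibrate_threshold(
            density,
            local_roi,
            r0=cfg.r0,
            grid_step=cfg.grid_step,
            n_sim=cfg.threshold_n_sim,
            quantile=cfg.threshold_quantile,
            seed=cfg.seed + i,
            method=cfg.map_method,
        )
        cmap = build_cluster_map(
            local, local_roi, r0=cfg.r0, grid_step=cfg.grid_step, method=cfg.map_method
        )
        clusters = binarize_and_label(cmap, calib, points=local, min_area=cfg.min_area)
        stats = summarize_clusters(clusters, local, local_roi, size_bin_edges=cfg.size_bin_edges)
        roi_stats.append((roi, stats))

    if not roi_stats:
        raise ValueError("no ROI contained >= 2 events")
    per_cell = {}
    for name in _SCALARS:
        vals = [getattr(st, name) for _, st in roi_stats if getattr(st, name) is not None]
        per_cell[name] = float(np.mean(vals)) if vals else None
    return GsdCellResult(roi_stats=roi_stats, per_cell=per_cell, config=cfg)


def auto_rois(
    table: LocalizationTable,
    field_width: float,
    field_height: float,
    roi_size: float = 3000.0,
    n_rois: int = 4,
) -> list:
    """Automatic ROI pick: the ``n_rois`` non-overlapping highest-density tiles.

    The field is tiled with roi_size x roi_size squares; tiles are ranked
    by event count.  Flagged for outputs since manual ROI selection is the
    reference behaviour.
    """
    nx = int(field_width // roi_size)
    ny = int(field_height // roi_size)
    if nx == 0 or ny == 0:
        raise ValueError("field smaller than one ROI")
    counts = []
    for iy in range(ny):
        for ix in range(nx):
            roi = RegionOfInterest(ix * roi_size, iy * roi_size, roi_size, roi_size)
            counts.append((int(roi.contains(table.x, table.y).sum()), roi))
    counts.sort(key=lambda t: -t[0])
    return [roi for _, roi in counts[:n_rois]]


@dataclass
class StedCellResult:
    """Two-channel workflow output for one cell."""

    coloc: object  # ColocResult
    clusters_a: list
    clusters_b: list
    centroid_dist: object  # CentroidDistances
    size_bins: object  # SizeBins
    observed: object  # AssociationResult
    null: object  # NullDistribution
    summary: pd.DataFrame
    config: AnalysisConfig

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "pearson_r": self.coloc.pearson_r,
            "costes_thresholds": [self.coloc.costes_threshold_a, self.coloc.costes_threshold_b],
            "n_clusters_a": len(self.clusters_a),
            "n_clusters_b": len(self.clusters_b),
            "median_centroid_distance_nm": self.centroid_dist.median,
            "observed": self.observed.to_dict(),
            "null_mean_tertile_fractions": self.null.mean_tertile_fractions,
            "null_mean_association_rates": self.null.mean_association_rate_by_tertile,
            "size_effect": self.summary.reset_index().to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def analyze_sted_cell(
    imgA: PixelImage,
    imgB: PixelImage,
    mask: CellMask,
    cfg: AnalysisConfig | None = None,
) -> StedCellResult:
    """Two-channel co-localization and association analysis of one cell.

    Channel A is the receptor channel, channel B the signaling channel.
    Stages: binarize both channels -> Costes-Pearson -> nearest-centroid
    distances -> area tertiles on channel-A clusters -> association
    screen -> randomization null -> size-effect summary.
    """
    cfg = cfg or AnalysisConfig()
    try:
        coloc = pearson_costes(imgA, imgB, mask)
    except ValueError as err:
        raise ValueError(f"pearson_costes: {err}") from err
    clusters_a = binarize_image_clusters(imgA, mask, method=cfg.sted_binarization)
    clusters_b = binarize_image_clusters(imgB, mask, method=cfg.sted_binarization)
    if not clusters_a:
        raise ValueError("binarize_image_clusters: no receptor (channel A) clusters found")
    try:
        cd = centroid_distances(clusters_a, clusters_b)
    except ValueError as err:
        raise ValueError(f"centroid_distances: {err}") from err
    acfg = cfg.association_config()
    bins, labels = assign_tertiles(clusters_a)
    observed = screen_association(clusters_a, clusters_b, imgB, acfg, tertile_labels=labels)
    null = randomize_null(clusters_b, imgB, mask, clusters_a, acfg, tertile_labels=labels)
    summary = size_effect_summary(observed, null)
    return StedCellResult(
        coloc=coloc,
        clusters_a=clusters_a,
        clusters_b=clusters_b,
        centroid_dist=cd,
        size_bins=bins,
        observed=observed,
        null=null,
        summary=summary,
        config=cfg,
    )
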