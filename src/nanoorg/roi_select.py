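"""Synapse ROI detection, import, and DBSCAN denoising.

Synapses are regions where the scaffold channel (gephyrin) forms a dense
localization cluster that overlaps the receptor channel and a presynaptic
VGAT mask, with a circle-equivalent diameter of roughly 100-800 nm.  In the
original workflow such regions are picked by hand; :func:`detect_candidates`
is an explicit automated surrogate (kernel-density maxima flood-grown to a
density floor) and :func:`import_rois` supports externally drawn polygons as
a first-class alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .cluster import dbscan_labels
from .exceptions import GeometryError, ParameterError
from .geometry import (DEFAULT_ALPHA_NM, alpha_shape, circle_equivalent_diameter,
                       points_in_polygon)
from .locio import LocalizationTable


@dataclass(frozen=True)
class DbscanParams:
    """DBSCAN denoising parameters for one channel (nm, counts)."""
    epsilon: float
    min_points: int

    def __post_init__(self):
        if self.epsilon <= 0 or self.min_points < 1:
            raise ParameterError("epsilon must be > 0 and min_points >= 1")


#: published denoising parameters for the two channels
RECEPTOR_DBSCAN = DbscanParams(epsilon=40.0, min_points=5)
SCAFFOLD_DBSCAN = DbscanParams(epsilon=30.0, min_points=5)


@dataclass
class SynapseROI:
    """A selected synapse region with its per-channel localization subsets."""

    roi_id: int
    polygon: Polygon
    locs_receptor: LocalizationTable
    locs_scaffold: LocalizationTable
    vgat_overlap: bool | None = None
    effective_diameter: float = float("nan")
    denoise_counts: dict = field(default_factory=dict)

    @property
    def n_locs(self) -> int:
        return len(self.locs_receptor) + len(self.locs_scaffold)

    def channel(self, which: str) -> LocalizationTable:
        if which == "receptor":
            return self.locs_receptor
        if which == "scaffold":
            return self.locs_scaffold
        raise ParameterError(f"unknown channel {which!r}")


@dataclass
class SelectionConfig:
    """Automated candidate-selection settings.

    The kernel-density surrogate bins the scaffold channel on a
    ``bin_size``-nm grid, smooths with a Gaussian of ``smooth_sigma`` nm, and
    flood-labels bins whose density exceeds ``density_floor`` (locs/nm^2).
    Candidate regions must contain >= ``min_scaffold_locs`` scaffold
    localizations, have a circle-equivalent diameter in ``[dmin, dmax]``,
    carry a receptor overlap fraction >= ``min_overlap_fraction`` (receptor
    localizations inside the scaffold footprint, relative to those within
    ``neighborhood_buffer`` nm of it), and — when ``require_vgat`` — overlap
    the VGAT mask (pixel size ``pixel_size_nm``).
    """

    pixel_size_nm: float = 100.0
    bin_size: float = 20.0
    smooth_sigma: float = 30.0
    density_floor: float = 5e-4
    min_scaffold_locs: int = 25
    min_receptor_locs: int = 10
    min_overlap_fraction: float = 0.5
    neighborhood_buffer: float = 100.0
    require_vgat: bool = True
    dmin: float = 100.0
    dmax: float = 800.0
    alpha_radius: float = DEFAULT_ALPHA_NM


def detect_candidates(receptor: LocalizationTable, scaffold: LocalizationTable,
                      vgat_mask: np.ndarray | None = None,
                      cfg: SelectionConfig | None = None) -> list[SynapseROI]:
    """Automated synapse-candidate detection (surrogate for manual picking).

    Returns ROIs sorted by descending total localization count, each
    satisfying the scaffold-cluster, receptor-overlap, VGAT-overlap and
    diameter criteria of ``cfg``.
    """
    cfg = cfg or SelectionConfig()
    if len(receptor) == 0 and len(scaffold) == 0:
        return []
    extent = (max(receptor.field_extent[0], scaffold.field_extent[0]),
              max(receptor.field_extent[1], scaffold.field_extent[1]))
    if vgat_mask is not None:
        mask_w = vgat_mask.shape[1] * cfg.pixel_size_nm
        mask_h = vgat_mask.shape[0] * cfg.pixel_size_nm
        if mask_w < extent[0] - cfg.pixel_size_nm or mask_h < extent[1] - cfg.pixel_size_nm:
            raise GeometryError("VGAT mask does not cover the localization field")
    if len(scaffold) == 0:
        return []

    sxy = scaffold.xy
    rxy = receptor.xy
    nx = max(int(np.ceil(extent[0] / cfg.bin_size)), 1)
    ny = max(int(np.ceil(extent[1] / cfg.bin_size)), 1)
    ix = np.clip((sxy[:, 0] / cfg.bin_size).astype(int), 0, nx - 1)
    iy = np.clip((sxy[:, 1] / cfg.bin_size).astype(int), 0, ny - 1)
    hist = np.zeros((ny, nx))
    np.add.at(hist, (iy, ix), 1.0)
    density = ndimage.gaussian_filter(hist, cfg.smooth_sigma / cfg.bin_size)
    density /= cfg.bin_size ** 2

    labels, n_comp = ndimage.label(density >= cfg.density_floor,
                                   structure=np.ones((3, 3), dtype=int))
    rois: list[SynapseROI] = []
    for comp in range(1, n_comp + 1):
        member = labels[iy, ix] == comp
        if member.sum() < cfg.min_scaffold_locs:
            continue
        shape = alpha_shape(sxy[member], cfg.alpha_radius)
        if shape.area <= 0:
            continue
        diameter = circle_equivalent_diameter(shape.area)
        if not (cfg.dmin <= diameter <= cfg.dmax):
            continue
        poly = shape.polygon
        r_in = points_in_polygon(poly, rxy)
        n_in = int(r_in.sum())
        if n_in < cfg.min_receptor_locs:
            continue
        n_near = int(points_in_polygon(poly.buffer(cfg.neighborhood_buffer), rxy).sum())
        if n_in / max(n_near, 1) < cfg.min_overlap_fraction:
            continue
        vgat = None
        if vgat_mask is not None:
            vgat = _polygon_touches_mask(poly, vgat_mask, cfg.pixel_size_nm)
            if cfg.require_vgat and not vgat:
                continue
        s_in = points_in_polygon(poly, sxy)
        rois.append(SynapseROI(
            roi_id=-1, polygon=poly,
            locs_receptor=receptor.subset(r_in),
            locs_scaffold=scaffold.subset(s_in),
            vgat_overlap=vgat, effective_diameter=diameter))

    rois.sort(key=lambda r: -r.n_locs)
    for i, roi in enumerate(rois):
        roi.roi_id = i
    return rois


def _polygon_touches_mask(poly: Polygon, mask: np.ndarray, pixel_size: float) -> bool:
    """True if any foreground pixel's centre lies inside (or on) the polygon."""
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(minx / pixel_size) - 1, 0)
    c1 = min(int(maxx / pixel_size) + 2, mask.shape[1])
    r0 = max(int(miny / pixel_size) - 1, 0)
    r1 = min(int(maxy / pixel_size) + 2, mask.shape[0])
    sub = np.asarray(mask[r0:r1, c0:c1]) != 0
    if not sub.any():
        return False
    rr, cc = np.nonzero(sub)
    centers = np.column_stack([(cc + c0 + 0.5) * pixel_size,
                               (rr + r0 + 0.5) * pixel_size])
    return bool(points_in_polygon(poly, centers).any())


def import_rois(path: str | Path, receptor: LocalizationTable,
                scaffold: LocalizationTable) -> list[SynapseROI]:
    """Load externally drawn ROI polygons (JSON, coordinates in nm).

    The file holds either a GeoJSON-style ``FeatureCollection`` of polygons
    or ``{"rois": [{"coordinates_nm": [[x, y], ...]}, ...]}``.  Localizations
    are assigned by a boundary-inclusive point-in-polygon test.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "features" in doc:
        rings = [f["geometry"]["coordinates"][0] for f in doc["features"]]
    else:
        rings = [r["coordinates_nm"] for r in doc["rois"]]
    rois = []
    for i, ring in enumerate(rings):
        poly = Polygon(ring)
        if not poly.is_valid:
            raise GeometryError(f"ROI {i}: invalid (self-intersecting?) polygon")
        rois.append(SynapseROI(
            roi_id=i, polygon=poly,
            locs_receptor=receptor.subset(points_in_polygon(poly, receptor.xy)),
            locs_scaffold=scaffold.subset(points_in_polygon(poly, scaffold.xy)),
            effective_diameter=circle_equivalent_diameter(poly.area)))
    return rois


def denoise_dbscan(roi: SynapseROI,
                   receptor_params: DbscanParams = RECEPTOR_DBSCAN,
                   scaffold_params: DbscanParams = SCAFFOLD_DBSCAN) -> SynapseROI:
    """Remove background localizations from both channels of an ROI.

    Each channel is labelled by DBSCAN; noise-labelled localizations are
    dropped and the union of all clusters is retained.  The returned ROI's
    ``denoise_counts`` records kept/removed counts per channel.
    """
    kept = {}
    counts = {}
    for name, params in (("receptor", receptor_params), ("scaffold", scaffold_params)):
        table = roi.channel(name)
        if len(table) == 0:
            kept[name] = table
            counts[name] = {"kept": 0, "removed": 0}
            continue
        labels = dbscan_labels(table.xy, params.epsilon, params.min_points)
        keep = labels >= 0
        kept[name] = table.subset(keep)
        counts[name] = {"kept": int(keep.sum()), "removed": int((~keep).sum())}
    return replace(roi, locs_receptor=kept["receptor"], locs_scaffold=kept["scaffold"],
                   denoise_counts=counts)
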