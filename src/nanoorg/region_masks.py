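"""Binary-mask logic for fixed-imaging experiments.

Implements the confocal-analysis conventions used for immunofluorescence
(IF) and proximity-ligation (PLA) quantification: the synaptic receptor
signal is the binary intersection of the surface-receptor and presynaptic
marker (GAD65/VGAT) thresholds; the extrasynaptic signal is the receptor
threshold minus the once-dilated synaptic threshold; a PLA spot is synaptic
iff any of its pixels overlaps the marker threshold ("Having").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, ParameterError

#: 3x3 cross (4-connected) structuring element used for the pre-subtraction dilation
CROSS = ndimage.generate_binary_structure(2, 1)
#: 8-connectivity structure for cluster counting
EIGHT = np.ones((3, 3), dtype=bool)


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask) != 0


@dataclass
class MaskSet:
    """Co-registered binary rasters: receptor, marker, and the derived
    synaptic / extrasynaptic masks."""

    pixel_size: float
    receptor_mask: np.ndarray
    marker_mask: np.ndarray
    synaptic_mask: np.ndarray
    extrasynaptic_mask: np.ndarray
    dilation_iterations: int = 1


def classify_if_masks(receptor_mask, marker_mask, dilation_iterations: int = 1,
                      structure: np.ndarray = CROSS,
                      pixel_size: float = 1.0) -> MaskSet:
    """Split a surface-receptor mask into synaptic and extrasynaptic parts.

    synaptic = receptor AND marker; extrasynaptic = receptor AND NOT
    dilate(synaptic).  ``dilation_iterations = 0`` skips the dilation, giving
    an exact set difference.
    """
    receptor = _as_bool(receptor_mask)
    marker = _as_bool(marker_mask)
    if receptor.shape != marker.shape:
        raise GeometryError(
            f"mask shapes differ: {receptor.shape} vs {marker.shape}")
    if dilation_iterations < 0:
        raise ParameterError("dilation_iterations must be >= 0")
    synaptic = receptor & marker
    if dilation_iterations > 0:
        dilated = ndimage.binary_dilation(synaptic, structure=structure,
                                          iterations=dilation_iterations)
    else:
        dilated = synaptic
    extrasynaptic = receptor & ~dilated
    return MaskSet(pixel_size, receptor, marker, synaptic, extrasynaptic,
                   dilation_iterations)


def roi_measurements(mask, intensity_image, rois, pixel_size: float = 1.0):
    """Cluster/area/intensity measurements of ``mask`` within each ROI.

    ``rois`` is a list of boolean rasters (same shape as ``mask``), each
    marking one dendritic region of interest.  Per ROI: connected components
    of mask∩ROI (8-connectivity) are counted as clusters; ``binary_area`` is
    foreground pixel count times pixel area; intensities are taken from
    ``intensity_image`` over the foreground pixels (0 when empty).
    """
    mask = _as_bool(mask)
    img = np.asarray(intensity_image, dtype=float)
    if img.shape != mask.shape:
        raise GeometryError("intensity image and mask shapes differ")
    out = []
    for i, roi in enumerate(rois):
        roi = _as_bool(roi)
        if roi.shape != mask.shape:
            raise GeometryError(f"ROI {i} shape differs from image shape")
        fg = mask & roi
        _, n_clusters = ndimage.label(fg, structure=EIGHT)
        vals = img[fg]
        out.append({
            "roi": i,
            "n_clusters": int(n_clusters),
            "binary_area": float(fg.sum()) * pixel_size ** 2,
            "mean_intensity": float(vals.mean()) if len(vals) else 0.0,
            "sum_intensity": float(vals.sum()),
        })
    return out


def band_roi(shape: tuple[int, int], start: tuple[int, int], end: tuple[int, int],
             width_px: int) -> np.ndarray:
    """Rectangular line-band ROI raster between two (row, col) endpoints.

    Pixels within ``width_px / 2`` of the segment are included; endpoints
    must lie inside the image.
    """
    r0, c0 = start
    r1, c1 = end
    for r, c in (start, end):
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise GeometryError("ROI endpoint outside image")
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d = np.array([r1 - r0, c1 - c0], dtype=float)
    length2 = float(d @ d)
    if length2 == 0:
        dist = np.hypot(rr - r0, cc - c0)
    else:
        t = np.clip(((rr - r0) * d[0] + (cc - c0) * d[1]) / length2, 0, 1)
        dist = np.hypot(rr - (r0 + t * d[0]), cc - (c0 + t * d[1]))
    return dist <= width_px / 2.0


def average_cell_rois(measurements: list[dict]) -> dict:
    """Per-cell value: mean over that cell's ROI measurements."""
    if not measurements:
        raise ParameterError("no ROI measurements to average")
    keys = [k for k in measurements[0] if k != "roi"]
    return {k: float(np.mean([m[k] for m in measurements])) for k in keys}


# ---------------------------------------------------------------------------
# PLA spots
# ---------------------------------------------------------------------------

@dataclass
class PLASpot:
    """A detected proximity-ligation spot (pixel coordinates)."""

    center: tuple[float, float]        # (x, y) px
    diameter: float                    # px (typical physical size 0.50 um)
    pixels: np.ndarray = field(default=None)  # (n, 2) array of (row, col)
    synaptic: bool | None = None

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Member pixels of the spot disc, clipped to the image frame."""
        cx, cy = self.center
        r = self.diameter / 2.0
        r0 = max(int(np.floor(cy - r)), 0)
        r1 = min(int(np.ceil(cy + r)) + 1, shape[0])
        c0 = max(int(np.floor(cx - r)), 0)
        c1 = min(int(np.ceil(cx + r)) + 1, shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = (cc + 0.5 - cx) ** 2 + (rr + 0.5 - cy) ** 2 <= r ** 2
        return np.column_stack([rr[inside], cc[inside]])


def classify_pla_spots(spots: list[PLASpot], marker_mask) -> dict:
    """Partition PLA spots into synaptic / extrasynaptic against a marker mask.

    A spot is synaptic iff any of its member pixels overlaps the marker
    ("Having"); the extrasynaptic count is total minus synaptic.  Each spot's
    ``synaptic`` flag is set in place.
    """
    marker = _as_bool(marker_mask)
    n_syn = 0
    for spot in spots:
        pixels = spot.pixels if spot.pixels is not None else spot.rasterize(marker.shape)
        if len(pixels):
            rows = np.clip(pixels[:, 0].astype(int), 0, marker.shape[0] - 1)
            cols = np.clip(pixels[:, 1].astype(int), 0, marker.shape[1] - 1)
            spot.synaptic = bool(marker[rows, cols].any())
        else:
            spot.synaptic = False
        n_syn += spot.synaptic
    return {"n_total": len(spots), "n_synaptic": n_syn,
            "n_extrasynaptic": len(spots) - n_syn}


def read_spots_csv(path) -> list[PLASpot]:
    """Read a PLA spot list from CSV with columns ``x_px,y_px,diameter_px``."""
    import pandas as pd
    df = pd.read_csv(path)
    needed = ["x_px", "y_px", "diameter_px"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        from .exceptions import SchemaError
        raise SchemaError(f"spot list missing column(s): {missing}")
    return [PLASpot(center=(row.x_px, row.y_px), diameter=row.diameter_px)
            for row in df.itertuples()]
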