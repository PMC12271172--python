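"""End-to-end composition: link -> select -> denoise -> metrics.

Thin orchestration over the library modules, producing the tidy per-synapse
and per-SSD tables that the analysis drivers and the acceptance checks
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import locio, nanoscale, roi_select
from .geometry import alpha_shape
from .locio import LocalizationTable
from .nanoscale import SsdConfig, detect_ssds, enrichment_index, synapse_metrics
from .roi_select import (RECEPTOR_DBSCAN, SCAFFOLD_DBSCAN, DbscanParams,
                         SelectionConfig)

CHANNELS = ("receptor", "scaffold")


@dataclass
class PipelineConfig:
    """Settings for :func:`analyze_field`."""

    link_radius: float = 30.0
    link_max_gap: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    receptor_dbscan: DbscanParams = RECEPTOR_DBSCAN
    scaffold_dbscan: DbscanParams = SCAFFOLD_DBSCAN
    ssd: SsdConfig = field(default_factory=SsdConfig)
    enrichment_radius: float = 60.0
    compute_ssds: bool = True
    compute_enrichment: bool = True


def analyze_field(receptor: LocalizationTable, scaffold: LocalizationTable,
                  vgat_mask: np.ndarray | None = None,
                  cfg: PipelineConfig | None = None, seed: int = 0,
                  rois: list | None = None):
    """Run the full localization pipeline on one field of view.

    Links re-blinking duplicates in both channels, detects synapse ROIs
    (unless pre-selected ``rois`` are given), denoises each ROI by DBSCAN,
    measures per-channel synapse metrics, detects SSDs, and computes the
    cross-channel enrichment indices.

    Returns ``(synapse_df, ssd_df, rois)``: one row per (roi, channel) with
    all synapse metrics plus enrichment, and one row per SSD.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    receptor = locio.link_consecutive(receptor, cfg.link_radius, cfg.link_max_gap)
    scaffold = locio.link_consecutive(scaffold, cfg.link_radius, cfg.link_max_gap)
    if rois is None:
        rois = roi_select.detect_candidates(receptor, scaffold, vgat_mask,
                                            cfg.selection)
    rois = [roi_select.denoise_dbscan(r, cfg.receptor_dbscan, cfg.scaffold_dbscan)
            for r in rois]

    syn_rows, ssd_rows = [], []
    for roi in rois:
        shapes, ssds = {}, {}
        for ch in CHANNELS:
            pts = roi.channel(ch).xy
            shapes[ch] = alpha_shape(pts, cfg.ssd.alpha_radius)
            if cfg.compute_ssds and shapes[ch].area > 0 and len(pts):
                ssds[ch] = detect_ssds(pts, shapes[ch], cfg.ssd, rng)
            else:
                ssds[ch] = []
        for ch in CHANNELS:
            if shapes[ch].area <= 0:
                continue
            m = synapse_metrics(roi, ch, ssds[ch], cfg.ssd.alpha_radius)
            row = {"roi_id": roi.roi_id, "channel": ch,
                   "vgat_overlap": roi.vgat_overlap, **vars(m)}
            other = CHANNELS[1 - CHANNELS.index(ch)]
            if (cfg.compute_enrichment and ssds[other]
                    and shapes[ch].area > 0 and len(roi.channel(ch))):
                enr = enrichment_index(roi.channel(ch).xy, ssds[other],
                                       shapes[ch], cfg.enrichment_radius)
                row["enrichment_vs_other"] = enr.enrichment_index
            else:
                row["enrichment_vs_other"] = float("nan")
            syn_rows.append(row)
            for k, s in enumerate(ssds[ch]):
                ssd_rows.append({"roi_id": roi.roi_id, "channel": ch, "ssd_id": k,
                                 "n_locs": s.n_locs, "area": s.area,
                                 "peak_x": s.peak[0], "peak_y": s.peak[1]})
    syn_df = pd.DataFrame(syn_rows)
    ssd_df = pd.DataFrame(ssd_rows)
    return syn_df, ssd_df, rois
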