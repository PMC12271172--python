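"""Calibration and parameter-recovery runs on synthetic ground truth.

These routines quantify how well the pipeline recovers known generative
parameters and how its detectors behave under complete spatial randomness
(CSR).  They are the basis of the validation suite and of the reproduction
script, and are useful for re-calibrating configuration choices against
user-specific imaging conditions.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .geometry import alpha_shape, circle_equivalent_diameter
from .nanoscale import SsdConfig, SubsynapticDomain, detect_ssds, enrichment_index
from .pipeline import PipelineConfig, analyze_field


def recover_preset(preset: str, seed: int, n_synapses: int = 110,
                   field_extent=(21000.0, 21000.0),
                   compute_ssds: bool = False) -> dict:
    """Generate a field at a group preset and re-estimate its parameters.

    Runs the full pipeline (link -> select -> denoise -> alpha-area ->
    metrics) and returns, per channel, the generator-truth and
    pipeline-estimated mean synapse area (nm^2), localization density
    (locs/nm^2) and circle-equivalent diameter (nm), plus the number of
    synapses analysed.
    """
    cfg = synth.config_from_preset(preset, seed=seed, n_synapses=n_synapses,
                                   field_extent=field_extent)
    receptor, scaffold, vgat_mask, truths = synth.generate_field(cfg)
    pipe_cfg = PipelineConfig(compute_ssds=compute_ssds,
                              compute_enrichment=False)
    syn_df, ssd_df, _ = analyze_field(receptor, scaffold, vgat_mask, pipe_cfg,
                                      seed=seed + 1)
    out = {"preset": preset, "n_synapses_detected": int(syn_df["roi_id"].nunique())}
    for ch in ("receptor", "scaffold"):
        sub = syn_df[syn_df["channel"] == ch]
        est_area = float(sub["total_area"].mean())
        out[ch] = {
            "true_mean_area": float(np.mean([t.true_area[ch] for t in truths])),
            "est_mean_area": est_area,
            "true_density": cfg.channel(ch).loc_density_per_nm2,
            "est_density": float(sub["loc_density"].mean()),
            "est_diameter": circle_equivalent_diameter(est_area),
            "n": int(len(sub)),
        }
        if compute_ssds:
            ssd_sub = ssd_df[ssd_df["channel"] == ch] if len(ssd_df) else ssd_df
            out[ch]["est_mean_n_ssd"] = float(sub["n_ssd"].mean())
            out[ch]["est_mean_ssd_area"] = (float(ssd_sub["area"].mean())
                                            if len(ssd_sub) else float("nan"))
    return out


def ssd_false_positive_rate(seed: int, n_synapses: int = 100, n_locs: int = 200,
                            synapse_diameter: float = 400.0,
                            cfg: SsdConfig | None = None) -> float:
    """Fraction of CSR synapses (no planted structure) with zero detected SSDs.

    Each synapse is ``n_locs`` points uniform in a disc of the given
    diameter; detection runs at default settings with per-synapse seeds.
    """
    cfg = cfg or SsdConfig()
    rng = np.random.default_rng(seed)
    r = synapse_diameter / 2.0
    zero = 0
    for i in range(n_synapses):
        u = rng.uniform(size=n_locs)
        th = rng.uniform(0, 2 * np.pi, n_locs)
        pts = np.column_stack([r * np.sqrt(u) * np.cos(th),
                               r * np.sqrt(u) * np.sin(th)])
        shape = alpha_shape(pts, cfg.alpha_radius)
        ssds = detect_ssds(pts, shape, cfg, seed=int(rng.integers(2 ** 31)))
        zero += (len(ssds) == 0)
    return zero / n_synapses


def enrichment_csr_mean(seed: int, n_replicates: int = 200, n_locs: int = 400,
                        synapse_radius: float = 300.0, n_peaks: int = 3,
                        range_radius: float = 60.0) -> float:
    """Mean enrichment index of CSR fields around interior reference peaks.

    Protein-*a* localizations are uniform over the synapse shape and the
    reference peaks are drawn from the interior eroded by ``range_radius``
    (so the search disc never leaves the synapse); the uniform expectation
    of the index is then exactly 1.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=4000)
    th = rng.uniform(0, 2 * np.pi, 4000)
    boundary = np.column_stack([synapse_radius * np.sqrt(u) * np.cos(th),
                                synapse_radius * np.sqrt(u) * np.sin(th)])
    shape = alpha_shape(boundary, 150.0)
    inner = synapse_radius - 2 * range_radius
    values = []
    for _ in range(n_replicates):
        locs_a = shape.sample_uniform(n_locs, rng)
        u = rng.uniform(size=n_peaks)
        t = rng.uniform(0, 2 * np.pi, n_peaks)
        peaks = np.column_stack([inner * np.sqrt(u) * np.cos(t),
                                 inner * np.sqrt(u) * np.sin(t)])
        ssds = [SubsynapticDomain(np.arange(1), p.reshape(1, 2), 100.0,
                                  (float(p[0]), float(p[1])), 1) for p in peaks]
        values.append(enrichment_index(locs_a, ssds, shape,
                                       range_radius).enrichment_index)
    return float(np.mean(values))


def grubbs_false_removal_rate(seed: int, n_runs: int = 1000, n: int = 20,
                              alpha: float = 0.05) -> float:
    """Fraction of clean Gaussian samples from which Grubbs removes anything."""
    from .stats_report import remove_outliers_grubbs
    rng = np.random.default_rng(seed)
    hits = sum(len(remove_outliers_grubbs(rng.normal(size=n), alpha)[1]) > 0
               for _ in range(n_runs))
    return hits / n_runs
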