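"""Synthetic ground-truth generators for every pipeline stage.

The localization-field generator emulates two-channel DNA-PAINT data of
inhibitory synapses: circular synapses (circle-equivalent diameters roughly
100-800 nm) containing 1-4 Gaussian subsynaptic domains over a uniform
within-synapse background, field-wide uniform noise, multi-frame re-blinking
duplicates, a fixed two-channel registration offset, and a VGAT disc mask.
Group presets ``vehicle`` and ``dzp`` carry the published group-mean synapse
areas, localization densities and SSD sizes, so parameter-recovery runs
target printed values.

All generators are pure functions of their seeded config: identical config
=> identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import PackingError, ParameterError
from .frap import FRAPSeries
from .locio import LocalizationTable
from .region_masks import PLASpot

CHANNELS = ("receptor", "scaffold")


def load_presets() -> dict:
    """Group presets (vehicle / dzp) with published group-mean parameters."""
    with resources.files("nanoorg.data").joinpath("presets.json").open() as fh:
        return json.load(fh)


@dataclass
class ChannelSpec:
    """Per-channel generative parameters for one treatment group."""

    mean_area_nm2: float          # group-mean synapse area (alpha-shape scale)
    loc_density_per_nm2: float    # localizations per nm^2 inside the synapse
    ssd_area_nm2: float           # target circle-equivalent SSD area
    n_ssd_range: tuple[int, int]  # inclusive range of SSDs per synapse

    @property
    def ssd_sigma(self) -> float:
        """Gaussian sigma so ~95% of an SSD's locs fall in the target area
        (sigma = SSD circle-equivalent radius / 2)."""
        return float(np.sqrt(self.ssd_area_nm2 / np.pi) / 2.0)


@dataclass
class FieldConfig:
    """Configuration for :func:`generate_field`.

    Synapse diameters are lognormal in log-diameter (sd ``diameter_sigma_log``)
    with the scale set so the *mean area* equals the channel's
    ``mean_area_nm2``.  ``seed`` is mandatory.
    """

    seed: int
    receptor: ChannelSpec = field(default_factory=lambda: ChannelSpec(50100.0, 4.3e-3, 1134.0, (1, 3)))
    scaffold: ChannelSpec = field(default_factory=lambda: ChannelSpec(130100.0, 4.0e-3, 5200.0, (1, 4)))
    field_extent: tuple[float, float] = (20000.0, 20000.0)
    n_synapses: int = 100
    diameter_sigma_log: float = 0.15
    ssd_loc_fraction: float = 0.4
    background_density: float = 2e-5     # locs/nm^2, field-wide, per channel
    precision_nm: float = 10.0
    reblink_prob: float = 0.3
    max_chain: int = 5
    channel_offset: tuple[float, float] = (12.0, -8.0)  # applied to receptor
    vgat_fraction: float = 1.0
    mask_pixel_size: float = 100.0
    n_frames: int = 30000

    def channel(self, name: str) -> ChannelSpec:
        if name not in CHANNELS:
            raise ParameterError(f"unknown channel {name!r}")
        return getattr(self, name)


def config_from_preset(name: str, seed: int, **overrides) -> FieldConfig:
    """FieldConfig for a treatment-group preset (``vehicle`` or ``dzp``)."""
    presets = load_presets()
    if name not in presets:
        raise ParameterError(f"unknown preset {name!r}; have {sorted(presets)}")
    p = presets[name]
    channels = {ch: ChannelSpec(p[ch]["mean_area_nm2"], p[ch]["loc_density_per_nm2"],
                                p[ch]["ssd_area_nm2"], tuple(p[ch]["n_ssd_range"]))
                for ch in CHANNELS}
    return FieldConfig(seed=seed, receptor=channels["receptor"],
                       scaffold=channels["scaffold"], **overrides)


@dataclass
class SynapseTruth:
    """Ground truth for one generated synapse (per-channel dicts)."""

    center: tuple[float, float]
    true_area: dict               # channel -> disc area nm^2
    n_ssd: dict                   # channel -> planted SSD count
    ssd_centers: dict             # channel -> (k, 2) array
    ssd_sigma: dict               # channel -> nm
    locs_per_channel: dict        # channel -> base localization count (pre-reblink)
    has_vgat: bool


def _lognormal_diameter(mean_area: float, sigma_log: float, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    # E[d^2] = exp(2 mu + 2 sigma^2); choose mu so that pi/4 E[d^2] = mean_area
    mu = 0.5 * np.log(4.0 * mean_area / np.pi) - sigma_log ** 2
    return rng.lognormal(mu, sigma_log, size)


def _uniform_disc(center, radius, n, rng):
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def _place_centers(cfg: FieldConfig, radii: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping synapse centres by bounded rejection sampling."""
    w, h = cfg.field_extent
    centers = []
    clearance = 300.0
    max_tries = 200 * cfg.n_synapses + 1000
    tries = 0
    for i in range(cfg.n_synapses):
        margin = radii[i] + 100.0
        while True:
            tries += 1
            if tries > max_tries:
                raise PackingError(
                    f"could not place {cfg.n_synapses} synapses in "
                    f"{w:.0f} x {h:.0f} nm after {max_tries} tries")
            cand = np.array([rng.uniform(margin, w - margin),
                             rng.uniform(margin, h - margin)])
            ok = True
            for j, c in enumerate(centers):
                if np.hypot(*(cand - c)) < radii[i] + radii[j] + clearance:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                break
    return np.asarray(centers)


def _reblink(xy: np.ndarray, frames: np.ndarray, photons: np.ndarray,
             cfg: FieldConfig, rng: np.random.Generator):
    """Duplicate localizations into subsequent frames with positional jitter.

    Each localization continues into the next frame with probability
    ``reblink_prob`` (chains capped at ``max_chain`` total appearances),
    jittered per axis by the localization precision.
    """
    all_xy, all_frames, all_photons = [xy], [frames], [photons]
    prev_xy, prev_frames, prev_photons = xy, frames, photons
    for _ in range(cfg.max_chain - 1):
        cont = rng.uniform(size=len(prev_xy)) < cfg.reblink_prob
        if not cont.any():
            break
        prev_xy = (prev_xy[cont]
                   + rng.normal(0, cfg.precision_nm, (int(cont.sum()), 2)))
        prev_frames = prev_frames[cont] + 1
        prev_photons = np.maximum(prev_photons[cont]
                                  * rng.uniform(0.5, 1.0, int(cont.sum())), 1.0)
        all_xy.append(prev_xy)
        all_frames.append(prev_frames)
        all_photons.append(prev_photons)
    return (np.concatenate(all_xy), np.concatenate(all_frames),
            np.concatenate(all_photons))


def generate_field(cfg: FieldConfig):
    """Generate a two-channel localization field with ground truth.

    Returns ``(receptor, scaffold, vgat_mask, truths)``: two
    :class:`~nanoorg.locio.LocalizationTable` (the receptor channel shifted
    by ``cfg.channel_offset``), a boolean VGAT raster at
    ``cfg.mask_pixel_size`` nm/px, and one :class:`SynapseTruth` per synapse.
    """
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.field_extent

    diam = {ch: _lognormal_diameter(cfg.channel(ch).mean_area_nm2,
                                    cfg.diameter_sigma_log, cfg.n_synapses, rng)
            for ch in CHANNELS}
    # scaffold is the larger, synapse-defining channel; receptor disc is
    # concentric and clipped to the scaffold radius
    radii = {ch: diam[ch] / 2.0 for ch in CHANNELS}
    radii["receptor"] = np.minimum(radii["receptor"], radii["scaffold"])

    centers = (_place_centers(cfg, radii["scaffold"], rng)
               if cfg.n_synapses else np.empty((0, 2)))
    has_vgat = rng.uniform(size=cfg.n_synapses) < cfg.vgat_fraction

    tables = {}
    truths = [None] * cfg.n_synapses
    per_syn = {ch: [] for ch in CHANNELS}
    for ch in CHANNELS:
        spec = cfg.channel(ch)
        sigma = spec.ssd_sigma
        xy_parts, frame_parts, photon_parts = [], [], []
        for i in range(cfg.n_synapses):
            r = radii[ch][i]
            area = np.pi * r ** 2
            n_locs = rng.poisson(spec.loc_density_per_nm2 * area)
            n_ssd = int(rng.integers(spec.n_ssd_range[0], spec.n_ssd_range[1] + 1))
            ssd_centers = _ssd_centers(centers[i], r, sigma, n_ssd, rng)
            n_in_ssds = int(round(cfg.ssd_loc_fraction * n_locs)) if n_ssd else 0
            split = rng.multinomial(n_in_ssds, np.full(n_ssd, 1.0 / n_ssd)) if n_ssd else []
            pts = [ssd_centers[k] + rng.normal(0, sigma, (split[k], 2))
                   for k in range(n_ssd)]
            pts.append(_uniform_disc(centers[i], r, n_locs - n_in_ssds, rng))
            xy = np.concatenate(pts) if pts else np.empty((0, 2))
            xy_parts.append(xy)
            frame_parts.append(rng.integers(0, cfg.n_frames - cfg.max_chain, len(xy)))
            photon_parts.append(rng.lognormal(7.0, 0.4, len(xy)))
            per_syn[ch].append((n_locs, n_ssd, ssd_centers, area))
        # field-wide uniform background
        n_bg = rng.poisson(cfg.background_density * w * h)
        xy_parts.append(np.column_stack([rng.uniform(0, w, n_bg),
                                         rng.uniform(0, h, n_bg)]))
        frame_parts.append(rng.integers(0, cfg.n_frames - cfg.max_chain, n_bg))
        photon_parts.append(rng.lognormal(7.0, 0.4, n_bg))

        xy = np.concatenate(xy_parts)
        # every localization carries its fit error
        xy = xy + rng.normal(0, cfg.precision_nm, xy.shape)
        frames = np.concatenate(frame_parts)
        photons = np.concatenate(photon_parts)
        xy, frames, photons = _reblink(xy, frames, photons, cfg, rng)
        if ch == "receptor":
            xy = xy + np.asarray(cfg.channel_offset)
        xy[:, 0] = np.clip(xy[:, 0], 0, w)
        xy[:, 1] = np.clip(xy[:, 1], 0, h)
        tables[ch] = LocalizationTable(
            df=pd.DataFrame({"frame": frames, "x": xy[:, 0], "y": xy[:, 1],
                             "photons": photons,
                             "precision": np.full(len(xy), cfg.precision_nm)}),
            channel_label=ch, n_frames=cfg.n_frames, field_extent=(w, h))

    for i in range(cfg.n_synapses):
        truths[i] = SynapseTruth(
            center=tuple(centers[i]),
            true_area={ch: per_syn[ch][i][3] for ch in CHANNELS},
            n_ssd={ch: per_syn[ch][i][1] for ch in CHANNELS},
            ssd_centers={ch: per_syn[ch][i][2] for ch in CHANNELS},
            ssd_sigma={ch: cfg.channel(ch).ssd_sigma for ch in CHANNELS},
            locs_per_channel={ch: per_syn[ch][i][0] for ch in CHANNELS},
            has_vgat=bool(has_vgat[i]))

    ps = cfg.mask_pixel_size
    mask = np.zeros((int(np.ceil(h / ps)), int(np.ceil(w / ps))), dtype=bool)
    rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    px = (cc + 0.5) * ps
    py = (rr + 0.5) * ps
    for i in range(cfg.n_synapses):
        if has_vgat[i]:
            r_mask = radii["scaffold"][i] + ps
            mask |= (px - centers[i, 0]) ** 2 + (py - centers[i, 1]) ** 2 <= r_mask ** 2
    return tables["receptor"], tables["scaffold"], mask, truths


def _ssd_centers(center, radius, sigma, n_ssd, rng, min_sep_sigma=4.0):
    """SSD centres inside the synapse interior, kept >= min_sep_sigma*sigma
    apart when geometrically feasible."""
    if n_ssd == 0:
        return np.empty((0, 2))
    inner = max(radius - 2.0 * sigma, 0.2 * radius)
    out = []
    for _ in range(n_ssd):
        for _attempt in range(200):
            cand = _uniform_disc(center, inner, 1, rng)[0]
            if all(np.hypot(*(cand - c)) >= min_sep_sigma * sigma for c in out):
                break
        out.append(cand)
    return np.asarray(out)


def generate_beads(cfg: FieldConfig, n_beads: int = 12,
                   jitter_nm: float = 0.0):
    """Index-matched fiducial bead pairs related by the field's channel offset.

    Returns ``(ref, mov)`` with ``mov = ref + channel_offset`` plus optional
    Gaussian jitter; used to exercise channel-transform fitting.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    w, h = cfg.field_extent
    ref = np.column_stack([rng.uniform(0, w, n_beads), rng.uniform(0, h, n_beads)])
    mov = ref + np.asarray(cfg.channel_offset)
    if jitter_nm > 0:
        mov = mov + rng.normal(0, jitter_nm, mov.shape)
    return ref, mov


# ---------------------------------------------------------------------------
# binary-mask fixtures
# ---------------------------------------------------------------------------

@dataclass
class MasksetConfig:
    seed: int
    shape: tuple[int, int] = (256, 256)
    n_discs: int = 20
    disc_radius_px: float = 6.0
    overlap_fraction: float = 0.5    # target marker/receptor disc overlap
    pixel_size: float = 100.0


def _disc(mask_shape, center, radius):
    rr, cc = np.mgrid[0:mask_shape[0], 0:mask_shape[1]]
    return (cc - center[0]) ** 2 + (rr - center[1]) ** 2 <= radius ** 2


def _lens_fraction(d: float, r: float) -> float:
    """Overlap area of two radius-r discs at centre distance d, as a fraction
    of one disc's area (closed form)."""
    if d >= 2 * r:
        return 0.0
    if d <= 0:
        return 1.0
    area = 2 * r ** 2 * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r ** 2 - d ** 2)
    return float(area / (np.pi * r ** 2))


def generate_maskset(cfg: MasksetConfig):
    """Rasterized disc pairs with a controlled receptor/marker overlap.

    Returns ``(receptor_mask, marker_mask, truth)`` where ``truth`` lists the
    per-disc target overlap fraction and marker displacement in px.
    """
    rng = np.random.default_rng(cfg.seed)
    r = cfg.disc_radius_px
    if cfg.overlap_fraction >= 1.0:
        d = 0.0
    elif cfg.overlap_fraction <= 0.0:
        d = 2 * r + 2.0
    else:
        d = brentq(lambda x: _lens_fraction(x, r) - cfg.overlap_fraction, 0, 2 * r)
    receptor = np.zeros(cfg.shape, dtype=bool)
    marker = np.zeros(cfg.shape, dtype=bool)
    centers = []
    margin = 2 * r + d + 2
    tries = 0
    truth = []
    while len(centers) < cfg.n_discs:
        tries += 1
        if tries > 500 * cfg.n_discs:
            raise PackingError("could not place mask discs without contact")
        cand = np.array([rng.uniform(margin, cfg.shape[1] - margin),
                         rng.uniform(margin, cfg.shape[0] - margin)])
        if any(np.hypot(*(cand - c)) < 2 * (r + d) + 4 for c in centers):
            continue
        theta = rng.uniform(0, 2 * np.pi)
        offset = d * np.array([np.cos(theta), np.sin(theta)])
        receptor |= _disc(cfg.shape, cand, r)
        marker |= _disc(cfg.shape, cand + offset, r)
        centers.append(cand)
        truth.append({"center": tuple(cand), "target_overlap": cfg.overlap_fraction,
                      "displacement_px": float(d)})
    return receptor, marker, truth


# ---------------------------------------------------------------------------
# PLA fixtures
# ---------------------------------------------------------------------------

@dataclass
class PlaConfig:
    seed: int
    shape: tuple[int, int] = (512, 512)
    n_spots: int = 100
    synaptic_fraction: float = 0.5
    spot_diameter_px: float = 5.0    # 0.50 um at 100 nm/px
    n_marker_discs: int = 40
    marker_radius_px: float = 5.0


def generate_pla_field(cfg: PlaConfig):
    """PLA spots over a marker mask with a planted synaptic fraction.

    Returns ``(spots, marker_mask, truth_labels)``; a spot is planted
    synaptic by centring it on a marker pixel, and extrasynaptic by placing
    it so its disc clears the marker entirely.
    """
    rng = np.random.default_rng(cfg.seed)
    marker = np.zeros(cfg.shape, dtype=bool)
    m = cfg.marker_radius_px + 2
    for _ in range(cfg.n_marker_discs):
        c = (rng.uniform(m, cfg.shape[1] - m), rng.uniform(m, cfg.shape[0] - m))
        marker |= _disc(cfg.shape, c, cfg.marker_radius_px)
    marker_rc = np.column_stack(np.nonzero(marker))

    n_syn = int(round(cfg.synaptic_fraction * cfg.n_spots))
    spots, labels = [], []
    spot_r = cfg.spot_diameter_px / 2.0
    for k in range(cfg.n_spots):
        synaptic = k < n_syn
        if synaptic:
            row, col = marker_rc[rng.integers(len(marker_rc))]
            center = (col + 0.5, row + 0.5)
        else:
            for _try in range(10_000):
                center = (rng.uniform(spot_r, cfg.shape[1] - spot_r),
                          rng.uniform(spot_r, cfg.shape[0] - spot_r))
                spot = PLASpot(center=center, diameter=cfg.spot_diameter_px)
                px = spot.rasterize(cfg.shape)
                if not marker[px[:, 0], px[:, 1]].any():
                    break
            else:
                raise PackingError("could not place an off-marker PLA spot")
        spots.append(PLASpot(center=center, diameter=cfg.spot_diameter_px))
        labels.append(synaptic)
    order = rng.permutation(cfg.n_spots)
    return ([spots[i] for i in order], marker,
            [labels[i] for i in order])


# ---------------------------------------------------------------------------
# FRAP fixtures
# ---------------------------------------------------------------------------

@dataclass
class FrapConfig:
    seed: int
    n_traces: int = 20
    roi_class: str = "synaptic"
    mobile_fraction: float = 0.6
    tau_min: float = 8.0
    noise_sd: float = 0.02
    f_i: float = 1.0
    f0: float = 0.2
    times: tuple = tuple(np.arange(2.0, 32.0, 2.0))  # 2-min spacing over 30 min
    n_pre: int = 3


def generate_frap_traces(cfg: FrapConfig, id_offset: int = 0):
    """Single-exponential recovery traces with known mobile fraction.

    ``F(t) = F0 + mobile * (F_i - F0) * (1 - exp(-t / tau))`` plus Gaussian
    noise of sd ``noise_sd`` (in intensity units).  Returns
    ``(series, truth)`` where ``truth`` holds the generating parameters and
    the closed-form expected plateau (mean of the final three samples).
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.times, dtype=float)
    series = []
    depth = cfg.f_i - cfg.f0
    for i in range(cfg.n_traces):
        f_pre = cfg.f_i + rng.normal(0, cfg.noise_sd, cfg.n_pre)
        f0 = cfg.f0 + rng.normal(0, cfg.noise_sd)
        f_t = (cfg.f0 + cfg.mobile_fraction * depth * (1 - np.exp(-times / cfg.tau_min))
               + rng.normal(0, cfg.noise_sd, len(times)))
        series.append(FRAPSeries(roi_id=id_offset + i, roi_class=cfg.roi_class,
                                 times=times, f_pre=f_pre, f0=float(f0), f_t=f_t))
    expected_plateau = float(np.mean(
        cfg.mobile_fraction * (1 - np.exp(-times[-3:] / cfg.tau_min))))
    truth = {"mobile_fraction": cfg.mobile_fraction, "tau_min": cfg.tau_min,
             "expected_plateau": expected_plateau}
    return series, truth
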