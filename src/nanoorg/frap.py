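"""FRAP trace normalization and synaptic/extrasynaptic ROI stratification.

Fluorescence recovery after photobleaching is normalized per ROI as
``(F_t - F_0) / (F_i - F_0)`` with ``F_i`` the mean pre-bleach intensity and
``F_0`` the intensity immediately after the bleach, so 0 means no recovery
and 1 means full return to the pre-bleach level.  ROIs are called synaptic
when their centre falls on a scaffold (gephyrin reporter) mask component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (DegenerateBleachError, GeometryError,
                         InsufficientDataError, ParameterError, SchemaError)

SYNAPTIC = "synaptic"
EXTRASYNAPTIC = "extrasynaptic"


@dataclass
class FRAPSeries:
    """One ROI's raw FRAP trace (pre-bleach, bleach, recovery)."""

    roi_id: int
    roi_class: str                 # synaptic | extrasynaptic
    times: np.ndarray              # minutes post-bleach, strictly increasing
    f_pre: np.ndarray              # pre-bleach intensities
    f0: float                      # intensity immediately after the bleach
    f_t: np.ndarray                # intensities at `times`

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.f_pre = np.asarray(self.f_pre, dtype=float)
        self.f_t = np.asarray(self.f_t, dtype=float)
        if len(self.times) != len(self.f_t):
            raise ParameterError("times and F_t must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if len(self.f_pre) == 0:
            raise ParameterError("at least one pre-bleach sample is required")

    @property
    def f_i(self) -> float:
        """Mean pre-bleach intensity."""
        return float(self.f_pre.mean())


@dataclass
class RecoveryCurve:
    """Normalized recovery fractions for one ROI."""

    roi_id: int
    roi_class: str
    times: np.ndarray
    recovery: np.ndarray
    plateau: float                 # mean of the final 3 samples


def normalize_recovery(series: FRAPSeries, plateau_samples: int = 3) -> RecoveryCurve:
    """Normalize a trace to (F_t - F_0) / (F_i - F_0).

    Raises :class:`DegenerateBleachError` when the bleach has no depth
    (F_i == F_0).  Values are not clipped: recovery above 1 (overshoot) is
    reported as-is.
    """
    f_i = series.f_i
    if np.isclose(f_i, series.f0):
        raise DegenerateBleachError(
            f"ROI {series.roi_id}: F_i == F_0, no bleach depth")
    recovery = (series.f_t - series.f0) / (f_i - series.f0)
    tail = recovery[-plateau_samples:] if len(recovery) else recovery
    return RecoveryCurve(series.roi_id, series.roi_class, series.times.copy(),
                         recovery, float(tail.mean()))


def classify_frap_roi(roi_center: tuple[float, float], scaffold_mask,
                      marker_uptake_mask=None) -> str:
    """Synaptic iff the ROI centre (x, y) px falls on a scaffold-mask pixel.

    When a presynaptic-uptake mask is also given, both must be hit for the
    synaptic call (stricter colocalization).
    """
    mask = np.asarray(scaffold_mask) != 0
    x, y = roi_center
    col, row = int(np.floor(x)), int(np.floor(y))
    if not (0 <= row < mask.shape[0] and 0 <= col < mask.shape[1]):
        raise GeometryError(f"ROI centre {roi_center} outside image {mask.shape}")
    hit = bool(mask[row, col])
    if marker_uptake_mask is not None:
        hit = hit and bool(np.asarray(marker_uptake_mask)[row, col] != 0)
    return SYNAPTIC if hit else EXTRASYNAPTIC


def group_recovery(curves: list[RecoveryCurve], labels: list[str]) -> pd.DataFrame:
    """Per-timepoint group means ± SEM and unpaired t-tests for two groups.

    All curves must share a common time grid.  Returns one row per timepoint
    with means, SEMs, Welch-free (classical) unpaired t statistic and its
    two-sided p-value, plus a Holm-corrected column (not part of the original
    per-timepoint policy; provided for convenience).
    """
    if len(curves) != len(labels):
        raise ParameterError("one label per curve required")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ParameterError(f"exactly two groups required, got {groups}")
    times = curves[0].times
    for c in curves:
        if len(c.times) != len(times) or not np.allclose(c.times, times):
            raise ParameterError("curves do not share a common time grid")
    by_group = {g: np.array([c.recovery for c, l in zip(curves, labels) if l == g])
                for g in groups}
    for g, arr in by_group.items():
        if arr.shape[0] < 2:
            raise InsufficientDataError(f"group {g!r} has n < 2 curves")
    a, b = by_group[groups[0]], by_group[groups[1]]
    rows = []
    for k, t_min in enumerate(times):
        va, vb = a[:, k], b[:, k]
        if np.allclose(va, va[0]) and np.allclose(vb, vb[0]) and va[0] == vb[0]:
            tstat, p = 0.0, 1.0  # identical constant groups
        else:
            tstat, p = stats.ttest_ind(va, vb)
        rows.append({
            "time_min": float(t_min),
            f"mean_{groups[0]}": float(va.mean()),
            f"sem_{groups[0]}": float(stats.sem(va)),
            f"mean_{groups[1]}": float(vb.mean()),
            f"sem_{groups[1]}": float(stats.sem(vb)),
            "t": float(tstat), "p": float(p),
        })
    df = pd.DataFrame(rows)
    df["p_holm"] = _holm(df["p"].to_numpy())
    return df


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def read_traces(path: str | Path) -> list[FRAPSeries]:
    """Read FRAP traces from a tidy CSV ``roi_id,class,time_min,intensity``.

    Rows with ``time_min < 0`` are pre-bleach samples, ``time_min == 0`` is
    F_0, and positive times are the recovery phase.
    """
    df = pd.read_csv(path)
    needed = ["roi_id", "class", "time_min", "intensity"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table missing column(s): {missing}")
    series = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("time_min")
        pre = sub[sub["time_min"] < 0]["intensity"].to_numpy()
        zero = sub[sub["time_min"] == 0]["intensity"].to_numpy()
        post = sub[sub["time_min"] > 0]
        if len(zero) != 1:
            raise SchemaError(f"ROI {roi_id}: exactly one time_min == 0 row required")
        series.append(FRAPSeries(
            roi_id=int(roi_id), roi_class=str(sub["class"].iloc[0]),
            times=post["time_min"].to_numpy(), f_pre=pre,
            f0=float(zero[0]), f_t=post["intensity"].to_numpy()))
    return series


def write_traces(series: list[FRAPSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        n_pre = len(s.f_pre)
        for i, v in enumerate(s.f_pre):
            rows.append((s.roi_id, s.roi_class, float(i - n_pre), v))
        rows.append((s.roi_id, s.roi_class, 0.0, s.f0))
        for t, v in zip(s.times, s.f_t):
            rows.append((s.roi_id, s.roi_class, float(t), v))
    pd.DataFrame(rows, columns=["roi_id", "class", "time_min", "intensity"]).to_csv(
        path, index=False)
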