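"""Localization table I/O, re-blink linking, and channel alignment.

Single-molecule localization microscopy (SMLM) produces one fitted emitter
position per blinking event: ``(frame, x, y, photons, precision)``, with
coordinates in nanometres.  This module reads and writes such tables, merges
re-blinking duplicates that persist across consecutive camera frames, and
fits/applies channel-registration transforms estimated from fiducial beads.

Conventions
-----------
* Coordinates are nm, origin at the field top-left, y increasing downward.
* All geometry is 2D (single-plane HILO imaging).
* Tables are kept sorted by frame, ties broken by x then y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import DegeneracyError, ParameterError, ParseError, SchemaError

#: exact CSV header names for localization tables
CSV_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "precision_nm"]
#: internal (unit-free) column names, in the same order
_INTERNAL = ["frame", "x", "y", "photons", "precision"]
_CSV_TO_INTERNAL = dict(zip(CSV_COLUMNS, _INTERNAL))


@dataclass
class LocalizationTable:
    """A per-channel table of localizations.

    Parameters
    ----------
    df
        DataFrame with columns ``frame`` (int), ``x``, ``y`` (nm),
        ``photons`` (counts) and ``precision`` (nm).  Extra columns are
        carried along untouched.
    channel_label
        Free-text channel name (e.g. ``"gephyrin"``).
    n_frames
        Number of camera frames in the acquisition.  Defaults to
        ``max(frame) + 1``.
    field_extent
        ``(width_nm, height_nm)`` of the imaged field.  Defaults to the
        smallest extent containing all localizations.
    """

    df: pd.DataFrame
    channel_label: str = ""
    n_frames: int | None = None
    field_extent: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _INTERNAL if c not in self.df.columns]
        if missing:
            raise SchemaError(f"localization table missing column(s): {missing}")
        df = self.df.copy()
        df["frame"] = df["frame"].astype(np.int64)
        df = df.sort_values(["frame", "x", "y"], kind="mergesort").reset_index(drop=True)
        self.df = df
        if self.n_frames is None:
            self.n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        if self.field_extent is None:
            if len(df):
                self.field_extent = (float(df["x"].max()), float(df["y"].max()))
            else:
                self.field_extent = (0.0, 0.0)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ParseError("non-finite coordinate in localization table")
        if (df["precision"] <= 0).any():
            raise ParseError("localization precision must be > 0 nm")
        if (df["frame"] < 0).any() or (df["frame"] >= max(self.n_frames, 1)).any():
            raise ParseError("frame index outside [0, n_frames)")

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask_or_index) -> "LocalizationTable":
        """New table restricted to a boolean mask or positional index."""
        if np.asarray(mask_or_index).dtype == bool:
            sub = self.df.loc[np.asarray(mask_or_index)]
        else:
            sub = self.df.iloc[np.asarray(mask_or_index)]
        return replace(self, df=sub.reset_index(drop=True))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_locs(path: str | Path, format: str | None = None, channel_label: str = "",
              **table_kwargs) -> LocalizationTable:
    """Read a localization table from CSV or HDF5.

    CSV files must carry the exact header
    ``frame,x_nm,y_nm,photons,precision_nm``; extra columns are preserved.
    HDF5 files hold one 1-D dataset per column under ``/locs/<channel>``.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if format == "csv":
        raw = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in raw.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing required column(s) {missing}")
        df = raw.rename(columns=_CSV_TO_INTERNAL)
        for col in _INTERNAL:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(f"{path.name}: non-numeric value in column "
                                 f"'{col}' at data row {row}")
            if coerced.isna().any():
                row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
                raise ParseError(f"{path.name}: missing value in column '{col}' "
                                 f"at data row {row}")
            df[col] = coerced
    elif format == "hdf5":
        with h5py.File(path, "r") as fh:
            group = fh["locs"]
            if channel_label:
                ch = channel_label
            else:
                ch = next(iter(group))
            sub = group[ch]
            missing = [c for c in _INTERNAL if c not in sub]
            if missing:
                raise SchemaError(f"{path.name}:/locs/{ch}: missing dataset(s) {missing}")
            df = pd.DataFrame({c: np.asarray(sub[c]) for c in sub})
            channel_label = ch
    else:
        raise ParameterError(f"unknown format {format!r}")
    return LocalizationTable(df=df, channel_label=channel_label, **table_kwargs)


def write_locs(table: LocalizationTable, path: str | Path,
               format: str | None = None) -> None:
    """Write a table to CSV (standard headers) or HDF5 (``/locs/<channel>``)."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if format == "csv":
        out = table.df.rename(columns={v: k for k, v in _CSV_TO_INTERNAL.items()})
        out.to_csv(path, index=False)
    elif format == "hdf5":
        ch = table.channel_label or "channel0"
        with h5py.File(path, "a") as fh:
            grp = fh.require_group("locs").require_group(ch)
            for col in table.df.columns:
                if col in grp:
                    del grp[col]
                grp.create_dataset(col, data=table.df[col].to_numpy())
    else:
        raise ParameterError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# re-blink linking
# ---------------------------------------------------------------------------

def link_consecutive(table: LocalizationTable, radius: float,
                     max_gap: int = 0) -> LocalizationTable:
    """Merge localizations that persist over consecutive frames.

    Any two localizations whose frames differ by ``1 .. max_gap + 1`` and
    whose positions are within ``radius`` nm are considered the same emitter
    re-blinking; chains of such pairs are merged into a single localization.
    The merged position and precision are photon-weighted means (the
    minimum-variance combination) and photons are summed; the merged frame is
    the first frame of the chain.

    With ``max_gap = 0`` only strictly consecutive frames are linked.
    """
    if radius < 0:
        raise ParameterError("linking radius must be >= 0")
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")
    n = len(table)
    if n == 0 or radius == 0:
        return table.subset(np.arange(n))

    df = table.df
    frames = df["frame"].to_numpy()
    xy = table.xy

    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        dframe = np.abs(frames[pairs[:, 0]] - frames[pairs[:, 1]])
        pairs = pairs[(dframe >= 1) & (dframe <= max_gap + 1)]

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra

    roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
    _, comp = np.unique(roots, return_inverse=True)
    n_comp = comp.max() + 1

    photons = df["photons"].to_numpy(dtype=float)
    weights = np.where(photons > 0, photons, 1.0)  # photon-less rows weighted equally
    wsum = np.bincount(comp, weights=weights, minlength=n_comp)
    merged = pd.DataFrame({
        "frame": _group_min(comp, frames, n_comp),
        "x": np.bincount(comp, weights=weights * xy[:, 0], minlength=n_comp) / wsum,
        "y": np.bincount(comp, weights=weights * xy[:, 1], minlength=n_comp) / wsum,
        "photons": np.bincount(comp, weights=photons, minlength=n_comp),
        "precision": np.bincount(
            comp, weights=weights * df["precision"].to_numpy(dtype=float),
            minlength=n_comp) / wsum,
    })
    return replace(table, df=merged)


def _group_min(groups: np.ndarray, values: np.ndarray, n_groups: int) -> np.ndarray:
    out = np.full(n_groups, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(out, groups, values)
    return out


# ---------------------------------------------------------------------------
# channel alignment
# ---------------------------------------------------------------------------

@dataclass
class ChannelTransform:
    """A fitted 2D channel-registration transform.

    ``matrix`` is a 2x3 augmented matrix mapping reference-channel
    coordinates onto the moving channel: ``mov ≈ A @ ref + t``.
    """

    model: str  # "translation" | "affine"
    matrix: np.ndarray  # (2, 3)
    residual_rmse: float

    @property
    def parameters(self) -> np.ndarray:
        if self.model == "translation":
            return self.matrix[:, 2].copy()
        return self.matrix.copy()

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "ChannelTransform":
        a = self.matrix[:, :2]
        t = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return ChannelTransform(self.model, np.column_stack([a_inv, -a_inv @ t]),
                                self.residual_rmse)

    def to_dict(self) -> dict:
        return {"model": self.model, "matrix": self.matrix.tolist(),
                "residual_rmse": self.residual_rmse}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelTransform":
        return cls(d["model"], np.asarray(d["matrix"], dtype=float),
                   float(d["residual_rmse"]))


def fit_channel_transform(ref_beads, mov_beads, model: str = "affine") -> ChannelTransform:
    """Least-squares channel transform from index-matched fiducial beads.

    The returned transform maps reference-bead coordinates onto the moving
    beads (``mov ≈ T(ref)``), minimizing the sum of squared residuals.

    ``translation`` needs >= 1 bead pair; ``affine`` needs >= 3 non-collinear
    pairs (collinear inputs raise :class:`DegeneracyError`).
    """
    ref = np.asarray(ref_beads, dtype=float).reshape(-1, 2)
    mov = np.asarray(mov_beads, dtype=float).reshape(-1, 2)
    if ref.shape != mov.shape:
        raise ParameterError("bead lists must be index-matched and equal length")
    n = len(ref)
    if model == "translation":
        if n < 1:
            raise ParameterError("translation model needs >= 1 bead pair")
        t = (mov - ref).mean(axis=0)
        matrix = np.column_stack([np.eye(2), t])
    elif model == "affine":
        if n < 3:
            raise ParameterError("affine model needs >= 3 bead pairs")
        centered = ref - ref.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(ref).max())) < 2:
            raise DegeneracyError("beads are collinear; affine fit is degenerate")
        design = np.column_stack([ref, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, mov, rcond=None)  # (3, 2)
        matrix = coef.T
    else:
        raise ParameterError(f"unknown transform model {model!r}")
    fitted = ref @ matrix[:, :2].T + matrix[:, 2]
    rmse = float(np.sqrt(np.mean(np.sum((fitted - mov) ** 2, axis=1)))) if n else 0.0
    return ChannelTransform(model, matrix, rmse)


def apply_transform(table: LocalizationTable, t: ChannelTransform) -> LocalizationTable:
    """Return a copy of ``table`` with coordinates mapped through ``t``."""
    new_xy = t.apply(table.xy)
    df = table.df.copy()
    df["x"] = new_xy[:, 0]
    df["y"] = new_xy[:, 1]
    out = replace(table, df=df, field_extent=None)
    out.field_extent = table.field_extent
    return out
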