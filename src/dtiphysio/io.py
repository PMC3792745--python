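"""Readers and writers for all external artifacts.

Formats: NIfTI-1 volumes (via nibabel), FSL-style bvec/bval gradient
tables, plain-TSV physiological traces (`time  cardiac  respiratory`,
seconds / arbitrary units; the BIDS ``*_physio.tsv.gz`` dialect with a JSON
sidecar is also accepted), TSV slice-timing tables
(`volume  slice  time_s`), ROI masks and YAML run configs.

Conventions: voxel indices are 0-based, times are in seconds with time zero
at the first slice trigger of volume 0 (peripheral recordings are
scan-locked and may start before zero), and gradient directions are
interpreted in the image frame.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "VolumeSeries",
    "GradientScheme",
    "PhysioRecording",
    "SliceTiming",
    "ROIMask",
    "read_dwi",
    "write_dwi",
    "read_physio",
    "write_physio",
    "read_slice_timing",
    "write_slice_timing",
    "read_mask",
    "write_map",
    "load_config",
]

#: b-values at or below this (s/mm^2) count as the low-DW reference shell.
B_LOW_THRESHOLD = 150.0


class FormatError(ValueError):
    """Raised when an external artifact violates its format contract."""


@dataclass
class GradientScheme:
    """Per-volume diffusion weighting b (s/mm^2) and unit direction g."""

    b: np.ndarray
    g: np.ndarray
    b_low_threshold: float = B_LOW_THRESHOLD

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.g = np.asarray(self.g, dtype=float).reshape(-1, 3)
        if self.b.shape[0] != self.g.shape[0]:
            raise FormatError(
                f"{self.b.shape[0]} b-values but {self.g.shape[0]} gradient vectors"
            )
        norms = np.linalg.norm(self.g, axis=1)
        high = self.b > self.b_low_threshold
        bad = high & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise FormatError(
                f"non-unit gradient direction(s) at high-b volume(s) {np.where(bad)[0].tolist()}"
            )
        if not np.any(~high):
            raise FormatError("gradient scheme contains no low-b reference volume")

    @property
    def n_volumes(self) -> int:
        return self.b.shape[0]

    @property
    def is_high(self) -> np.ndarray:
        return self.b > self.b_low_threshold

    @property
    def is_low(self) -> np.ndarray:
        return ~self.is_high

    @property
    def b_low(self) -> float:
        """Representative b-value of the reference (low-DW) shell."""
        return float(np.mean(self.b[self.is_low]))

    def high_indices(self) -> np.ndarray:
        return np.where(self.is_high)[0]


@dataclass
class VolumeSeries:
    """4D diffusion-weighted intensity array (x, y, z, volume) with affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected a 4D series, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class PhysioRecording:
    """Peripheral pulse-oximeter and breathing-belt traces on a uniform grid."""

    time: np.ndarray
    cardiac: np.ndarray
    respiratory: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise FormatError("physio time axis is not strictly increasing")
        if dt.size and np.ptp(dt) > 1e-6:
            raise FormatError("physio time axis is not uniformly sampled")
        if self.fs <= 20.0:
            raise FormatError(f"physio sampling rate {self.fs} Hz too low (need > 20 Hz)")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class SliceTiming:
    """Acquisition time t[volume, slice] in seconds, plus the slice order."""

    t: np.ndarray
    slice_order: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 2:
            raise FormatError("slice timing must be a (n_volumes, n_slices) table")
        self.slice_order = np.asarray(self.slice_order, dtype=int)

    @property
    def n_volumes(self) -> int:
        return self.t.shape[0]

    @property
    def n_slices(self) -> int:
        return self.t.shape[1]


@dataclass
class ROIMask:
    """3D boolean mask aligned to a VolumeSeries grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise FormatError("ROI mask must be 3D")
        if not self.mask.any():
            raise FormatError("ROI mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# DWI + gradient table


def _load_table(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def read_dwi(path_nifti, path_bval, path_bvec) -> tuple[VolumeSeries, GradientScheme]:
    """Read a 4D NIfTI plus FSL bval/bvec into a paired series and scheme.

    bvec is accepted as 3xN (FSL) or Nx3, disambiguated by shape.  Non-unit
    directions at b > 0 are normalized with a warning; a column-count
    mismatch with the NIfTI 4th dimension is a :class:`FormatError`.
    """
    img = nib.load(str(path_nifti))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path_nifti}: expected 4D data, got {data.ndim}D")
    n_vol = data.shape[3]

    bval = np.loadtxt(path_bval).ravel()
    bvec = _load_table(path_bvec)
    if bvec.shape[0] == 3 and bvec.shape[1] != 3:
        bvec = bvec.T
    elif bvec.shape[1] != 3:
        raise FormatError(f"{path_bvec}: cannot interpret shape {bvec.shape} as 3xN or Nx3")
    if bval.shape[0] != n_vol or bvec.shape[0] != n_vol:
        raise FormatError(
            f"gradient table length ({bval.shape[0]} bvals, {bvec.shape[0]} bvecs) "
            f"does not match {n_vol} volumes"
        )

    norms = np.linalg.norm(bvec, axis=1)
    needs_norm = (bval > 0) & (norms > 0) & (np.abs(norms - 1.0) > 1e-6)
    if np.any(needs_norm):
        warnings.warn(
            f"normalized {int(needs_norm.sum())} non-unit gradient direction(s)",
            stacklevel=2,
        )
        bvec = bvec.copy()
        bvec[needs_norm] /= norms[needs_norm, None]

    series = VolumeSeries(data=data, affine=img.affine)
    scheme = GradientScheme(b=bval, g=bvec)
    return series, scheme


def write_dwi(path_nifti, path_bval, path_bvec, series: VolumeSeries, scheme: GradientScheme):
    """Write a series + scheme in the exact formats :func:`read_dwi` reads."""
    nib.save(nib.Nifti1Image(series.data.astype(np.float32), series.affine), str(path_nifti))
    np.savetxt(path_bval, scheme.b[None, :], fmt="%.6g")
    np.savetxt(path_bvec, scheme.g.T, fmt="%.10g")


# ---------------------------------------------------------------------------
# Physiological traces


def _physio_from_columns(time, cardiac, respiratory) -> PhysioRecording:
    time = np.asarray(time, dtype=float)
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise FormatError("physio time column is not strictly increasing")
    fs = 1.0 / float(np.median(dt))
    gaps = np.where(dt > 2.0 / fs)[0]
    if gaps.size:
        locs = ", ".join(f"{time[i]:.4f}s" for i in gaps[:10])
        raise FormatError(f"physio trace has {gaps.size} gap(s) > 2/fs, at: {locs}")
    # snap to an exactly uniform grid; jitter beyond 1e-6 s is a format error
    uniform = time[0] + np.arange(time.size) / fs
    if np.max(np.abs(uniform - time)) > 1e-6:
        raise FormatError("physio time axis deviates from uniform sampling by > 1e-6 s")
    return PhysioRecording(time=uniform, cardiac=cardiac, respiratory=respiratory, fs=fs)


def read_physio(path_tsv, path_sidecar=None) -> PhysioRecording:
    """Read a physiological recording TSV (plain or BIDS-physio dialect).

    Plain dialect: header naming ``time``, ``cardiac``, ``respiratory``
    columns.  BIDS dialect (``*_physio.tsv.gz``): header-less columns
    described by a JSON sidecar with ``Columns``, ``SamplingFrequency`` and
    ``StartTime``.
    """
    path_tsv = Path(path_tsv)
    if path_sidecar is None:
        candidate = path_tsv.with_name(path_tsv.name.split(".")[0] + ".json")
        if candidate.exists():
            path_sidecar = candidate

    if path_sidecar is not None:
        with open(path_sidecar) as fh:
            meta = json.load(fh)
        cols = [c.lower() for c in meta["Columns"]]
        fs = float(meta["SamplingFrequency"])
        start = float(meta.get("StartTime", 0.0))
        opener = gzip.open if path_tsv.suffix == ".gz" else open
        with opener(path_tsv, "rt") as fh:
            table = pd.read_csv(fh, sep="\t", header=None, names=cols)
        n = len(table)
        time = start + np.arange(n) / fs
        return _physio_from_columns(
            time, table["cardiac"].to_numpy(), table["respiratory"].to_numpy()
        )

    table = pd.read_csv(path_tsv, sep="\t")
    table.columns = [c.strip().lower() for c in table.columns]
    missing = {"time", "cardiac", "respiratory"} - set(table.columns)
    if missing:
        raise FormatError(f"{path_tsv}: missing physio column(s) {sorted(missing)}")
    return _physio_from_columns(
        table["time"].to_numpy(),
        table["cardiac"].to_numpy(),
        table["respiratory"].to_numpy(),
    )


def write_physio(path_tsv, rec: PhysioRecording) -> None:
    pd.DataFrame(
        {"time": rec.time, "cardiac": rec.cardiac, "respiratory": rec.respiratory}
    ).to_csv(path_tsv, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Slice timing


def read_slice_timing(path_tsv, n_volumes: int, n_slices: int) -> SliceTiming:
    """Read a `volume  slice  time_s` table; every pair must appear once."""
    table = pd.read_csv(path_tsv, sep="\t")
    table.columns = [c.strip().lower() for c in table.columns]
    missing = {"volume", "slice", "time_s"} - set(table.columns)
    if missing:
        raise FormatError(f"{path_tsv}: missing column(s) {sorted(missing)}")
    t = np.full((n_volumes, n_slices), np.nan)
    vol = table["volume"].to_numpy(dtype=int)
    slc = table["slice"].to_numpy(dtype=int)
    if np.any((vol < 0) | (vol >= n_volumes) | (slc < 0) | (slc >= n_slices)):
        raise FormatError(f"{path_tsv}: volume/slice index out of range")
    dup = pd.DataFrame({"v": vol, "s": slc}).duplicated()
    if dup.any():
        i = int(np.where(dup)[0][0])
        raise FormatError(f"duplicate timing entry for volume {vol[i]}, slice {slc[i]}")
    t[vol, slc] = table["time_s"].to_numpy(dtype=float)
    if np.isnan(t).any():
        v, s = np.argwhere(np.isnan(t))[0]
        raise FormatError(f"slice timing table is missing volume {v}, slice {s}")
    slice_order = np.argsort(t[0], kind="stable")
    return SliceTiming(t=t, slice_order=slice_order)


def write_slice_timing(path_tsv, timing: SliceTiming) -> None:
    vol, slc = np.meshgrid(
        np.arange(timing.n_volumes), np.arange(timing.n_slices), indexing="ij"
    )
    pd.DataFrame(
        {"volume": vol.ravel(), "slice": slc.ravel(), "time_s": timing.t.ravel()}
    ).to_csv(path_tsv, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Maps and masks


def write_map(path_nifti, array3d, affine) -> None:
    """Write a 3D float32 map; read-back is bit-exact at float32 precision.

    NaN is permitted (background outside the brain mask); non-finite values
    other than NaN are rejected.
    """
    array3d = np.asarray(array3d)
    if array3d.ndim != 3:
        raise FormatError(f"expected a 3D map, got {array3d.ndim}D")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise FormatError(f"affine must be 4x4, got {affine.shape}")
    if np.isinf(array3d).any():
        raise FormatError("map contains infinite values")
    nib.save(nib.Nifti1Image(array3d.astype(np.float32), affine), str(path_nifti))


def read_map(path_nifti) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path_nifti))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def read_mask(path_nifti, shape=None) -> ROIMask:
    data, _ = read_map(path_nifti)
    if shape is not None and tuple(data.shape) != tuple(shape):
        raise FormatError(f"ROI shape {data.shape} does not match series grid {tuple(shape)}")
    return ROIMask(mask=data > 0.5)


def load_config(path_yaml) -> dict:
    with open(path_yaml) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path_yaml}: run config must be a YAML mapping")
    return cfg
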