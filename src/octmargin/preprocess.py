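"""Volume preprocessing: depth compensation, surface handling, patches, QC.

The chain reproduces what the analysis needs before any optical-property
fitting: divide out the system's roll-off/focus sensitivity (in linear
units), detect and flatten the tissue surface, project en-face images,
restrict to a region-of-interest subvolume, extract fixed-size B-scan
patches containing only valid data, and flag scans whose artifacts
(fold-over, signal dropout) make them unusable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .params import SystemModel
from .volume import OCTVolume

__all__ = [
    "QCError",
    "SurfaceMap",
    "Patch",
    "compensate_depth",
    "detect_surface",
    "normalize_surface",
    "enface_projection",
    "extract_subvolume",
    "extract_patches",
    "normalize_patch",
    "qc_scan",
]

MISSING_SURFACE = -1


class QCError(RuntimeError):
    """Raised when a scan fails a quality-control precondition."""


@dataclass
class SurfaceMap:
    """Per-(B-scan, lateral) surface depth index; missing columns are -1."""

    indices: np.ndarray  # int, (n_bscans, lateral)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2:
            raise ValueError("surface indices must be 2-D (b-scan x lateral)")

    @property
    def missing(self) -> np.ndarray:
        return self.indices == MISSING_SURFACE

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())


@dataclass
class Patch:
    """A 2-D B-scan patch (lateral x axial, dB) with provenance."""

    data: np.ndarray
    axial_spacing_um: float
    lateral_spacing_um: float
    patient_id: str = "P000"
    scan_id: str = "S000"
    bscan_index: int = 0
    lateral_offset: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("patch data must be 2-D (lateral x axial)")


def compensate_depth(volume: OCTVolume, system: SystemModel) -> OCTVolume:
    """Divide out roll-off x focus sensitivity in linear units.

    Idempotent when both profiles are flat; exact inverse of the sensitivity
    applied at acquisition, so a noiseless compensated A-scan is pure
    ``I * exp(-2 mu z)`` plus the (re-weighted) noise floor.
    """
    sens = system.sensitivity
    if sens.shape[0] != volume.n_depth:
        raise ValueError(
            f"sensitivity profile length {sens.shape[0]} != volume depth {volume.n_depth}"
        )
    compensated = 10.0 * np.log10(volume.linear / sens[None, None, :])
    return volume.with_data(compensated)


def _estimate_noise_floor_db(volume: OCTVolume) -> float:
    # top two rows of a raw volume sit above the tissue surface; the median
    # of speckled floor draws lies ~1.6 dB below the floor itself
    return float(np.median(volume.data[:, :, :2]) + 1.6)


def detect_surface(
    volume: OCTVolume,
    threshold_db_above_floor: float = 10.0,
    noise_floor_db: float | None = None,
    smooth_columns: int = 5,
) -> SurfaceMap:
    """First depth index whose lateral-median-smoothed dB exceeds floor+threshold.

    Columns that never exceed the threshold are marked missing.  When
    ``noise_floor_db`` is not given it is estimated from the top rows of the
    (raw, unnormalized) volume.
    """
    if threshold_db_above_floor <= 0:
        raise ValueError("threshold_db_above_floor must be > 0")
    floor = _estimate_noise_floor_db(volume) if noise_floor_db is None else noise_floor_db
    smoothed = median_filter(volume.data, size=(1, smooth_columns, 1), mode="nearest")
    above = smoothed > floor + threshold_db_above_floor
    first = above.argmax(axis=2)
    first[~above.any(axis=2)] = MISSING_SURFACE
    return SurfaceMap(first)


def normalize_surface(
    volume: OCTVolume,
    surface: SurfaceMap,
    noise_floor_db: float | None = None,
    min_valid_fraction: float = 0.5,
) -> OCTVolume:
    """Shift each A-scan so its surface sits at depth row 0.

    Vacated deep rows are padded with the noise floor; columns with no
    detected surface are filled entirely and flagged invalid.  Raises
    :class:`QCError` when fewer than ``min_valid_fraction`` of columns have a
    surface.
    """
    if surface.indices.shape != volume.data.shape[:2]:
        raise ValueError("surface map shape does not match volume")
    valid_fraction = 1.0 - surface.missing_fraction
    if valid_fraction < min_valid_fraction:
        raise QCError(
            f"surface detected on only {valid_fraction:.0%} of columns "
            f"(< {min_valid_fraction:.0%})"
        )
    fill = float(np.min(volume.data)) if noise_floor_db is None else noise_floor_db
    nz = volume.n_depth
    shift = np.where(surface.missing, nz, surface.indices)  # missing: push all out
    idx = shift[:, :, None] + np.arange(nz)[None, None, :]
    gathered = np.take_along_axis(volume.data, np.minimum(idx, nz - 1), axis=2)
    out_data = np.where(idx < nz, gathered, fill)
    out = volume.with_data(out_data)
    out.invalid_columns = surface.missing.copy()
    return out


def enface_projection(
    volume: OCTVolume,
    surface: SurfaceMap | None = None,
    band_px: tuple[int, int] = (0, 50),
    scale: str = "db",
) -> np.ndarray:
    """Project the volume to a 2-D (B-scan x lateral) en-face image.

    The projection averages a depth band; for surface-normalized volumes the
    band is absolute, otherwise a :class:`SurfaceMap` places it below the
    per-column surface.  ``scale="db"`` averages dB values, ``scale="linear"``
    averages linear intensities and re-expresses the mean in dB.
    """
    b0, b1 = band_px
    if b1 <= b0:
        raise ValueError(f"empty depth band {band_px}")
    if scale not in ("db", "linear"):
        raise ValueError("scale must be 'db' or 'linear'")
    values = volume.linear if scale == "linear" else volume.data
    nz = volume.n_depth
    if surface is None:
        band = values[:, :, max(b0, 0) : min(b1, nz)]
        if band.shape[2] == 0:
            raise ValueError("depth band lies outside the volume")
        img = band.mean(axis=2)
    else:
        base = np.where(surface.missing, 0, surface.indices)
        idx = np.clip(base[:, :, None] + np.arange(b0, b1)[None, None, :], 0, nz - 1)
        img = np.take_along_axis(values, idx, axis=2).mean(axis=2)
        img[surface.missing] = np.nan
    if scale == "linear":
        with np.errstate(divide="ignore"):
            img = 10.0 * np.log10(img)
    return img


def extract_subvolume(
    volume: OCTVolume,
    bscan_range: tuple[int, int],
    lateral_range: tuple[int, int] | None = None,
) -> OCTVolume:
    """Restrict the volume to a half-open ROI rectangle, keeping provenance."""
    b0, b1 = bscan_range
    x0, x1 = lateral_range if lateral_range is not None else (0, volume.n_lateral)
    if not (0 <= b0 < b1 <= volume.n_bscans and 0 <= x0 < x1 <= volume.n_lateral):
        raise ValueError(
            f"ROI b-scans [{b0},{b1}) x lateral [{x0},{x1}) outside volume "
            f"{volume.n_bscans} x {volume.n_lateral}"
        )
    out = volume.with_data(volume.data[b0:b1, x0:x1].copy())
    if volume.invalid_columns is not None:
        out.invalid_columns = volume.invalid_columns[b0:b1, x0:x1].copy()
    return out


def extract_patches(
    volume: OCTVolume,
    patch_size: tuple[int, int] = (144, 56),
    bscan_stride: int = 2,
    lateral_stride: int | None = None,
    noise_floor_db: float = 28.0,
    min_above_floor_fraction: float = 0.8,
    margin_db: float = 3.0,
    label: str | None = None,
) -> list[Patch]:
    """Tile surface-normalized B-scans into patches and keep the valid ones.

    A candidate is valid when it overlaps no invalid-flagged column and at
    least ``min_above_floor_fraction`` of its pixels lie ``margin_db`` above
    the noise floor (i.e. the patch contains tissue signal, not padding,
    artifact or empty frame).
    """
    n_lat, n_ax = patch_size
    lateral_stride = lateral_stride or n_lat
    if n_ax > volume.n_depth or n_lat > volume.n_lateral:
        return []
    patches: list[Patch] = []
    invalid = volume.invalid_columns
    for b in range(0, volume.n_bscans, bscan_stride):
        for x0 in range(0, volume.n_lateral - n_lat + 1, lateral_stride):
            if invalid is not None and invalid[b, x0 : x0 + n_lat].any():
                continue
            data = volume.data[b, x0 : x0 + n_lat, :n_ax]
            frac = float((data > noise_floor_db + margin_db).mean())
            if frac < min_above_floor_fraction:
                continue
            patches.append(
                Patch(
                    data=data.copy(),
                    axial_spacing_um=volume.axial_spacing_um,
                    lateral_spacing_um=volume.lateral_spacing_um,
                    patient_id=volume.patient_id,
                    scan_id=volume.scan_id,
                    bscan_index=b,
                    lateral_offset=x0,
                    label=label,
                )
            )
    return patches


def normalize_patch(patch: Patch | np.ndarray) -> Patch | np.ndarray:
    """Z-score a patch (zero mean, unit standard deviation)."""
    data = patch.data if isinstance(patch, Patch) else np.asarray(patch, dtype=float)
    sd = data.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant (zero-variance) patch")
    z = (data - data.mean()) / sd
    if isinstance(patch, Patch):
        return replace(patch, data=z)
    return z


def qc_scan(
    volume: OCTVolume,
    noise_floor_db: float | None = None,
    threshold_db: float = 10.0,
    top_rows: int = 5,
    fold_signal_db: float = 12.0,
    fold_fraction: float = 0.2,
    dropout_fraction: float = 0.3,
) -> set[str]:
    """Flag a raw scan as ok / fold_over / dropout.

    Fold-over: a large fraction of columns carry structured (well above
    floor) signal in the top rows, above the tissue surface.  Dropout: the
    fraction of columns with no detectable surface exceeds a threshold.
    """
    surface = detect_surface(volume, threshold_db, noise_floor_db)
    floor = _estimate_noise_floor_db(volume) if noise_floor_db is None else noise_floor_db
    flags: set[str] = set()
    if surface.missing_fraction > dropout_fraction:
        flags.add("dropout")
    smoothed = median_filter(
        volume.data[:, :, :top_rows], size=(1, 5, 1), mode="nearest"
    )
    strong_top = (smoothed.max(axis=2) > floor + fold_signal_db).mean()
    if strong_top > fold_fraction:
        flags.add("fold_over")
    return flags or {"ok"}
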