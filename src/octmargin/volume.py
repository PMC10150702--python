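"""The OCT volume container and its on-disk format.

A volume is a 3-D intensity array in dB, indexed ``(b_scan, lateral, depth)``
with depth increasing away from the objective.  On disk a volume is a
multi-page TIFF (one page per B-scan, 32-bit float dB) next to a JSON sidecar
with the spatial metadata and scan identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["OCTVolume", "write_volume", "read_volume"]

QC_FLAGS = {"ok", "fold_over", "dropout"}


@dataclass
class OCTVolume:
    """3-D OCT intensity volume in dB with spatial metadata and identity."""

    data: np.ndarray  # (n_bscans, lateral, depth), dB
    axial_spacing_um: float
    lateral_spacing_um: float
    patient_id: str = "P000"
    scan_id: str = "S000"
    qc_flags: set[str] = field(default_factory=set)
    #: columns flagged invalid, e.g. missing surface; shape (n_bscans, lateral)
    invalid_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.axial_spacing_um <= 0 or self.lateral_spacing_um <= 0:
            raise ValueError("pixel spacings must be > 0")
        unknown = self.qc_flags - QC_FLAGS
        if unknown:
            raise ValueError(f"unknown qc flags: {sorted(unknown)}")

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.data.shape[1]

    @property
    def n_depth(self) -> int:
        return self.data.shape[2]

    @property
    def linear(self) -> np.ndarray:
        """Intensity on the linear scale (dB = 10 log10 linear)."""
        return 10.0 ** (self.data / 10.0)

    def with_data(self, data: np.ndarray) -> "OCTVolume":
        """Copy of the volume with replaced intensity data."""
        out = replace(self, data=data)
        out.qc_flags = set(self.qc_flags)
        if self.invalid_columns is not None:
            out.invalid_columns = self.invalid_columns.copy()
        return out


def write_volume(volume: OCTVolume, directory: str | Path, stem: str | None = None) -> Path:
    """Write a volume as multi-page float32 TIFF plus JSON sidecar.

    Returns the TIFF path; the sidecar sits next to it as ``<stem>.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{volume.patient_id}_{volume.scan_id}"
    tiff_path = directory / f"{stem}.tiff"
    tifffile.imwrite(
        tiff_path, volume.data.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "axial_spacing_um": volume.axial_spacing_um,
        "lateral_spacing_um": volume.lateral_spacing_um,
        "patient_id": volume.patient_id,
        "scan_id": volume.scan_id,
        "qc_flags": sorted(volume.qc_flags),
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return tiff_path


def read_volume(tiff_path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`."""
    tiff_path = Path(tiff_path)
    data = np.asarray(tifffile.imread(tiff_path), dtype=np.float64)
    if data.ndim == 2:  # single-page volume
        data = data[None]
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    return OCTVolume(
        data=data,
        axial_spacing_um=float(sidecar["axial_spacing_um"]),
        lateral_spacing_um=float(sidecar["lateral_spacing_um"]),
        patient_id=str(sidecar["patient_id"]),
        scan_id=str(sidecar["scan_id"]),
        qc_flags=set(sidecar.get("qc_flags", [])),
    )
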