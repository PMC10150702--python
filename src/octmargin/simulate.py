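"""Physics-based synthetic OCT generator.

Generates labeled cohorts with the statistical structure the downstream
analysis assumes: exponential depth decay per tissue class, fully developed
(multiplicative exponential) speckle, system roll-off/focus sensitivity, an
additive detector noise floor, per-A-scan surface topography, a spatially
smooth heterogeneity field, Poisson-placed microstructure shadows, and
optional fold-over / signal-dropout artifacts for QC exercise.

All randomness flows through numpy Generators; a cohort is reproduced
bit-identically from its seed, and each scan's volume is regenerated on
demand from a per-scan child seed so large cohorts never need to be held in
memory at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .params import CohortSpec, SystemModel, TissueLabel, TissueParams, default_system, default_tissue_params
from .volume import OCTVolume, write_volume

__all__ = [
    "simulate_ascan",
    "simulate_bscan",
    "simulate_volume",
    "simulate_cohort",
    "read_scan_table",
    "inject_fold_over",
    "inject_dropout",
    "BScan",
    "SyntheticCohort",
    "SHADOW_ATTENUATION",
    "RESIDUAL_TUMOR_LABELS",
]

#: multiplicative attenuation applied below an occluding microstructure
SHADOW_ATTENUATION = 0.05
#: axial extent of the specular surface-reflection peak, micrometres
SURFACE_PEAK_UM = 12.0
#: shadow onset range below the surface, micrometres (near-surface occluders)
SHADOW_ONSET_UM = (60.0, 150.0)
#: correlation lengths of the heterogeneity field, pixels (lateral, depth)
HETEROGENEITY_SIGMA = (12.0, 6.0)
#: labels that count as residual tumor at patient level
RESIDUAL_TUMOR_LABELS = frozenset(
    {TissueLabel.WM0_30, TissueLabel.WM30_60, TissueLabel.WM60plus}
)


def _default_surface_px(system: SystemModel) -> int:
    # nominal surface ~120 um below the top of the frame
    return int(round(120.0 / system.axial_spacing_um))


def simulate_ascan(
    params: TissueParams,
    system: SystemModel,
    surface_px: int,
    rng: np.random.Generator | None = None,
    *,
    speckle: bool = True,
) -> np.ndarray:
    """Simulate one A-scan (depth profile) in dB.

    Below the surface the expected linear intensity is
    ``I * exp(-2 mu z) * rolloff(z) * focus(z)`` with z in mm from the
    surface; above the surface only the noise floor contributes.  Speckle is
    unit-mean multiplicative exponential noise.
    """
    if not isinstance(params, TissueParams):
        raise TypeError("params must be a TissueParams")
    if not (0 <= surface_px < system.depth_pixels):
        raise ValueError(
            f"surface_px {surface_px} outside [0, {system.depth_pixels})"
        )
    if speckle and rng is None:
        raise ValueError("rng is required when speckle is enabled")
    z_rel_mm = (np.arange(system.depth_pixels) - surface_px) * system.axial_spacing_um / 1000.0
    signal = 10.0 ** (params.intensity_db / 10.0) * np.exp(-2.0 * params.mu * z_rel_mm)
    peak = np.where(
        (z_rel_mm >= 0) & (z_rel_mm < SURFACE_PEAK_UM / 1000.0),
        10.0 ** (params.surface_reflection_db / 10.0),
        1.0,
    )
    signal = np.where(z_rel_mm >= 0, signal * peak, 0.0) * system.sensitivity
    floor = 10.0 ** (system.noise_floor_db / 10.0)
    if speckle:
        signal = signal * rng.exponential(1.0, signal.shape)
        noise = floor * rng.exponential(1.0, signal.shape)
    else:
        noise = floor
    return 10.0 * np.log10(signal + noise)


@dataclass
class BScan:
    """One simulated B-scan with its generative ground truth."""

    data: np.ndarray               # (lateral, depth), dB
    surface_px: np.ndarray         # per-column surface depth index
    shadow_columns: np.ndarray     # bool per column
    n_shadow_events: int = 0       # Poisson-drawn microstructure count


def _unit_std_smooth(field: np.ndarray, sigma) -> np.ndarray:
    smoothed = gaussian_filter(field, sigma, mode="reflect")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def simulate_bscan(
    params: TissueParams,
    system: SystemModel,
    rng: np.random.Generator,
    *,
    speckle: bool = True,
    base_surface_px: int | None = None,
) -> BScan:
    """Simulate a B-scan with surface jitter, heterogeneity and shadows.

    The heterogeneity field is spatially smooth multiplicative log-noise
    shared across the frame (correlation lengths of a few tens of
    micrometres); it also jitters the per-column attenuation so that
    heterogeneous classes show non-uniform penetration and reduced fit r^2.
    Shadow artifacts (count ~ Poisson(microstructure_rate)) attenuate one to
    three adjacent columns below a near-surface onset.
    """
    nx, nz = system.lateral_pixels, system.depth_pixels
    dz_mm = system.axial_spacing_um / 1000.0
    base = _default_surface_px(system) if base_surface_px is None else int(base_surface_px)
    if not (0 <= base < nz):
        raise ValueError("base_surface_px outside the depth range")

    rough_px = params.surface_roughness_um / system.axial_spacing_um
    if rough_px > 0:
        jitter = rng.normal(0.0, rough_px, nx)
        # gentle lateral correlation so the surface is a topography, not salt
        jitter = gaussian_filter1d(jitter, 2.0, mode="reflect")
        surf = np.clip(np.rint(base + jitter).astype(int), 0, nz - 1)
    else:
        surf = np.full(nx, base, dtype=int)

    h = params.heterogeneity
    if h > 0:
        field = _unit_std_smooth(rng.standard_normal((nx, nz)), HETEROGENEITY_SIGMA)
        mu_jit = _unit_std_smooth(rng.standard_normal(nx), HETEROGENEITY_SIGMA[0])
        mu_col = params.mu * np.clip(1.0 + 0.5 * h * mu_jit, 0.05, None)
        log_factor = h * field
    else:
        mu_col = np.full(nx, params.mu)
        log_factor = 0.0

    z_rel = (np.arange(nz)[None, :] - surf[:, None]) * dz_mm
    signal = (
        10.0 ** (params.intensity_db / 10.0)
        * np.exp(log_factor)
        * np.exp(-2.0 * mu_col[:, None] * z_rel)
    )
    peak = np.where(
        (z_rel >= 0) & (z_rel < SURFACE_PEAK_UM / 1000.0),
        10.0 ** (params.surface_reflection_db / 10.0),
        1.0,
    )
    signal = np.where(z_rel >= 0, signal * peak, 0.0) * system.sensitivity[None, :]
    if speckle:
        signal = signal * rng.exponential(1.0, signal.shape)

    shadow_cols = np.zeros(nx, dtype=bool)
    n_shadows = rng.poisson(params.microstructure_rate)
    for _ in range(n_shadows):
        x0 = int(rng.integers(0, nx))
        width = int(rng.integers(1, 4))
        onset_um = rng.uniform(*SHADOW_ONSET_UM)
        for x in range(x0, min(x0 + width, nx)):
            start = surf[x] + int(round(onset_um / system.axial_spacing_um))
            if start < nz:
                signal[x, start:] *= SHADOW_ATTENUATION
                shadow_cols[x] = True

    floor = 10.0 ** (system.noise_floor_db / 10.0)
    noise = floor * rng.exponential(1.0, signal.shape) if speckle else floor
    return BScan(
        data=10.0 * np.log10(signal + noise),
        surface_px=surf,
        shadow_columns=shadow_cols,
        n_shadow_events=int(n_shadows),
    )


def inject_fold_over(volume: OCTVolume, base_surface_px: int) -> OCTVolume:
    """Mirror below-surface signal into the rows above the surface.

    Emulates the zero-delay wrap-around ("fold-over") artifact: the strong
    signal just below the surface reappears, mirrored, in the empty rows at
    the top of the frame.
    """
    k = min(max(base_surface_px - 2, 2), volume.n_depth // 4)
    lin = volume.linear
    seg = lin[:, :, base_surface_px : base_surface_px + k]
    lin[:, :, :k] = lin[:, :, :k] + seg[:, :, ::-1]
    out = volume.with_data(10.0 * np.log10(lin))
    return out


def inject_dropout(
    volume: OCTVolume,
    rng: np.random.Generator,
    noise_floor_db: float,
    fraction: float = 0.5,
) -> OCTVolume:
    """Replace a contiguous lateral block of columns with pure noise floor."""
    nx = volume.n_lateral
    width = max(1, int(round(fraction * nx)))
    start = int(rng.integers(0, nx - width + 1))
    lin = volume.linear
    floor = 10.0 ** (noise_floor_db / 10.0)
    lin[:, start : start + width, :] = floor * rng.exponential(
        1.0, lin[:, start : start + width, :].shape
    )
    return volume.with_data(10.0 * np.log10(lin))


@dataclass
class VolumeTruth:
    """Generative ground truth for one simulated volume scan."""

    label: TissueLabel
    mu: float
    intensity_db: float
    base_surface_px: int
    n_shadow_columns: int
    artifact: str  # 'none' | 'fold_over' | 'dropout'


def simulate_volume(
    params: TissueParams,
    system: SystemModel,
    n_bscans: int,
    rng: np.random.Generator,
    *,
    speckle: bool = True,
    artifact: str = "none",
    patient_id: str = "P000",
    scan_id: str = "S000",
) -> tuple[OCTVolume, VolumeTruth]:
    """Simulate a subvolume of ``n_bscans`` sequential B-scans."""
    if artifact not in ("none", "fold_over", "dropout"):
        raise ValueError(f"unknown artifact kind {artifact!r}")
    base = _default_surface_px(system)
    frames = [
        simulate_bscan(params, system, rng, speckle=speckle, base_surface_px=base)
        for _ in range(n_bscans)
    ]
    volume = OCTVolume(
        data=np.stack([f.data for f in frames]),
        axial_spacing_um=system.axial_spacing_um,
        lateral_spacing_um=system.lateral_spacing_um,
        patient_id=patient_id,
        scan_id=scan_id,
    )
    if artifact == "fold_over":
        volume = inject_fold_over(volume, base)
    elif artifact == "dropout":
        volume = inject_dropout(volume, rng, system.noise_floor_db)
    truth = VolumeTruth(
        label=params.label,
        mu=params.mu,
        intensity_db=params.intensity_db,
        base_surface_px=base,
        n_shadow_columns=int(sum(f.shadow_columns.sum() for f in frames)),
        artifact=artifact,
    )
    return volume, truth


class SyntheticCohort:
    """A lazily generated, fully reproducible synthetic scan cohort.

    The scan table (patient, scan, label, true optical properties, injected
    artifact) is drawn once from the cohort seed; each volume is regenerated
    deterministically from a per-scan child seed via :meth:`volume`.
    """

    def __init__(
        self,
        spec: CohortSpec,
        class_params: dict[TissueLabel, TissueParams],
        system: SystemModel,
    ) -> None:
        self.spec = spec
        self.class_params = class_params
        self.system = system
        self.scans = self._draw_scan_table()

    def _draw_scan_table(self) -> pd.DataFrame:
        spec = self.spec
        mix_labels = [lab for lab, p in spec.label_mix.items() if p > 0]
        missing = [lab for lab in mix_labels if lab not in self.class_params]
        if missing:
            raise ValueError(
                f"class_params missing labels requested by label_mix: {missing}"
            )
        probs = np.array([spec.label_mix[lab] for lab in mix_labels], dtype=float)
        probs = probs / probs.sum()
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
        rows = []
        idx = 0
        for p in range(spec.n_patients):
            pid = f"P{p + 1:03d}"
            n_scans = spec.scans_per_patient + (1 if spec.tumor_surface_scans else 0)
            for s in range(n_scans):
                surface_scan = spec.tumor_surface_scans and s == spec.scans_per_patient
                if surface_scan:
                    label = TissueLabel.WM60plus  # tumor-surface reference scan
                else:
                    label = mix_labels[int(rng.choice(len(mix_labels), p=probs))]
                if rng.random() < spec.artifact_fraction:
                    artifact = "fold_over" if rng.random() < 0.5 else "dropout"
                else:
                    artifact = "none"
                params = self.class_params[label]
                rows.append(
                    {
                        "scan_index": idx,
                        "patient_id": pid,
                        "scan_id": f"S{s + 1:02d}",
                        "label": label.value,
                        "true_mu": params.mu,
                        "true_intensity_db": params.intensity_db,
                        "artifact": artifact,
                        "tumor_surface": surface_scan,
                    }
                )
                idx += 1
        return pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.scans)

    def volume(self, scan_index: int) -> tuple[OCTVolume, VolumeTruth]:
        """Regenerate the volume for one scan-table row, deterministically."""
        row = self.scans.iloc[scan_index]
        rng = np.random.default_rng(
            np.random.SeedSequence(self.spec.seed, spawn_key=(1, int(row["scan_index"])))
        )
        params = self.class_params[TissueLabel(row["label"])]
        return simulate_volume(
            params,
            self.system,
            self.spec.bscans_per_subvolume,
            rng,
            artifact=str(row["artifact"]),
            patient_id=str(row["patient_id"]),
            scan_id=str(row["scan_id"]),
        )

    def volumes(self):
        """Iterate ``(OCTVolume, VolumeTruth)`` over the whole cohort."""
        for i in range(len(self)):
            yield self.volume(i)

    def patient_truth(self) -> pd.DataFrame:
        """Patient-level residual-tumor truth: residual iff any scan is infiltrated."""
        residual_values = {lab.value for lab in RESIDUAL_TUMOR_LABELS}
        grouped = self.scans.groupby("patient_id")["label"].agg(
            lambda labels: "residual" if any(l in residual_values for l in labels) else "clear"
        )
        return grouped.rename("truth").reset_index()

    def write(self, directory: str | Path, *, tables_only: bool = False) -> Path:
        """Write scan/truth tables (CSV) and, optionally, all volumes (TIFF+JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scans.to_csv(directory / "scans.csv", index=False, float_format="%.17g")
        self.patient_truth().to_csv(directory / "patients.csv", index=False)
        if not tables_only:
            for vol, _ in self.volumes():
                write_volume(vol, directory / "volumes")
        return directory


def read_scan_table(path) -> pd.DataFrame:
    """Read a scans.csv written by :meth:`SyntheticCohort.write` losslessly."""
    return pd.read_csv(path, float_precision="round_trip")


def simulate_cohort(
    spec: CohortSpec | None = None,
    class_params: dict[TissueLabel, TissueParams] | None = None,
    system: SystemModel | None = None,
) -> SyntheticCohort:
    """Build a synthetic cohort from a spec (defaults: 21 patients x 5 scans)."""
    return SyntheticCohort(
        spec or CohortSpec(),
        class_params or default_tissue_params(),
        system or default_system(),
    )
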