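"""Tissue classes, tissue/system parameters and cohort specification.

The forward model throughout the package is single-scattering exponential
decay of backscattered intensity below the tissue surface,

    A^2(z) = I * exp(-2 mu z),

with ``mu`` the attenuation coefficient (mm^-1), ``I`` the peak backscattered
intensity and ``z`` the depth from the surface in mm.  Absolute attenuation
values at 830 nm are not standardized across systems, so the defaults here fix
healthy white matter at 6.0 mm^-1 and anchor the other classes by the relative
differences the field reports: gray matter 56% lower than healthy white
matter, edematous white matter about 40% lower, and a monotone decrease with
increasing tumor infiltration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "TissueLabel",
    "TissueParams",
    "SystemModel",
    "CohortSpec",
    "DISPLAY_MIN_DB",
    "DISPLAY_MAX_DB",
    "BENIGN_TO_MALIGNANT",
    "default_tissue_params",
    "default_system",
]

#: dB display range used by the qualitative criteria ("deep red" vs "deep blue").
DISPLAY_MIN_DB = 40.0
DISPLAY_MAX_DB = 70.0


class TissueLabel(str, Enum):
    """Six-class histopathology label at the resection edge."""

    GM0 = "GM0"            # gray matter, 0% tumor infiltration
    WM0 = "WM0"            # healthy white matter
    WM0_30 = "WM0-30"      # white matter, 0-30% infiltration
    WM30_60 = "WM30-60"    # white matter, 30-60% infiltration
    WM60plus = "WM>60"     # white matter, >60% infiltration
    WME = "WME"            # edematous white matter

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Label ordering from benign to malignant, used for agreement heatmaps.
BENIGN_TO_MALIGNANT = (
    TissueLabel.GM0,
    TissueLabel.WM0,
    TissueLabel.WME,
    TissueLabel.WM0_30,
    TissueLabel.WM30_60,
    TissueLabel.WM60plus,
)


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class TissueParams:
    """Per-class generative parameters of the synthetic tissue model.

    Parameters
    ----------
    label
        Histology class the parameters describe.
    mu
        Attenuation coefficient, mm^-1 (>= 0).
    intensity_db
        Mean peak backscattered intensity at the surface, dB. Constrained to
        the display range [40, 70] dB by default.
    heterogeneity
        Standard deviation of the per-A-scan log-intensity fluctuation field
        (natural-log units, dimensionless). Drives lateral signal variation,
        penetration non-uniformity and the depth structure that lowers the
        fit r^2.
    surface_roughness_um
        Standard deviation of the per-A-scan surface depth, micrometres.
    microstructure_rate
        Expected number of shadow artifacts (occluding microstructures such
        as vessels or calcifications) per B-scan; Poisson-distributed.
    surface_reflection_db
        Specular enhancement of the first ~12 um below the surface, dB.
        Models the strong index-mismatch reflection at the tissue interface;
        it anchors the A-scan maximum at the surface, which is why the fit
        window starts 20 um after the maximum.
    """

    label: TissueLabel
    mu: float
    intensity_db: float
    heterogeneity: float = 0.0
    surface_roughness_um: float = 10.0
    microstructure_rate: float = 0.0
    surface_reflection_db: float = 4.0

    def __post_init__(self) -> None:
        _require_finite(
            "TissueParams",
            self.mu,
            self.intensity_db,
            self.heterogeneity,
            self.surface_roughness_um,
            self.microstructure_rate,
        )
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if not (DISPLAY_MIN_DB <= self.intensity_db <= DISPLAY_MAX_DB):
            raise ValueError(
                f"intensity_db {self.intensity_db} outside display range "
                f"[{DISPLAY_MIN_DB}, {DISPLAY_MAX_DB}] dB"
            )
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.surface_roughness_um < 0:
            raise ValueError("surface_roughness_um must be >= 0")
        if self.microstructure_rate < 0:
            raise ValueError("microstructure_rate must be >= 0")
        _require_finite("TissueParams", self.surface_reflection_db)
        if self.surface_reflection_db < 0:
            raise ValueError("surface_reflection_db must be >= 0")


#: Relative attenuation anchors (ratio to healthy white matter).
GM_TO_WM_MU_RATIO = 0.44
WME_TO_WM_MU_RATIO = 0.60


def default_tissue_params(wm_mu: float = 6.0) -> dict[TissueLabel, TissueParams]:
    """Default per-class generative parameters.

    ``wm_mu`` sets the absolute attenuation of healthy white matter; the
    other classes follow the relative anchors (gray matter 0.44x, edema
    0.60x) and a monotone decrease with infiltration grade, all below the
    edema value.
    """
    mk = TissueParams
    return {
        TissueLabel.WM0: mk(TissueLabel.WM0, mu=wm_mu, intensity_db=67.0,
                            heterogeneity=0.05, surface_roughness_um=10.0),
        TissueLabel.GM0: mk(TissueLabel.GM0, mu=GM_TO_WM_MU_RATIO * wm_mu,
                            intensity_db=53.0, heterogeneity=0.10,
                            surface_roughness_um=10.0),
        TissueLabel.WME: mk(TissueLabel.WME, mu=WME_TO_WM_MU_RATIO * wm_mu,
                            intensity_db=52.0, heterogeneity=0.10,
                            surface_roughness_um=10.0),
        TissueLabel.WM0_30: mk(TissueLabel.WM0_30, mu=0.50 * wm_mu,
                               intensity_db=54.0, heterogeneity=0.35,
                               surface_roughness_um=15.0,
                               microstructure_rate=2.0),
        TissueLabel.WM30_60: mk(TissueLabel.WM30_60, mu=0.43 * wm_mu,
                                intensity_db=52.0, heterogeneity=0.45,
                                surface_roughness_um=15.0,
                                microstructure_rate=3.0),
        TissueLabel.WM60plus: mk(TissueLabel.WM60plus, mu=1.0 / 3.0 * wm_mu,
                                 intensity_db=50.0, heterogeneity=0.50,
                                 surface_roughness_um=20.0,
                                 microstructure_rate=4.0),
    }


@dataclass(frozen=True)
class SystemModel:
    """Geometry and depth-dependent sensitivity of the OCT system.

    The roll-off and focus profiles are strictly positive per-depth-pixel
    multiplicative sensitivities; acquisition multiplies the tissue signal by
    them and preprocessing divides them back out.
    """

    axial_spacing_um: float = 6.0
    lateral_spacing_um: float = 15.0
    depth_pixels: int = 256
    lateral_pixels: int = 160
    noise_floor_db: float = 28.0
    rolloff_profile: np.ndarray | None = None
    focus_profile: np.ndarray | None = None
    # metadata (not used numerically)
    central_wavelength_nm: float = 830.0
    axial_resolution_um: float = 8.0
    lateral_resolution_um: float = 23.0

    def __post_init__(self) -> None:
        if self.axial_spacing_um <= 0 or self.lateral_spacing_um <= 0:
            raise ValueError("pixel spacings must be > 0")
        if self.depth_pixels < 1 or self.lateral_pixels < 1:
            raise ValueError("image dimensions must be >= 1")
        for name in ("rolloff_profile", "focus_profile"):
            prof = getattr(self, name)
            if prof is not None:
                prof = np.asarray(prof, dtype=float)
                if prof.shape != (self.depth_pixels,):
                    raise ValueError(
                        f"{name} must have length depth_pixels="
                        f"{self.depth_pixels}, got {prof.shape}"
                    )
                if not np.all(np.isfinite(prof)) or np.any(prof <= 0):
                    raise ValueError(f"{name} must be strictly positive and finite")
                object.__setattr__(self, name, prof)

    @property
    def rolloff(self) -> np.ndarray:
        """Roll-off sensitivity; default 6 dB exponential loss over full depth."""
        if self.rolloff_profile is not None:
            return self.rolloff_profile
        frac = np.arange(self.depth_pixels) / max(self.depth_pixels - 1, 1)
        return 10.0 ** (-6.0 * frac / 10.0)

    @property
    def focus(self) -> np.ndarray:
        """Focus sensitivity; default Gaussian with waist at 1/3 depth, floor 0.7."""
        if self.focus_profile is not None:
            return self.focus_profile
        z = np.arange(self.depth_pixels, dtype=float)
        zf = self.depth_pixels / 3.0
        sigma = self.depth_pixels / 2.0
        return 0.7 + 0.3 * np.exp(-0.5 * ((z - zf) / sigma) ** 2)

    @property
    def sensitivity(self) -> np.ndarray:
        """Combined roll-off x focus profile."""
        return self.rolloff * self.focus

    def with_flat_profiles(self) -> "SystemModel":
        """Copy of the system with unit roll-off and focus (for identities)."""
        ones = np.ones(self.depth_pixels)
        return replace(self, rolloff_profile=ones, focus_profile=ones.copy())

    def depth_mm(self, n: float = 1.0) -> np.ndarray:
        """Physical depth axis in mm for refractive index ``n``."""
        return np.arange(self.depth_pixels) * self.axial_spacing_um / 1000.0 / n


def default_system(**overrides) -> SystemModel:
    """The default system model (830 nm spectral-domain geometry)."""
    return SystemModel(**overrides)


@dataclass(frozen=True)
class CohortSpec:
    """Size, composition and artifact burden of a synthetic cohort."""

    n_patients: int = 21
    scans_per_patient: int = 5
    bscans_per_subvolume: int = 40
    label_mix: dict[TissueLabel, float] = field(
        default_factory=lambda: {
            TissueLabel.GM0: 0.15,
            TissueLabel.WM0: 0.25,
            TissueLabel.WM0_30: 0.15,
            TissueLabel.WM30_60: 0.10,
            TissueLabel.WM60plus: 0.20,
            TissueLabel.WME: 0.15,
        }
    )
    artifact_fraction: float = 0.6
    tumor_surface_scans: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "scans_per_patient", "bscans_per_subvolume"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.label_mix:
            raise ValueError("label_mix must not be empty")
        total = sum(self.label_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"label_mix proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.label_mix.values()):
            raise ValueError("label_mix proportions must be >= 0")
        if not (0.0 <= self.artifact_fraction <= 1.0):
            raise ValueError("artifact_fraction must be in [0, 1]")
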