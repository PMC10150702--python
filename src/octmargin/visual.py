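"""Five-criterion qualitative assessment and the flowchart classifier.

The rule set mirrors how a trained observer reads a resection-edge scan:
signal intensity is the major criterion (high intensity means myelinated
white matter), and only for low-intensity scans do the four additional
criteria (homogeneity, penetration depth, uniformity of penetration,
microstructure shadows) refine the call into one of five classes from
"rather not tumorous" to "tumorous".

``grade_criteria`` is an automated surrogate for the human grading so the
flowchart is testable end-to-end on simulated volumes; every threshold it
uses is plain configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter, uniform_filter1d

from .preprocess import QCError
from .volume import OCTVolume

__all__ = [
    "Intensity",
    "Homogeneity",
    "Penetration",
    "Uniformity",
    "Microstructures",
    "CriteriaAssessment",
    "VisualClass",
    "VISUAL_BENIGN_TO_MALIGNANT",
    "GradingConfig",
    "classify_visual",
    "binarize_visual",
    "grade_criteria",
    "measure_criteria",
    "observer_agreement",
]


class Intensity(str, Enum):
    HIGH = "high"
    LOW = "low"


class Homogeneity(str, Enum):
    HOMOGENEOUS = "homogeneous"
    HETEROGENEOUS = "heterogeneous"


class Penetration(str, Enum):
    HIGH = "high"
    LOW = "low"


class Uniformity(str, Enum):
    UNIFORM = "uniform"
    NON_UNIFORM = "non_uniform"


class Microstructures(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"


@dataclass(frozen=True)
class CriteriaAssessment:
    """The five qualitative gradings of one subvolume."""

    intensity: Intensity
    homogeneity: Homogeneity
    penetration: Penetration
    uniformity: Uniformity
    microstructures: Microstructures

    def __post_init__(self) -> None:
        for name, enum_type in (
            ("intensity", Intensity),
            ("homogeneity", Homogeneity),
            ("penetration", Penetration),
            ("uniformity", Uniformity),
            ("microstructures", Microstructures),
        ):
            value = getattr(self, name)
            if not isinstance(value, enum_type):
                object.__setattr__(self, name, enum_type(value))


class VisualClass(str, Enum):
    WHITE_MATTER = "white_matter"
    RATHER_NOT_TUMOROUS = "rather_not_tumorous"
    RATHER_TUMOROUS_GRAY_MATTER = "rather_tumorous_gray_matter"
    RATHER_TUMOROUS = "rather_tumorous"
    TUMOROUS = "tumorous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: class ordering from benign to malignant, used for agreement heatmaps
VISUAL_BENIGN_TO_MALIGNANT = (
    VisualClass.WHITE_MATTER,
    VisualClass.RATHER_NOT_TUMOROUS,
    VisualClass.RATHER_TUMOROUS_GRAY_MATTER,
    VisualClass.RATHER_TUMOROUS,
    VisualClass.TUMOROUS,
)


def classify_visual(c: CriteriaAssessment) -> VisualClass:
    """Total, deterministic flowchart over the 32 criteria combinations.

    High intensity dominates (white matter).  Among low-intensity scans, the
    all-benign additional pattern is "rather not tumorous", the
    homogeneous/deep/uniform/shadow-free pattern is "rather tumorous / gray
    matter", the fully malignant pattern is "tumorous", and every other
    combination is "rather tumorous".
    """
    if c.intensity is Intensity.HIGH:
        return VisualClass.WHITE_MATTER
    key = (c.homogeneity, c.penetration, c.uniformity, c.microstructures)
    if key == (Homogeneity.HOMOGENEOUS, Penetration.LOW, Uniformity.UNIFORM,
               Microstructures.ABSENT):
        return VisualClass.RATHER_NOT_TUMOROUS
    if key == (Homogeneity.HOMOGENEOUS, Penetration.HIGH, Uniformity.UNIFORM,
               Microstructures.ABSENT):
        return VisualClass.RATHER_TUMOROUS_GRAY_MATTER
    if key == (Homogeneity.HETEROGENEOUS, Penetration.HIGH,
               Uniformity.NON_UNIFORM, Microstructures.PRESENT):
        return VisualClass.TUMOROUS
    return VisualClass.RATHER_TUMOROUS


def binarize_visual(v: VisualClass, gray_matter_as_tumor: bool = True) -> str:
    """Collapse the five classes to a tumor / non-tumor call.

    The "rather tumorous / gray matter" class maps to tumor by default (its
    name leads with "rather tumorous"); the mapping is configurable because
    gray matter itself is healthy tissue.
    """
    if v in (VisualClass.WHITE_MATTER, VisualClass.RATHER_NOT_TUMOROUS):
        return "non_tumor"
    if v is VisualClass.RATHER_TUMOROUS_GRAY_MATTER and not gray_matter_as_tumor:
        return "non_tumor"
    return "tumor"


@dataclass(frozen=True)
class GradingConfig:
    """Thresholds of the automated criteria-grading surrogate.

    ``intensity_db`` splits high/low signal at the midpoint of the 70 dB
    ("deep red") and 40 dB ("deep blue") display anchors; ``penetration_um``
    is the 500 um signal-depth criterion, measured against the display
    visibility floor ``visibility_db``; homogeneity thresholds the
    coefficient of variation of the (smoothed, linear-scale) en-face image;
    uniformity thresholds the lateral standard deviation of the per-column
    penetration depth; microstructures are counted as columns whose
    below-surface band intensity falls ``shadow_db`` under the local lateral
    median.
    """

    intensity_db: float = 55.0
    penetration_um: float = 500.0
    visibility_db: float = 40.0
    homogeneity_cv: float = 0.10
    uniformity_um: float = 100.0
    shadow_db: float = 5.0
    noise_floor_db: float = 28.0
    #: band for the intensity criterion, below the specular surface peak
    near_surface_band_um: tuple[float, float] = (18.0, 66.0)
    enface_band_um: float = 300.0
    shadow_band_um: tuple[float, float] = (100.0, 450.0)


def measure_criteria(volume: OCTVolume, config: GradingConfig = GradingConfig()) -> dict:
    """Continuous measurements behind the five gradings of a normalized subvolume."""
    if volume.qc_flags & {"fold_over", "dropout"}:
        raise QCError(f"cannot grade a QC-failed scan (flags={sorted(volume.qc_flags)})")
    ax = volume.axial_spacing_um
    linear = volume.linear
    valid = (
        ~volume.invalid_columns
        if volume.invalid_columns is not None
        else np.ones(linear.shape[:2], dtype=bool)
    )
    if not valid.any():
        raise QCError("no valid columns to grade")

    # (1) signal intensity: median near-surface column intensity, linear mean -> dB
    n0 = int(round(config.near_surface_band_um[0] / ax))
    n1 = max(n0 + 1, int(round(config.near_surface_band_um[1] / ax)))
    near_db = 10.0 * np.log10(linear[:, :, n0:n1].mean(axis=2))
    intensity_db = float(np.median(near_db[valid]))

    # (3)+(4) penetration: depth at which the laterally/axially smoothed
    # linear profile drops below the visibility floor
    smoothed = uniform_filter1d(linear, 9, axis=1, mode="nearest")
    smoothed = uniform_filter1d(smoothed, 5, axis=2, mode="nearest")
    vis = smoothed > 10.0 ** (config.visibility_db / 10.0)
    depth_idx = vis.shape[2] - 1 - vis[:, :, ::-1].argmax(axis=2)  # last visible row
    depth_idx[~vis.any(axis=2)] = 0
    depths_um = depth_idx.astype(float) * ax
    penetration_um = float(np.median(depths_um[valid]))
    uniformity_um = float(np.std(depths_um[valid]))

    # (2) homogeneity: CV of the smoothed linear en-face image
    n_band = max(1, int(round(config.enface_band_um / ax)))
    enface = linear[:, :, :n_band].mean(axis=2)
    enface = uniform_filter(enface, size=5, mode="nearest")
    vals = enface[valid]
    homogeneity_cv = float(vals.std() / vals.mean())

    # (5) microstructures: columns shadowed well below the local lateral median
    b0 = int(round(config.shadow_band_um[0] / ax))
    b1 = max(b0 + 1, int(round(config.shadow_band_um[1] / ax)))
    band_db = 10.0 * np.log10(linear[:, :, b0:b1].mean(axis=2))
    local_med = median_filter(band_db, size=(1, 25), mode="nearest")
    shadowed = (band_db < local_med - config.shadow_db) & valid
    return {
        "intensity_db": intensity_db,
        "penetration_um": penetration_um,
        "penetration_sd_um": uniformity_um,
        "homogeneity_cv": homogeneity_cv,
        "shadow_column_count": int(shadowed.sum()),
    }


def grade_criteria(volume: OCTVolume, config: GradingConfig = GradingConfig()) -> CriteriaAssessment:
    """Grade a surface-normalized, QC-ok subvolume into the five criteria."""
    m = measure_criteria(volume, config)
    return CriteriaAssessment(
        intensity=Intensity.HIGH if m["intensity_db"] >= config.intensity_db else Intensity.LOW,
        homogeneity=(
            Homogeneity.HETEROGENEOUS
            if m["homogeneity_cv"] > config.homogeneity_cv
            else Homogeneity.HOMOGENEOUS
        ),
        penetration=(
            Penetration.HIGH
            if m["penetration_um"] > config.penetration_um
            else Penetration.LOW
        ),
        uniformity=(
            Uniformity.NON_UNIFORM
            if m["penetration_sd_um"] > config.uniformity_um
            else Uniformity.UNIFORM
        ),
        microstructures=(
            Microstructures.PRESENT
            if m["shadow_column_count"] > 0
            else Microstructures.ABSENT
        ),
    )


def observer_agreement(
    class_a: list[VisualClass],
    class_b: list[VisualClass],
) -> tuple[pd.DataFrame, float | None]:
    """Cross-tabulate two observers' calls and compute Cohen's kappa.

    Returns the agreement table (rows observer A, columns observer B, both
    ordered benign to malignant) and kappa in [-1, 1]; kappa is None when
    chance agreement is exactly 1 (single-class degenerate case).
    """
    if len(class_a) != len(class_b):
        raise ValueError(f"length mismatch: {len(class_a)} vs {len(class_b)}")
    order = [v.value for v in VISUAL_BENIGN_TO_MALIGNANT]
    a = pd.Categorical([VisualClass(v).value for v in class_a], categories=order)
    b = pd.Categorical([VisualClass(v).value for v in class_b], categories=order)
    table = pd.crosstab(a, b, rownames=["observer_a"], colnames=["observer_b"],
                        dropna=False)
    table = table.reindex(index=order, columns=order, fill_value=0)
    n = len(class_a)
    if n == 0:
        return table, None
    counts = table.to_numpy()
    po = np.trace(counts) / n
    pe = float((counts.sum(axis=1) / n) @ (counts.sum(axis=0) / n))
    if pe == 1.0:
        return table, None
    return table, float((po - pe) / (1.0 - pe))
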