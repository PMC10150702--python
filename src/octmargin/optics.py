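"""Optical-property extraction from B-scan patches and group statistics.

Each patch is averaged laterally (in linear units) to a single depth
profile, the profile is log-transformed, and an ordinary least-squares line
is fitted in a window that starts 20 um after the intensity maximum and runs
for 300 um.  For the single-scattering model A^2(z) = I exp(-2 mu z) the
natural log is exactly linear in depth, so the slope b and intercept a give

    mu = -b / 2   (mm^-1, z in mm),    I = exp(a).

The coefficient of determination r^2 = 1 - SS_res / SS_tot of the same fit
serves as a homogeneity proxy: structured deviations from exponential decay
(heterogeneous tissue) lower it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Patch

__all__ = [
    "AScanProfile",
    "FitWindow",
    "OpticalProperties",
    "InsufficientDepthError",
    "average_patch_to_ascan",
    "select_fit_window",
    "fit_optical_properties",
    "fit_patch",
    "fit_patch_table",
    "compare_groups",
    "significance_stars",
]

LN10_OVER_10 = math.log(10.0) / 10.0


class InsufficientDepthError(ValueError):
    """Profile too short to place the fit window after its maximum."""


@dataclass
class AScanProfile:
    """Laterally averaged A-scan: depth z (mm, from surface) vs ln intensity."""

    z_mm: np.ndarray
    log_intensity: np.ndarray
    patient_id: str = "P000"
    scan_id: str = "S000"

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.log_intensity = np.asarray(self.log_intensity, dtype=float)
        if self.z_mm.shape != self.log_intensity.shape or self.z_mm.ndim != 1:
            raise ValueError("z and log-intensity must be 1-D arrays of equal length")
        if len(self.z_mm) >= 2 and not np.all(np.diff(self.z_mm) > 0):
            raise ValueError("depth axis must be strictly increasing")
        if not np.all(np.isfinite(self.log_intensity)):
            raise ValueError("log-intensity must be finite")

    @property
    def spacing_mm(self) -> float:
        return float(self.z_mm[1] - self.z_mm[0])


@dataclass(frozen=True)
class FitWindow:
    """Half-open sample window [start, stop) of the log-linear fit."""

    start: int
    stop: int

    @property
    def n(self) -> int:
        return self.stop - self.start

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"fit window needs >= 3 samples, has {self.n}")
        if self.start < 0:
            raise ValueError("fit window start must be >= 0")


@dataclass(frozen=True)
class OpticalProperties:
    """The (mu, I, r^2) triple extracted from one averaged A-scan."""

    mu: float                  # attenuation coefficient, mm^-1
    intensity: float           # peak backscatter, linear units
    r2: float | None           # None when SS_tot = 0 (undefined)

    @property
    def intensity_db(self) -> float:
        return 10.0 * math.log10(self.intensity)


def average_patch_to_ascan(patch: Patch, refractive_index: float = 1.0) -> AScanProfile:
    """Average a patch laterally (linear units) and log-transform.

    The depth axis converts pixel pitch (optical path in air) to physical
    depth via the configured refractive index.
    """
    linear = 10.0 ** (patch.data / 10.0)
    mean_profile = linear.mean(axis=0)
    z_mm = (
        np.arange(patch.data.shape[1])
        * patch.axial_spacing_um
        / 1000.0
        / refractive_index
    )
    return AScanProfile(
        z_mm=z_mm,
        log_intensity=np.log(mean_profile),
        patient_id=patch.patient_id,
        scan_id=patch.scan_id,
    )


def select_fit_window(
    profile: AScanProfile,
    start_offset_um: float = 20.0,
    length_um: float = 300.0,
) -> FitWindow:
    """Window starting ``start_offset_um`` after the profile maximum.

    The start index is rounded up to the next sample; the length is
    ``floor(length_um / spacing)`` samples; ties in the maximum break to the
    shallowest sample.
    """
    spacing_um = profile.spacing_mm * 1000.0
    i_max = int(np.argmax(profile.log_intensity))
    start = i_max + math.ceil(start_offset_um / spacing_um)
    n = math.floor(length_um / spacing_um)
    stop = start + n
    if stop > len(profile.z_mm):
        raise InsufficientDepthError(
            f"profile {profile.patient_id}/{profile.scan_id}: needs "
            f"{stop} samples past the maximum at index {i_max}, has "
            f"{len(profile.z_mm)}"
        )
    return FitWindow(start=start, stop=stop)


def fit_optical_properties(profile: AScanProfile, window: FitWindow) -> OpticalProperties:
    """Ordinary least squares of log intensity on depth within the window."""
    z = profile.z_mm[window.start : window.stop]
    y = profile.log_intensity[window.start : window.stop]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return OpticalProperties(mu=0.0, intensity=float(np.exp(y.mean())), r2=None)
    slope, intercept = np.polyfit(z, y, 1)
    fitted = slope * z + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return OpticalProperties(mu=-slope / 2.0, intensity=float(np.exp(intercept)), r2=r2)


def fit_patch(patch: Patch, refractive_index: float = 1.0) -> OpticalProperties:
    """Full per-patch pipeline: average, select window, fit."""
    profile = average_patch_to_ascan(patch, refractive_index)
    return fit_optical_properties(profile, select_fit_window(profile))


def fit_patch_table(
    patches, refractive_index: float = 1.0, on_short_profile: str = "skip"
) -> pd.DataFrame:
    """Fit a list of patches into a tidy per-patch properties table.

    Patches whose averaged profile cannot hold the fit window (the maximum
    sits too deep) are skipped by default; pass ``on_short_profile="raise"``
    to propagate the error instead.
    """
    rows = []
    for p in patches:
        try:
            props = fit_patch(p, refractive_index)
        except InsufficientDepthError:
            if on_short_profile == "raise":
                raise
            continue
        rows.append(
            {
                "patient_id": p.patient_id,
                "scan_id": p.scan_id,
                "label": p.label,
                "mu": props.mu,
                "intensity": props.intensity,
                "intensity_db": props.intensity_db,
                "r2": props.r2,
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star coding: *** < 0.001, ** < 0.01, * < 0.05 (strict inequalities)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    table: pd.DataFrame,
    value: str = "mu",
    group: str = "label",
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group normality and pairwise location tests on a property column.

    Returns ``(normality, pairwise)``: Shapiro-Wilk p per group, and for
    every group pair a rank-based location test p-value with significance
    stars.  The groups here are unpaired tissue classes, so the rank-sum
    (Mann-Whitney) variant of the Wilcoxon test is used; comparisons with a
    group below ``min_n`` samples are marked not computable.
    """
    groups = {k: np.asarray(v[value].dropna(), dtype=float)
              for k, v in table.groupby(group, observed=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    norm_rows = []
    for name, vals in groups.items():
        if len(vals) >= min_n:
            p = float(stats.shapiro(vals).pvalue)
        else:
            p = np.nan
        norm_rows.append({group: name, "n": len(vals), "shapiro_p": p})
    pair_rows = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = groups[a], groups[b]
            if len(va) < min_n or len(vb) < min_n:
                p, stars, computable = np.nan, "", False
            else:
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
                stars, computable = significance_stars(p), True
            pair_rows.append(
                {"group_a": a, "group_b": b, "p": p, "stars": stars,
                 "computable": computable}
            )
    return pd.DataFrame(norm_rows), pd.DataFrame(pair_rows)
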