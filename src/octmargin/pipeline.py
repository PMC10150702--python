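"""End-to-end synthetic-cohort analysis: simulate -> preprocess -> fit -> evaluate.

Runs the whole chain scan by scan (volumes are regenerated from per-scan
seeds, so memory stays bounded): quality control on the raw volume, depth
compensation, surface detection and normalization, automated visual grading
and flowchart classification, patch extraction, per-patch optical-property
fitting, and finally the task-wise leave-one-patient-out SVM evaluation plus
the visual-vs-histology agreement heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import (
    EvalReport,
    agreement_heatmap,
    assign_task_labels,
    loo_svm_evaluate,
)
from .optics import fit_patch_table
from .params import CohortSpec, SystemModel, TissueLabel, TissueParams
from .preprocess import (
    QCError,
    compensate_depth,
    detect_surface,
    extract_patches,
    normalize_surface,
    qc_scan,
)
from .simulate import SyntheticCohort, simulate_cohort, simulate_volume
from .visual import GradingConfig, classify_visual, grade_criteria

__all__ = [
    "PipelineResult",
    "run_cohort_analysis",
    "simulate_normalized_patches",
    "SVM_FEATURES",
]

#: optical-property feature columns used by the SVM
SVM_FEATURES = ("mu", "intensity_db", "r2")


def simulate_normalized_patches(
    params: TissueParams,
    system: SystemModel,
    n_patches: int,
    rng: np.ndarray | np.random.Generator,
    bscans_per_volume: int = 2,
):
    """Simulate, compensate and surface-normalize volumes until ``n_patches``
    patches of one tissue class are available (for calibration studies)."""
    patches = []
    while len(patches) < n_patches:
        volume, _ = simulate_volume(params, system, bscans_per_volume, rng)
        comp = compensate_depth(volume, system)
        surface = detect_surface(comp, noise_floor_db=system.noise_floor_db)
        norm = normalize_surface(comp, surface, noise_floor_db=system.noise_floor_db)
        patches.extend(
            extract_patches(
                norm,
                bscan_stride=1,
                noise_floor_db=system.noise_floor_db,
                label=params.label.value,
            )
        )
    return patches[:n_patches]


@dataclass
class PipelineResult:
    """Everything the end-to-end synthetic analysis produces."""

    qc: pd.DataFrame                    # per scan: qc flags, accepted, label
    visual: pd.DataFrame                # per accepted scan: criteria + class
    properties: pd.DataFrame            # per patch: mu, I, r2, provenance
    reports: dict[str, EvalReport]      # per task
    heatmap: pd.DataFrame               # visual class x histology counts
    n_patches_skipped: int = 0
    shuffled_report: EvalReport | None = None
    errors: list[str] = field(default_factory=list)

    @property
    def qc_rejection_fraction(self) -> float:
        return float(1.0 - self.qc["accepted"].mean())


def run_cohort_analysis(
    cohort: SyntheticCohort | None = None,
    *,
    spec: CohortSpec | None = None,
    class_params: dict[TissueLabel, TissueParams] | None = None,
    system: SystemModel | None = None,
    tasks: tuple[str, ...] = ("I", "II", "III"),
    grading: GradingConfig = GradingConfig(),
    patch_bscan_stride: int = 2,
    cost: float = 0.1,
    shuffle_labels_seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis on a (default 21-patient) synthetic cohort.

    ``shuffle_labels_seed`` additionally evaluates task II with permuted
    binary labels (the chance-level control).
    """
    if cohort is None:
        cohort = simulate_cohort(spec, class_params, system)
    sysm = cohort.system
    qc_rows, visual_rows, prop_tables, errors = [], [], [], []
    n_skipped = 0
    for i in range(len(cohort)):
        row = cohort.scans.iloc[i]
        volume, truth = cohort.volume(i)
        flags = qc_scan(volume, noise_floor_db=sysm.noise_floor_db)
        accepted = flags == {"ok"}
        qc_rows.append(
            {
                "patient_id": row["patient_id"],
                "scan_id": row["scan_id"],
                "label": row["label"],
                "artifact": row["artifact"],
                "qc_flags": ",".join(sorted(flags)),
                "accepted": accepted,
            }
        )
        if not accepted:
            continue
        try:
            comp = compensate_depth(volume, sysm)
            surface = detect_surface(comp, noise_floor_db=sysm.noise_floor_db)
            norm = normalize_surface(comp, surface, noise_floor_db=sysm.noise_floor_db)
            criteria = grade_criteria(norm, grading)
            visual_rows.append(
                {
                    "patient_id": row["patient_id"],
                    "scan_id": row["scan_id"],
                    "label": row["label"],
                    "intensity": criteria.intensity.value,
                    "homogeneity": criteria.homogeneity.value,
                    "penetration": criteria.penetration.value,
                    "uniformity": criteria.uniformity.value,
                    "microstructures": criteria.microstructures.value,
                    "visual_class": classify_visual(criteria).value,
                }
            )
            patches = extract_patches(
                norm,
                bscan_stride=patch_bscan_stride,
                noise_floor_db=sysm.noise_floor_db,
                label=str(row["label"]),
            )
            table = fit_patch_table(patches)
            n_skipped += len(patches) - len(table)
            if not table.empty:
                prop_tables.append(table)
        except QCError as exc:  # pragma: no cover - defensive
            errors.append(f"{row['patient_id']}/{row['scan_id']}: {exc}")
    qc = pd.DataFrame(qc_rows)
    visual = pd.DataFrame(visual_rows)
    properties = (
        pd.concat(prop_tables, ignore_index=True) if prop_tables else pd.DataFrame()
    )

    reports: dict[str, EvalReport] = {}
    shuffled_report = None
    if not properties.empty:
        X_all = properties[list(SVM_FEATURES)].to_numpy()
        for task in tasks:
            mask, y = assign_task_labels(properties["label"], task)
            reports[task] = loo_svm_evaluate(
                X_all[mask], y, properties.loc[mask, "patient_id"], cost=cost
            )
        if shuffle_labels_seed is not None:
            mask, y = assign_task_labels(properties["label"], "II")
            rng = np.random.default_rng(shuffle_labels_seed)
            shuffled_report = loo_svm_evaluate(
                X_all[mask],
                rng.permutation(y),
                properties.loc[mask, "patient_id"],
                cost=cost,
            )
    heatmap = (
        agreement_heatmap(visual["visual_class"].tolist(), visual["label"].tolist())
        if not visual.empty
        else pd.DataFrame()
    )
    return PipelineResult(
        qc=qc,
        visual=visual,
        properties=properties,
        reports=reports,
        heatmap=heatmap,
        n_patches_skipped=n_skipped,
        shuffled_report=shuffled_report,
        errors=errors,
    )
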