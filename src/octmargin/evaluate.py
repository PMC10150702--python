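"""Task mapping, leave-one-patient-out SVM, diagnostic metrics, contingencies.

Three binary classification tasks are defined over the six histology
classes:

* Task I   - all six classes; healthy gray and white matter are
  non-pathological, every infiltrated class and edema are pathological.
* Task II  - healthy white matter vs white matter with any degree of tumor
  infiltration (gray matter and edema excluded).
* Task III - healthy white matter vs white matter with >60% infiltration
  only (the extreme-grade separation).

Classification of the per-patch optical properties (mu, I, r^2) uses a
linear-kernel support vector machine with regularization cost 0.1,
evaluated leave-one-patient-out so no patient contributes to both training
and test data; performance is the mean sensitivity and specificity over
folds, with balanced accuracy their arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .params import BENIGN_TO_MALIGNANT, TissueLabel
from .visual import VISUAL_BENIGN_TO_MALIGNANT, VisualClass

__all__ = [
    "TaskSpec",
    "TASKS",
    "ContingencyCounts",
    "Metrics",
    "EvalReport",
    "assign_task_labels",
    "loo_svm_evaluate",
    "compute_metrics",
    "balanced_accuracy_from_rates",
    "round_half_away",
    "contingency_from_outcomes",
    "agreement_heatmap",
    "render_agreement_heatmap",
    "FLUORESCENCE_GUIDANCE_COUNTS",
    "POSTOP_MRI_COUNTS",
    "OBSERVER_RATES",
    "REPORTED_CLASSIFIER_RATES",
    "worked_examples",
]

_INFILTRATED = (TissueLabel.WM0_30, TissueLabel.WM30_60, TissueLabel.WM60plus)


@dataclass(frozen=True)
class TaskSpec:
    """A binary classification task over the six-class histology labels."""

    task_id: str
    included: frozenset[TissueLabel]
    positives: frozenset[TissueLabel]

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError("task needs at least one positive label")
        if not self.positives <= self.included:
            raise ValueError("positive labels must be a subset of included labels")
        if not (self.included - self.positives):
            raise ValueError("task needs at least one negative label")


def make_task_one(edema_positive: bool = True) -> TaskSpec:
    """Task I: all classes; infiltrated white matter (and, by default, edema)
    is pathological, healthy gray and white matter are not."""
    positives = set(_INFILTRATED) | ({TissueLabel.WME} if edema_positive else set())
    return TaskSpec("I", frozenset(TissueLabel), frozenset(positives))


TASKS: dict[str, TaskSpec] = {
    "I": make_task_one(),
    "II": TaskSpec(
        "II",
        frozenset({TissueLabel.WM0, *_INFILTRATED}),
        frozenset(_INFILTRATED),
    ),
    "III": TaskSpec(
        "III",
        frozenset({TissueLabel.WM0, TissueLabel.WM60plus}),
        frozenset({TissueLabel.WM60plus}),
    ),
}


def assign_task_labels(
    labels, task: TaskSpec | str
) -> tuple[np.ndarray, np.ndarray]:
    """Map histology labels to (inclusion mask, binary labels on included rows).

    Binary labels are 1 for pathological, 0 for non-pathological.  Raises
    when the included subset does not contain both classes.
    """
    if isinstance(task, str):
        task = TASKS[task]
    labels = [TissueLabel(l) for l in labels]
    mask = np.array([l in task.included for l in labels], dtype=bool)
    y = np.array(
        [1 if l in task.positives else 0 for l, m in zip(labels, mask) if m],
        dtype=int,
    )
    if len(y) == 0 or y.min() == y.max():
        raise ValueError(
            f"task {task.task_id}: included rows contain only one class"
        )
    return mask, y


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting style)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class ContingencyCounts:
    """tp/fp/tn/fn counts of a binary residual-tumor decision."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("contingency table is empty")


@dataclass(frozen=True)
class Metrics:
    """Sensitivity/specificity/balanced accuracy (and accuracy) in percent.

    Exact rational values are kept alongside floats; rounded integers use
    half-away-from-zero, matching the integer reporting style.  A metric
    whose denominator is zero is None (not computable).
    """

    sensitivity_pct: float | None
    specificity_pct: float | None
    balanced_accuracy_pct: float | None
    accuracy_pct: float | None
    exact: dict = field(default_factory=dict, compare=False)

    def rounded(self) -> dict:
        return {
            k: (None if v is None else round_half_away(v))
            for k, v in {
                "sensitivity_pct": self.sensitivity_pct,
                "specificity_pct": self.specificity_pct,
                "balanced_accuracy_pct": self.balanced_accuracy_pct,
                "accuracy_pct": self.accuracy_pct,
            }.items()
        }


def compute_metrics(c: ContingencyCounts) -> Metrics:
    """Diagnostic metrics from counts, exact rational before rounding."""
    sens = Fraction(100 * c.tp, c.tp + c.fn) if c.tp + c.fn > 0 else None
    spec = Fraction(100 * c.tn, c.tn + c.fp) if c.tn + c.fp > 0 else None
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    acc = Fraction(100 * (c.tp + c.tn), c.tp + c.fp + c.tn + c.fn)
    return Metrics(
        sensitivity_pct=None if sens is None else float(sens),
        specificity_pct=None if spec is None else float(spec),
        balanced_accuracy_pct=None if bal is None else float(bal),
        accuracy_pct=float(acc),
        exact={"sensitivity": sens, "specificity": spec,
               "balanced_accuracy": bal, "accuracy": acc},
    )


def balanced_accuracy_from_rates(sensitivity_pct: float, specificity_pct: float) -> float:
    """Balanced accuracy (percent) from a printed sensitivity/specificity pair."""
    return (sensitivity_pct + specificity_pct) / 2.0


@dataclass
class EvalReport:
    """Per-fold and aggregate leave-one-patient-out evaluation results."""

    per_fold: pd.DataFrame
    mean_sensitivity_pct: float
    mean_specificity_pct: float
    balanced_accuracy_pct: float
    skipped_folds: list[str]
    cost: float
    standardized: bool

    def rounded(self) -> dict:
        return {
            "sensitivity_pct": round_half_away(self.mean_sensitivity_pct),
            "specificity_pct": round_half_away(self.mean_specificity_pct),
            "balanced_accuracy_pct": round_half_away(self.balanced_accuracy_pct),
        }


def loo_svm_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    patient_ids,
    cost: float = 0.1,
    standardize: bool = True,
) -> EvalReport:
    """Leave-one-patient-out linear-SVM evaluation of optical-property rows.

    One fold per patient: the fold's patient is the test set, everyone else
    trains a linear-kernel SVM (regularization cost ``cost``), with features
    z-scored on training-fold statistics when ``standardize``.  Folds whose
    training data collapse to one class are skipped with a warning.  The
    report aggregates the mean per-fold sensitivity and specificity (over
    folds where each is defined) and their arithmetic mean as balanced
    accuracy.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pids = np.asarray(patient_ids)
    if X.ndim != 2 or len(X) != len(y) != len(pids):
        raise ValueError("features, labels and patient_ids must align")
    patients = pd.unique(pids)
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    rows, skipped = [], []
    for patient in patients:
        test = pids == patient
        y_train = y[~test]
        if y_train.min() == y_train.max():
            skipped.append(str(patient))
            warnings.warn(
                f"fold {patient}: single-class training data, skipped",
                stacklevel=2,
            )
            continue
        if standardize:
            model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=cost))
        else:
            model = SVC(kernel="linear", C=cost)
        model.fit(X[~test], y_train)
        pred = model.predict(X[test])
        truth = y[test]
        tp = int(((pred == 1) & (truth == 1)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        rows.append(
            {
                "patient_id": patient,
                "n_test": int(test.sum()),
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
                "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise ValueError("no evaluable folds")
    mean_sens = float(per_fold["sensitivity_pct"].mean())
    mean_spec = float(per_fold["specificity_pct"].mean())
    return EvalReport(
        per_fold=per_fold,
        mean_sensitivity_pct=mean_sens,
        mean_specificity_pct=mean_spec,
        balanced_accuracy_pct=(mean_sens + mean_spec) / 2.0,
        skipped_folds=skipped,
        cost=cost,
        standardized=standardize,
    )


def contingency_from_outcomes(predicted: dict, truth: dict) -> ContingencyCounts:
    """Patient-level contingency from {patient: 'residual'|'clear'} maps."""
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth cover different patient sets")
    for mapping in (predicted, truth):
        bad = {v for v in mapping.values()} - {"residual", "clear"}
        if bad:
            raise ValueError(f"unknown outcome values: {sorted(bad)}")
    tp = sum(1 for p in predicted if predicted[p] == "residual" and truth[p] == "residual")
    fp = sum(1 for p in predicted if predicted[p] == "residual" and truth[p] == "clear")
    tn = sum(1 for p in predicted if predicted[p] == "clear" and truth[p] == "clear")
    fn = sum(1 for p in predicted if predicted[p] == "clear" and truth[p] == "residual")
    return ContingencyCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def agreement_heatmap(visual_classes, histo_labels) -> pd.DataFrame:
    """Joint count matrix of visual class (rows) vs histology label (columns).

    Both axes run benign to malignant so concordance concentrates along the
    diagonal band.
    """
    if len(visual_classes) != len(histo_labels):
        raise ValueError(
            f"length mismatch: {len(visual_classes)} vs {len(histo_labels)}"
        )
    v_order = [v.value for v in VISUAL_BENIGN_TO_MALIGNANT]
    h_order = [l.value for l in BENIGN_TO_MALIGNANT]
    if len(visual_classes) == 0:
        return pd.DataFrame(0, index=pd.Index(v_order, name="visual"),
                            columns=pd.Index(h_order, name="histology"))
    v = pd.Categorical([VisualClass(x).value for x in visual_classes], categories=v_order)
    h = pd.Categorical([TissueLabel(x).value for x in histo_labels], categories=h_order)
    table = pd.crosstab(v, h, rownames=["visual"], colnames=["histology"], dropna=False)
    return table.reindex(index=v_order, columns=h_order, fill_value=0)


def render_agreement_heatmap(table: pd.DataFrame, path) -> None:
    """Render an agreement count matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(table.to_numpy(), cmap="viridis")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), table.index)
    ax.set_xlabel("histology label")
    ax.set_ylabel("visual class")
    for (i, j), v in np.ndenumerate(table.to_numpy()):
        if v:
            ax.text(j, i, str(int(v)), ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="scans")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Worked-example inputs: published per-patient decision counts and printed
# sensitivity/specificity pairs of the comparator arms and classifiers in the
# 21-patient clinical cohort this pipeline models.
# ---------------------------------------------------------------------------

#: Fluorescence (FNa) guidance + neuronavigation: surgeon's residual/clear
#: call vs histopathology, per patient.
FLUORESCENCE_GUIDANCE_COUNTS = ContingencyCounts(tp=5, fp=0, tn=9, fn=7)

#: Early post-operative gadolinium MRI vs histopathology, per patient.
POSTOP_MRI_COUNTS = ContingencyCounts(tp=9, fp=0, tn=9, fn=3)

#: Visual-classifier observer sensitivity/specificity (percent).
OBSERVER_RATES: dict[str, tuple[float, float]] = {
    "observer_1": (75.0, 89.0),
    "observer_2": (91.0, 83.0),
}

#: Reported classifier sensitivity/specificity (percent) per task.
REPORTED_CLASSIFIER_RATES: dict[tuple[str, str], tuple[float, float]] = {
    ("svm", "II"): (81.0, 89.0),
    ("cnn", "I"): (59.0, 77.0),
    ("cnn", "II"): (84.0, 79.0),
    ("cnn", "III"): (87.0, 79.0),
    ("ae_fc", "I"): (65.0, 66.0),
    ("ae_fc", "II"): (86.0, 83.0),
    ("ae_fc", "III"): (90.0, 84.0),
}


def worked_examples() -> dict[str, int]:
    """Recompute every metric derivable from the bundled counts and rate pairs.

    Returns rounded integer percentages keyed by a descriptive name.
    """
    fna = compute_metrics(FLUORESCENCE_GUIDANCE_COUNTS)
    mri = compute_metrics(POSTOP_MRI_COUNTS)
    out = {
        "fna_sensitivity_pct": fna.rounded()["sensitivity_pct"],
        "fna_accuracy_pct": fna.rounded()["accuracy_pct"],
        "mri_sensitivity_pct": mri.rounded()["sensitivity_pct"],
    }
    for name, (sens, spec) in OBSERVER_RATES.items():
        out[f"{name}_balanced_accuracy_pct"] = round_half_away(
            balanced_accuracy_from_rates(sens, spec)
        )
    for (approach, task), (sens, spec) in REPORTED_CLASSIFIER_RATES.items():
        out[f"{approach}_task_{task}_balanced_accuracy_pct"] = round_half_away(
            balanced_accuracy_from_rates(sens, spec)
        )
    return out
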