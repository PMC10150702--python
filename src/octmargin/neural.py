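"""Neural-network training protocols on z-scored B-scan patches.

Two protocols are implemented at desk scale:

* a direct patch classifier trained leave-one-patient-out, and
* an autoencoder whose bottleneck features feed a fully connected
  classifier evaluated on a random 30% held-out split.

The protocol parameters (batch size 32, epoch count, split policy, per-patch
z-scoring) are the fixed part; the network architectures are deliberately
small, data-driven configuration (layer lists) on top of scikit-learn
multilayer perceptrons.  Everything is seeded and single-threaded, so runs
are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .evaluate import EvalReport, Metrics, compute_metrics, ContingencyCounts
from .preprocess import Patch, normalize_patch

__all__ = [
    "TrainConfig",
    "prepare_patch_matrix",
    "train_classifier_loo",
    "train_autoencoder_classifier",
    "encoder_features",
    "AutoencoderReport",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol and architecture configuration.

    ``split`` is either ``leave_one_patient_out`` or ``random_split_30``
    (30% of patches held out for testing).  ``hidden_layers`` configures the
    direct classifier; ``autoencoder_layers`` must be an odd-length,
    mirror-symmetric list whose middle entry is the bottleneck; ``fc_layers``
    configures the classifier trained on bottleneck features.
    """

    batch_size: int = 32
    epochs: int = 100
    split: str = "leave_one_patient_out"
    seed: int = 0
    hidden_layers: tuple[int, ...] = (32,)
    autoencoder_layers: tuple[int, ...] = (64, 8, 64)
    fc_layers: tuple[int, ...] = (16,)
    test_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.split not in ("leave_one_patient_out", "random_split_30"):
            raise ValueError(f"unknown split mode {self.split!r}")
        n = len(self.autoencoder_layers)
        if n % 2 == 0 or list(self.autoencoder_layers) != list(self.autoencoder_layers)[::-1]:
            raise ValueError("autoencoder_layers must be odd-length and mirror-symmetric")


def prepare_patch_matrix(patches) -> np.ndarray:
    """Z-score each patch (mean 0, sd 1) and flatten into an (n, p) matrix."""
    rows = []
    for p in patches:
        data = p.data if isinstance(p, Patch) else np.asarray(p, dtype=float)
        rows.append(np.ravel(normalize_patch(data)))
    return np.asarray(rows)


def _confusion(pred: np.ndarray, truth: np.ndarray) -> dict:
    return {
        "tp": int(((pred == 1) & (truth == 1)).sum()),
        "fp": int(((pred == 1) & (truth == 0)).sum()),
        "tn": int(((pred == 0) & (truth == 0)).sum()),
        "fn": int(((pred == 0) & (truth == 1)).sum()),
    }


def _fit_mlp_classifier(X, y, cfg: TrainConfig, seed: int) -> MLPClassifier:
    model = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layers,
        batch_size=min(cfg.batch_size, len(X)),
        max_iter=cfg.epochs,
        solver="adam",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def train_classifier_loo(
    patches,
    labels: np.ndarray,
    patient_ids,
    cfg: TrainConfig = TrainConfig(),
) -> EvalReport:
    """Leave-one-patient-out training of the direct patch classifier.

    One model per left-out patient; folds whose training data collapse to a
    single class are skipped with a warning.  Aggregation matches the SVM
    evaluation: mean per-fold sensitivity and specificity, balanced accuracy
    from the means.
    """
    X = prepare_patch_matrix(patches)
    y = np.asarray(labels, dtype=int)
    pids = np.asarray(patient_ids)
    patients = pd.unique(pids)
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    rows, skipped = [], []
    for i, patient in enumerate(patients):
        test = pids == patient
        y_train = y[~test]
        if y_train.min() == y_train.max():
            skipped.append(str(patient))
            warnings.warn(f"fold {patient}: single-class training data, skipped",
                          stacklevel=2)
            continue
        model = _fit_mlp_classifier(X[~test], y_train, cfg, seed=cfg.seed + i)
        conf = _confusion(model.predict(X[test]), y[test])
        rows.append(
            {
                "patient_id": patient,
                "n_test": int(test.sum()),
                **conf,
                "sensitivity_pct": 100.0 * conf["tp"] / (conf["tp"] + conf["fn"])
                if conf["tp"] + conf["fn"] else np.nan,
                "specificity_pct": 100.0 * conf["tn"] / (conf["tn"] + conf["fp"])
                if conf["tn"] + conf["fp"] else np.nan,
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
        cost=float("nan"),
        standardized=True,
    )


def encoder_features(autoencoder: MLPRegressor, X: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Forward-propagate to the bottleneck of a trained autoencoder."""
    n_encoder = len(cfg.autoencoder_layers) // 2 + 1
    a = np.asarray(X, dtype=float)
    for i in range(n_encoder):
        a = a @ autoencoder.coefs_[i] + autoencoder.intercepts_[i]
        a = np.maximum(a, 0.0)  # hidden layers are ReLU
    return a


@dataclass
class AutoencoderReport:
    """Results of the autoencoder + fully-connected classification protocol."""

    metrics: Metrics
    counts: ContingencyCounts
    reconstruction_loss_curve: list[float]
    n_train: int
    n_test: int
    config: TrainConfig = field(repr=False, default=TrainConfig())


def train_autoencoder_classifier(
    patches,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> AutoencoderReport:
    """Unsupervised autoencoder features + fully connected classifier.

    Patches are split into training and a random held-out test fraction
    (default 30%, stratified); the autoencoder learns to reconstruct the
    training patches, its bottleneck activations train the classifier, and
    metrics are reported on the held-out split.
    """
    cfg = cfg or TrainConfig(split="random_split_30")
    X = prepare_patch_matrix(patches)
    y = np.asarray(labels, dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=cfg.test_fraction, random_state=cfg.seed, stratify=y
    )
    ae = MLPRegressor(
        hidden_layer_sizes=cfg.autoencoder_layers,
        activation="relu",
        batch_size=min(cfg.batch_size, len(X_tr)),
        max_iter=cfg.epochs,
        solver="adam",
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ae.fit(X_tr, X_tr)
    clf = _fit_mlp_classifier(encoder_features(ae, X_tr, cfg), y_tr, cfg, seed=cfg.seed)
    pred = clf.predict(encoder_features(ae, X_te, cfg))
    conf = _confusion(pred, y_te)
    counts = ContingencyCounts(**conf)
    return AutoencoderReport(
        metrics=compute_metrics(counts),
        counts=counts,
        reconstruction_loss_curve=[float(v) for v in ae.loss_curve_],
        n_train=len(X_tr),
        n_test=len(X_te),
        config=cfg,
    )
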