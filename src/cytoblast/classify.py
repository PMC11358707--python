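"""Blast classification on squared-reconstruction-error (SRE) features.

The classifier's healthy class is the autoencoder's held-out reference
(remission-test) cells; the blast class comes from annotated non-remission
cells.  Splits are leave-one-patient-out and class-balanced: each fold holds
out one patient's blasts, subsampled to the size of one remission validation
share, and training blasts are subsampled to the remaining remission share.
Model selection samples classifier families (margin-based, linear, small
feed-forward, tree ensemble) and keeps the highest mean validation accuracy.

Also provided: the conventional one-dimensional CD45low gating baseline and
classifiers trained directly on expression instead of SRE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .autoencoder import SREMatrix
from .matrix import CellMatrix
from .preprocess import MinMaxScaler, apply_minmax, fit_minmax

HEALTHY, BLAST = "healthy", "blast"


@dataclass
class LabeledSRESet:
    """SRE features with per-cell class labels and patient provenance."""

    sre: SREMatrix
    labels: np.ndarray  # {"healthy", "blast"}
    patient_ids: np.ndarray
    origin: np.ndarray  # {"remission_test", "annotated_nonremission"}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.patient_ids = np.asarray(self.patient_ids)
        self.origin = np.asarray(self.origin)
        n = self.sre.n_cells
        if not (len(self.labels) == len(self.patient_ids) == len(self.origin) == n):
            raise ValueError("per-cell arrays must align with the SRE matrix")


@dataclass
class SplitPlan:
    """Balanced leave-one-patient-out folds over a :class:`LabeledSRESet`."""

    folds: list  # list of (train_indices, validation_indices)
    balance_report: pd.DataFrame

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def build_lopo_splits(data: LabeledSRESet, seed: int = 0) -> SplitPlan:
    """One balanced fold per blast-contributing patient.

    The remission-test pool is partitioned into as many equal validation
    shares as folds.  Fold *i* validates on share *i* plus patient *i*'s
    blasts subsampled (without replacement) to the share size; it trains on
    the remaining shares plus the other patients' blasts subsampled to the
    remaining-share size.  A patient with fewer blasts than the share
    contributes them all and the fold is flagged imbalanced.
    """
    blast_mask = data.labels == BLAST
    rem_idx = np.flatnonzero(data.origin == "remission_test")
    patients = [p for p in pd.unique(data.patient_ids[blast_mask])]
    dropped = [
        p for p in pd.unique(data.patient_ids)
        if p not in patients and (data.patient_ids == p).any()
        and not blast_mask[data.patient_ids == p].any()
        and (data.origin[data.patient_ids == p] == "annotated_nonremission").any()
    ]
    for p in dropped:
        warnings.warn(f"patient {p!r} contributes no blasts; excluded from folds")
    if len(patients) < 2:
        raise ValueError("need blasts from at least 2 patients")
    n_folds = len(patients)
    if len(rem_idx) < n_folds:
        raise ValueError("remission-test pool smaller than the fold count")

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rem_perm = rng.permutation(rem_idx)
    shares = np.array_split(rem_perm, n_folds)

    folds = []
    report_rows = []
    for i, patient in enumerate(patients):
        val_rem = shares[i]
        train_rem = np.concatenate([s for j, s in enumerate(shares) if j != i])
        pat_blasts = np.flatnonzero(blast_mask & (data.patient_ids == patient))
        other_blasts = np.flatnonzero(blast_mask & (data.patient_ids != patient))

        fold_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i])
        )
        n_val = len(val_rem)
        if len(pat_blasts) > n_val:
            val_blasts = fold_rng.choice(pat_blasts, size=n_val, replace=False)
        else:
            val_blasts = pat_blasts
        n_train = len(train_rem)
        if len(other_blasts) > n_train:
            train_blasts = fold_rng.choice(other_blasts, size=n_train, replace=False)
        else:
            train_blasts = other_blasts

        train = np.concatenate([train_rem, train_blasts])
        val = np.concatenate([val_rem, val_blasts])
        folds.append((train, val))
        report_rows.append({
            "fold": i, "patient": patient,
            "train_healthy": len(train_rem), "train_blast": len(train_blasts),
            "val_healthy": n_val, "val_blast": len(val_blasts),
            "balanced": len(val_blasts) == n_val and len(train_blasts) == n_train,
        })
    return SplitPlan(folds=folds, balance_report=pd.DataFrame(report_rows))


# --------------------------------------------------------------------------
# Model space and selection


def _default_model_space() -> list[tuple[str, dict]]:
    # (family, sampling spec); kept deliberately modest so selection runs on
    # one CPU in minutes.
    return [
        ("svm", {"C": (1e-1, 1e1, "log"), "kernel": ["rbf", "linear"]}),
        ("linear", {"C": (1e-2, 1e2, "log")}),
        ("mlp", {"hidden_layer_sizes": [(10,), (20,), (50,), (10, 4)],
                 "activation": ["relu", "tanh"]}),
        ("rf", {"n_estimators": [50, 100], "max_depth": [None, 8, 16]}),
    ]


def _build_estimator(family: str, params: dict, seed: int):
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "linear":
        return LogisticRegression(max_iter=500, random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(max_iter=300, random_state=seed, **params)
    if family == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown model family {family!r}")


def _sample_params(spec: dict, rng: np.random.Generator) -> dict:
    out = {}
    for key, choices in spec.items():
        if isinstance(choices, list):
            out[key] = choices[rng.integers(len(choices))]
        elif isinstance(choices, tuple) and choices[-1] == "log":
            out[key] = float(np.exp(rng.uniform(np.log(choices[0]), np.log(choices[1]))))
        else:
            raise ValueError(f"cannot sample {choices!r}")
    return out


@dataclass
class FittedClassifier:
    """A selected and retrained blast classifier."""

    estimator: object
    family: str
    params: dict
    mean_val_accuracy: float
    channels: list[str]
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)
    threshold: float = 0.5
    retrain_indices: np.ndarray = field(default_factory=lambda: np.asarray([], dtype=int))

    def feature_importance(self, X: np.ndarray | None = None,
                           y: np.ndarray | None = None,
                           seed: int = 0) -> np.ndarray:
        """Impurity importances for tree ensembles; permutation importance
        (requires X, y) for other families."""
        if hasattr(self.estimator, "feature_importances_"):
            return np.asarray(self.estimator.feature_importances_)
        if X is None or y is None:
            raise ValueError("permutation importance needs X and y")
        from sklearn.inspection import permutation_importance

        r = permutation_importance(self.estimator, X, y, n_repeats=5,
                                   random_state=seed)
        return np.asarray(r.importances_mean)


def train_select_classifier(
    plan: SplitPlan,
    data: LabeledSRESet,
    model_space: list | None = None,
    n_trials: int = 100,
    seed: int = 0,
) -> FittedClassifier:
    """Sample (family, hyperparameter) trials, score each by mean validation
    accuracy over the folds, and retrain the best on all folds' data with
    class balance maintained."""
    model_space = model_space or _default_model_space()
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    X = data.sre.values
    y = (data.labels == BLAST).astype(int)

    for i, (tr, va) in enumerate(plan.folds):
        for name, part in (("train", tr), ("validation", va)):
            if len(np.unique(y[part])) < 2:
                raise ValueError(f"fold {i} has a single-class {name} partition")

    trial_rows = []
    best = None
    for trial in range(n_trials):
        family, spec = model_space[rng.integers(len(model_space))]
        params = _sample_params(spec, rng)
        accs = []
        for tr, va in plan.folds:
            est = _build_estimator(family, params, seed=int(seed) + trial)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[tr], y[tr])
            accs.append(float((est.predict(X[va]) == y[va]).mean()))
        mean_acc = float(np.mean(accs))
        trial_rows.append({"trial": trial, "family": family,
                           "mean_val_accuracy": mean_acc, **{k: str(v) for k, v in params.items()}})
        if best is None or mean_acc > best[0] + 1e-12:
            best = (mean_acc, family, params, trial)

    mean_acc, family, params, trial = best
    # Retrain on all data with balance maintained: every remission-test cell
    # plus an equal-size subsample of blasts.
    rem = np.flatnonzero(data.origin == "remission_test")
    blasts = np.flatnonzero(y == 1)
    retrain_rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 9999]))
    if len(blasts) > len(rem):
        blasts = retrain_rng.choice(blasts, size=len(rem), replace=False)
    idx = np.concatenate([rem, blasts])
    est = _build_estimator(family, params, seed=int(seed) + trial)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X[idx], y[idx])
    return FittedClassifier(estimator=est, family=family, params=params,
                            mean_val_accuracy=mean_acc,
                            channels=list(data.sre.channels),
                            trials=pd.DataFrame(trial_rows),
                            retrain_indices=np.asarray(idx, dtype=int))


@dataclass
class BlastPrediction:
    labels: np.ndarray  # {"healthy", "blast"}
    scores: np.ndarray
    model_id: str

    @property
    def blast_mask(self) -> np.ndarray:
        return self.labels == BLAST


def predict_blasts(model: FittedClassifier, sre: SREMatrix) -> BlastPrediction:
    """Per-cell blast call + decision score from SRE features."""
    if list(sre.channels) != list(model.channels):
        raise ValueError("SRE channels do not match the classifier's training channels")
    X = sre.values
    est = model.estimator
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(X)[:, 1]
        labels = np.where(scores > model.threshold, BLAST, HEALTHY)
    else:
        scores = est.decision_function(X)
        labels = np.where(scores > 0.0, BLAST, HEALTHY)
    return BlastPrediction(labels=labels, scores=np.asarray(scores, dtype=float),
                           model_id=model.family)


def cd45low_gate(m: CellMatrix, threshold: float) -> np.ndarray:
    """The conventional baseline: cells with CD45 below ``threshold``
    (arcsinh space) are called blasts."""
    cd45 = m.column("CD45")
    return np.where(cd45 < threshold, BLAST, HEALTHY)


def evaluate_predictions(pred, truth) -> dict:
    """Accuracy, balanced accuracy and confusion counts.

    Balanced accuracy is the mean per-class recall over classes present in
    the truth vector; a single-class truth triggers a warning and equals that
    class's recall.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    classes = np.unique(truth)
    if len(classes) < 2:
        warnings.warn("single-class truth: balanced accuracy is that class's recall")
    recalls = {}
    confusion = {}
    for c in classes:
        mask = truth == c
        recalls[str(c)] = float((pred[mask] == c).mean())
        for p in np.unique(pred):
            confusion[f"true_{c}|pred_{p}"] = int(((truth == c) & (pred == p)).sum())
    return {
        "accuracy": float((pred == truth).mean()),
        "balanced_accuracy": float(np.mean(list(recalls.values()))),
        "per_class_recall": recalls,
        "confusion": confusion,
        "n": int(len(truth)),
    }


# --------------------------------------------------------------------------
# Expression-direct baselines


@dataclass
class ExpressionBaseline:
    """A classifier trained on scaled intensities rather than SRE.

    The ``small_latent`` variant is a feed-forward net with hidden widths
    (10, 4); its 4-unit layer activations are exposed for latent-space
    comparison with the autoencoder.
    """

    estimator: MLPClassifier
    scaler: MinMaxScaler
    variant: str
    channels: list[str]

    def hidden_activations(self, m: CellMatrix) -> np.ndarray:
        """Activations of the last hidden layer for a scaled matrix."""
        m.require_state("scaled")
        h = m.values
        act = self.estimator.activation
        for W, b in zip(self.estimator.coefs_[:-1], self.estimator.intercepts_[:-1]):
            h = h @ W + b
            h = np.maximum(h, 0) if act == "relu" else np.tanh(h)
        return h

    def predict(self, m: CellMatrix) -> np.ndarray:
        m.require_state("scaled")
        return np.where(self.estimator.predict(m.values) == 1, BLAST, HEALTHY)


def train_expression_baseline(
    train: CellMatrix,
    labels,
    variant: str = "best",
    seed: int = 0,
) -> ExpressionBaseline:
    """Train a feed-forward classifier directly on expression.

    ``train`` is arcsinh-state; a fresh min-max scaler is fitted here
    (deliberately *not* the autoencoder's scaler).  ``variant='best'`` uses
    the wider (40, 60, 40, 10) stack; ``'small_latent'`` uses (10, 4).
    """
    if variant not in ("best", "small_latent"):
        raise ValueError(f"unknown variant {variant!r}")
    train.require_state("arcsinh")
    scaler = fit_minmax(train)
    scaled = apply_minmax(scaler, train)
    y = (np.asarray(labels) == BLAST).astype(int)
    hidden = (40, 60, 40, 10) if variant == "best" else (10, 4)
    est = MLPClassifier(hidden_layer_sizes=hidden, max_iter=300, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(scaled.values, y)
    return ExpressionBaseline(estimator=est, scaler=scaler, variant=variant,
                              channels=list(train.channels))
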