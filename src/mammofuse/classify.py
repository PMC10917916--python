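"""Shallow neural-network classifier presets and the evaluation metric suite.

The five presets mirror the common point-and-click taxonomy for shallow
MLPs on tabular features: *narrow*, *medium* and *wide* are single hidden
layers of width 10, 25 and 100; *bilayered* and *trilayered* stack two and
three hidden layers of width 10. All use ReLU activations and a softmax
output over the two classes, trained full-batch with a quasi-Newton solver.

Evaluation is stratified k-fold cross-validation with out-of-fold
predictions pooled into a single confusion matrix, from which the nine
performance measures are computed. Sensitivity and precision are
macro-averages over the two classes; F1 is the harmonic mean of the macro
pair; FNR is 100 - sensitivity by construction; MCC and Cohen's kappa are
reported on the percent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

PRESETS: dict[str, tuple[int, ...]] = {
    "narrow": (10,),
    "medium": (25,),
    "wide": (100,),
    "bilayered": (10, 10),
    "trilayered": (10, 10, 10),
}


@dataclass
class MetricsReport:
    """Confusion matrix plus the derived performance measures.

    All rate-like measures are percentages in [0, 100]; ``auc`` stays on
    the [0, 1] scale.
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    fnr: float
    g_measure: float
    mcc: float
    kappa: float
    auc: float | None = None
    preset: str | None = None
    folds: int | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "fnr": self.fnr,
            "g_measure": self.g_measure,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "auc": self.auc,
        }
        if self.preset is not None:
            d["preset"] = self.preset
        if self.folds is not None:
            d["folds"] = self.folds
        return d

    def summary(self) -> str:
        lines = [
            f"confusion matrix: {self.confusion.tolist()}",
            f"accuracy    {self.accuracy:6.2f} %",
            f"sensitivity {self.sensitivity:6.2f} %   (FNR {self.fnr:.2f} %)",
            f"precision   {self.precision:6.2f} %",
            f"F1          {self.f1:6.2f} %",
            f"G-measure   {self.g_measure:6.2f} %",
            f"MCC         {self.mcc:6.2f} %",
            f"kappa       {self.kappa:6.2f} %",
        ]
        if self.auc is not None:
            lines.append(f"AUC         {self.auc:6.3f}")
        return "\n".join(lines)


def build_classifier(preset: str, seed: int = 0, max_iter: int = 200) -> Pipeline:
    """A z-scoring + shallow-MLP pipeline for one preset.

    Features are standardized with statistics of the data the pipeline is
    fit on, so cross-validation never leaks test-fold statistics.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    clf = MLPClassifier(
        hidden_layer_sizes=PRESETS[preset],
        activation="relu",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    return Pipeline([("scale", StandardScaler()), ("mlp", clf)])


def compute_metrics(confusion, scores=None) -> MetricsReport:
    """Metric suite from a 2x2 confusion matrix.

    ``confusion[i, j]`` counts true class ``i`` predicted as ``j``.
    ``scores`` is an optional ``(y_true, class1_score)`` pair used for the
    rank-statistic AUC; when omitted AUC is ``None``.
    """
    c = np.asarray(confusion, dtype=np.int64)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    total = int(c.sum())
    if total < 1:
        raise ValueError("confusion matrix must contain at least one sample")
    with np.errstate(divide="ignore", invalid="ignore"):
        recalls = np.where(c.sum(1) > 0, np.diag(c) / c.sum(1), 0.0)
        precisions = np.where(c.sum(0) > 0, np.diag(c) / c.sum(0), 0.0)
    accuracy = 100.0 * np.trace(c) / total
    sensitivity = 100.0 * float(recalls.mean())
    precision = 100.0 * float(precisions.mean())
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    fnr = 100.0 - sensitivity
    g_measure = float(np.sqrt(precision * sensitivity))
    tn, fp = int(c[0, 0]), int(c[0, 1])
    fn, tp = int(c[1, 0]), int(c[1, 1])
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 100.0 * (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    po = np.trace(c) / total
    pe = float((c.sum(1) * c.sum(0)).sum()) / total ** 2
    kappa = 100.0 * (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    auc = None
    if scores is not None:
        y_true, s1 = scores
        if len(np.unique(y_true)) == 2:
            auc = float(roc_auc_score(y_true, s1))
    return MetricsReport(
        confusion=c, accuracy=float(accuracy), sensitivity=sensitivity,
        precision=precision, f1=float(f1), fnr=float(fnr),
        g_measure=g_measure, mcc=float(mcc), kappa=float(kappa), auc=auc,
    )


def crossval_evaluate(X, y, preset: str = "narrow", folds: int = 10,
                      seed: int = 0, max_iter: int = 200) -> MetricsReport:
    """Stratified k-fold evaluation with pooled out-of-fold predictions."""
    values = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    counts = np.bincount(y, minlength=2)
    if (counts < folds).any():
        raise ValueError("every class must appear in every training fold; "
                         "reduce folds or add samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    score1 = np.empty(len(y), dtype=np.float64)
    with warnings.catch_warnings():
        # capped-iteration fits are intentional (wrapper-fitness proxy)
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for train_idx, test_idx in skf.split(values, y):
            clf = build_classifier(preset, seed=seed, max_iter=max_iter)
            clf.fit(values[train_idx], y[train_idx])
            pred[test_idx] = clf.predict(values[test_idx])
            score1[test_idx] = clf.predict_proba(values[test_idx])[:, 1]
    confusion = np.zeros((2, 2), dtype=np.int64)
    np.add.at(confusion, (y, pred), 1)
    report = compute_metrics(confusion, scores=(y, score1))
    report.preset = preset
    report.folds = folds
    return report


def crossval_accuracy(X, y, preset: str = "narrow", folds: int = 5,
                      seed: int = 0, max_iter: int = 100) -> float:
    """Pooled out-of-fold accuracy as a fraction in [0, 1] (wrapper-fitness
    objective; cheaper than the full report)."""
    report = crossval_evaluate(X, y, preset=preset, folds=folds, seed=seed,
                               max_iter=max_iter)
    return report.accuracy / 100.0
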