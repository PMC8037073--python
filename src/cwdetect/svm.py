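"""Per-lead one-vs-one multi-class SVM over (p_st, p_pr) features.

Each ECG lead gets its own multi-class machine built from K(K-1)/2 binary
soft-margin RBF SVMs (one per unordered class pair). A test point's decision
value for one binary machine is

    R(x) = sum_{i in SVs} W_i K(x, x_i) + b,      W_i = alpha_i y_i,

with the Gaussian kernel K(x, x_i) = exp(-||x - x_i||^2 / (2 sigma^2));
sign(R) casts the pairwise vote, a majority over pairs labels the segment for
that lead, and a majority across leads ("cross-matching") gives the fused
label. Ties break toward the label with the larger summed |R| margin.

Each binary dual problem is solved by scikit-learn's ``SVC`` (libsvm); the
one-vs-one assembly, Eq.-style decision evaluation, lead fusion, metrics and
record-stratified cross-validation live here. Trained machines satisfy the
dual box constraints 0 <= alpha_i <= gamma (the cost parameter) and
sum alpha_i y_i = 0, which :func:`check_dual_constraints` verifies.

Features are min-max scaled to [0, 1] using statistics stored at training
time, so the default kernel width sigma = 0.1 is on a meaningful relative
scale.

Sensitivity and specificity pool the non-normal classes: "positive" means
ischemia or infarction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ContractError, ParameterError, ValidationError
from .records import FeatureTable

POSITIVE_CLASSES = ("ischemia", "infarction")

MODEL_FORMAT_VERSION = 1


def rbf_kernel(x: np.ndarray, xi: np.ndarray, sigma_rbf: float = 0.1) -> np.ndarray:
    """Gaussian kernel exp(-||x - xi||^2 / (2 sigma^2)); in (0, 1]."""
    if sigma_rbf <= 0:
        raise ParameterError(f"sigma_rbf must be positive, got {sigma_rbf}")
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    sq = np.sum((x - xi) ** 2, axis=-1)
    return np.exp(-sq / (2.0 * sigma_rbf**2))


@dataclass
class BinarySVM:
    """One trained pairwise machine; ``R > 0`` votes ``class_pos``."""

    class_neg: str
    class_pos: str
    support_vectors: np.ndarray  # (n_sv, 2) scaled features
    dual_coef: np.ndarray  # (n_sv,) = alpha_i y_i in libsvm sign convention
    bias: float
    sigma_rbf: float
    gamma_cost: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.class_neg, self.class_pos)


def decision_value(model_binary: BinarySVM, x: np.ndarray) -> np.ndarray | float:
    """R = sum_i W_i K(x, x_i) + b for one point (2,) or a batch (n, 2)."""
    if model_binary.support_vectors.size == 0:
        raise ContractError("binary model has no support vectors (untrained)")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    k = rbf_kernel(pts[:, None, :], model_binary.support_vectors[None, :, :],
                   model_binary.sigma_rbf)
    r = k @ model_binary.dual_coef + model_binary.bias
    return float(r[0]) if single else r


@dataclass
class TrainedModel:
    """Per-lead one-vs-one multi-class SVM bundle (the indicator model).

    ``scaler`` holds per-feature (min, max) of the training set; features are
    mapped to [0, 1] before any kernel evaluation.
    """

    classes: list[str]
    lead_models: dict[str, list[BinarySVM]]
    scaler: dict[str, tuple[float, float]]
    sigma_rbf: float
    gamma_cost: float

    @property
    def leads(self) -> list[str]:
        return sorted(self.lead_models)

    def scale(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in ("p_st", "p_pr"):
            lo, hi = self.scaler[name]
            span = hi - lo if hi > lo else 1.0
            cols.append((table[name].to_numpy(dtype=float) - lo) / span)
        return np.column_stack(cols)


@dataclass
class ClassDecision:
    """Per-segment decision: per-lead votes plus the fused label."""

    record_id: str
    segment_index: int
    lead_labels: dict[str, str]
    lead_margins: dict[str, float]
    fused_label: str
    votes: dict[str, int]
    truth: str | None = None


def train(
    features: FeatureTable,
    sigma_rbf: float = 0.1,
    gamma_cost: float = 10.0,
    seed: int = 0,
) -> TrainedModel:
    """Fit K(K-1)/2 pairwise RBF SVMs per lead on labeled features.

    Requires at least two classes and >= 5 examples per class on every lead.
    Deterministic: libsvm's solution depends only on the (ordered) data.
    """
    if sigma_rbf <= 0 or gamma_cost <= 0:
        raise ParameterError("sigma_rbf and gamma_cost must be positive")
    data = features.data
    if data["label"].isna().any():
        raise ValidationError("training features must all carry labels")
    classes = sorted(data["label"].unique())
    if len(classes) < 2:
        raise ValidationError(f"need >= 2 classes to train, got {classes}")

    scaler = {
        name: (float(data[name].min()), float(data[name].max())) for name in ("p_st", "p_pr")
    }
    stub = TrainedModel(classes=classes, lead_models={}, scaler=scaler,
                        sigma_rbf=sigma_rbf, gamma_cost=gamma_cost)

    for lead, lead_rows in data.groupby("lead_name", sort=True):
        counts = lead_rows["label"].value_counts()
        if len(counts) < 2:
            raise ValidationError(f"lead {lead!r} has a single class; cannot train")
        if (counts < 5).any():
            lacking = counts[counts < 5].index.tolist()
            raise ValidationError(f"lead {lead!r} has < 5 examples for classes {lacking}")
        x = stub.scale(lead_rows)
        y = lead_rows["label"].to_numpy()
        machines = []
        for a, b in itertools.combinations(sorted(counts.index), 2):
            mask = (y == a) | (y == b)
            svc = SVC(
                C=gamma_cost,
                kernel="rbf",
                gamma=1.0 / (2.0 * sigma_rbf**2),
                random_state=seed,
            )
            svc.fit(x[mask], y[mask])
            neg, pos = svc.classes_  # decision > 0 predicts classes_[1]
            machines.append(
                BinarySVM(
                    class_neg=str(neg),
                    class_pos=str(pos),
                    support_vectors=svc.support_vectors_.copy(),
                    dual_coef=svc.dual_coef_[0].copy(),
                    bias=float(svc.intercept_[0]),
                    sigma_rbf=sigma_rbf,
                    gamma_cost=gamma_cost,
                )
            )
        stub.lead_models[str(lead)] = machines
    return stub


def check_dual_constraints(model: TrainedModel, tol: float = 1e-6) -> None:
    """Assert the dual box constraints on every binary machine.

    Raises :class:`ValidationError` if any 0 <= alpha_i <= gamma bound or the
    equality sum alpha_i y_i = 0 is violated beyond ``tol``.
    """
    for lead, machines in model.lead_models.items():
        for m in machines:
            alphas = np.abs(m.dual_coef)
            if (alphas > m.gamma_cost + tol).any():
                raise ValidationError(f"{lead} {m.pair}: alpha exceeds cost bound")
            if abs(m.dual_coef.sum()) > tol:
                raise ValidationError(f"{lead} {m.pair}: sum alpha_i y_i != 0")


def _vote_lead(machines: list[BinarySVM], x: np.ndarray) -> tuple[str, float]:
    """Majority over pairwise machines; tie -> largest summed |R| support."""
    votes: dict[str, int] = {}
    margin: dict[str, float] = {}
    for m in machines:
        r = decision_value(m, x)
        winner = m.class_pos if r > 0 else m.class_neg
        votes[winner] = votes.get(winner, 0) + 1
        margin[winner] = margin.get(winner, 0.0) + abs(float(r))
    best = max(votes, key=lambda c: (votes[c], margin.get(c, 0.0)))
    return best, margin.get(best, 0.0)


def predict(model: TrainedModel, features: FeatureTable) -> list[ClassDecision]:
    """Per-lead one-vs-one voting, then majority fusion across leads."""
    data = features.data
    unknown = sorted(set(data["lead_name"]) - set(model.lead_models))
    if unknown:
        raise ValidationError(
            f"model has no machine for lead(s) {unknown}; available: {model.leads}"
        )
    decisions = []
    for (rid, seg), group in data.groupby(["record_id", "segment_index"], sort=True):
        lead_labels: dict[str, str] = {}
        lead_margins: dict[str, float] = {}
        for _, row in group.iterrows():
            x = model.scale(row.to_frame().T)[0]
            label, margin = _vote_lead(model.lead_models[row["lead_name"]], x)
            lead_labels[row["lead_name"]] = label
            lead_margins[row["lead_name"]] = margin
        votes: dict[str, int] = {}
        support: dict[str, float] = {}
        for lead, label in lead_labels.items():
            votes[label] = votes.get(label, 0) + 1
            support[label] = support.get(label, 0.0) + lead_margins[lead]
        fused = max(votes, key=lambda c: (votes[c], support[c]))
        truth = group["label"].iloc[0]
        decisions.append(
            ClassDecision(
                record_id=str(rid),
                segment_index=int(seg),
                lead_labels=lead_labels,
                lead_margins=lead_margins,
                fused_label=fused,
                votes=votes,
                truth=None if pd.isna(truth) else str(truth),
            )
        )
    return decisions


def evaluate(predictions: list[str], truth: list[str]) -> dict:
    """Accuracy, pooled sensitivity/specificity, and the confusion matrix.

    "Positive" pools the non-normal classes (ischemia, infarction):
    sensitivity = TP/(TP+FN) over truly positive segments, specificity =
    TN/(TN+FP) over truly normal ones.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValidationError(
            f"{len(predictions)} predictions vs {len(truth)} truth labels"
        )
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    classes = sorted(set(true) | set(pred))
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        confusion.loc[t, p] += 1

    pos_true = np.isin(true, POSITIVE_CLASSES)
    pos_pred = np.isin(pred, POSITIVE_CLASSES)
    tp = int(np.sum(pos_true & pos_pred))
    fn = int(np.sum(pos_true & ~pos_pred))
    tn = int(np.sum(~pos_true & ~pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    return {
        "accuracy": float(np.mean(pred == true)),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "confusion": confusion,
        "n": len(truth),
    }


def kfold_cv(
    features: FeatureTable,
    k: int = 10,
    seed: int = 0,
    sigma_rbf: float = 0.1,
    gamma_cost: float = 10.0,
) -> dict:
    """Record-stratified k-fold cross-validation of the fused classifier.

    Folds are stratified by record label and split by ``record_id`` so the
    minutes of one record never straddle the train/test boundary.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    data = features.data
    recs = data.groupby("record_id")["label"].first()
    if len(recs) < k:
        raise ParameterError(f"only {len(recs)} records for {k} folds")
    rec_ids = recs.index.to_numpy()
    rec_labels = recs.to_numpy()
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    fold_metrics = []
    pooled_pred: list[str] = []
    pooled_true: list[str] = []
    for train_idx, test_idx in splitter.split(rec_ids, rec_labels):
        train_tab = FeatureTable(data[data["record_id"].isin(rec_ids[train_idx])])
        test_tab = FeatureTable(data[data["record_id"].isin(rec_ids[test_idx])])
        model = train(train_tab, sigma_rbf=sigma_rbf, gamma_cost=gamma_cost, seed=seed)
        decisions = predict(model, test_tab)
        pred = [d.fused_label for d in decisions]
        true = [d.truth for d in decisions]
        fold_metrics.append(evaluate(pred, true))
        pooled_pred.extend(pred)
        pooled_true.extend(true)
    pooled = evaluate(pooled_pred, pooled_true)
    return {"folds": fold_metrics, "pooled": pooled, "k": k, "seed": seed}


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Versioned JSON dump: support vectors, coefficients, biases, settings."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classes": model.classes,
        "sigma_rbf": model.sigma_rbf,
        "gamma_cost": model.gamma_cost,
        "scaler": {k: list(v) for k, v in model.scaler.items()},
        "leads": {
            lead: [
                {
                    "class_neg": m.class_neg,
                    "class_pos": m.class_pos,
                    "support_vectors": m.support_vectors.tolist(),
                    "dual_coef": m.dual_coef.tolist(),
                    "bias": m.bias,
                }
                for m in machines
            ]
            for lead, machines in model.lead_models.items()
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    lead_models = {
        lead: [
            BinarySVM(
                class_neg=m["class_neg"],
                class_pos=m["class_pos"],
                support_vectors=np.asarray(m["support_vectors"], dtype=float),
                dual_coef=np.asarray(m["dual_coef"], dtype=float),
                bias=float(m["bias"]),
                sigma_rbf=float(payload["sigma_rbf"]),
                gamma_cost=float(payload["gamma_cost"]),
            )
            for m in machines
        ]
        for lead, machines in payload["leads"].items()
    }
    return TrainedModel(
        classes=list(payload["classes"]),
        lead_models=lead_models,
        scaler={k: (float(v[0]), float(v[1])) for k, v in payload["scaler"].items()},
        sigma_rbf=float(payload["sigma_rbf"]),
        gamma_cost=float(payload["gamma_cost"]),
    )
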