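"""Single-feature CART intensity classifiers and their evaluation.

The vector-magnitude epoch value is the sole predictor.  Two modes mirror
the study design:

* **one-vs-all (CART)** — one binary Gini tree per target class (SED vs
  rest, LPA vs rest, MVPA vs rest);
* **multiclass (MCART)** — a single tree predicting all three intensities.

Evaluation reports, per class: ROC AUC from the tree's leaf posterior
scores (rank statistic, ties half-credited), a seeded percentile-bootstrap
95% CI over epoch resampling, and sensitivity/specificity at the tree's
hard labels; plus the multiclass confusion matrix.  The default protocol is
resubstitution (train and evaluate on the same epochs), matching how the
published headline metrics appear to have been computed; a leave-one-child-
out split is available as an extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.tree import DecisionTreeClassifier

INTENSITIES = ("SED", "LPA", "MVPA")


@dataclass
class TreeModel:
    mode: str                      # "one_vs_all" | "multiclass"
    target: str | None             # positive class for one_vs_all
    clf: DecisionTreeClassifier
    classes: tuple
    min_leaf: int
    max_depth: int
    seed: int

    def scores(self, vm_values) -> np.ndarray:
        """Posterior score per epoch.

        One-vs-all: P(target).  Multiclass: (n, 3) columns ordered SED,
        LPA, MVPA (absent classes yield zero columns).
        """
        X = np.asarray(vm_values, dtype=float).reshape(-1, 1)
        proba = self.clf.predict_proba(X)
        if self.mode == "one_vs_all":
            idx = list(self.clf.classes_).index(True)
            return proba[:, idx]
        out = np.zeros((X.shape[0], len(INTENSITIES)))
        for j, cls in enumerate(INTENSITIES):
            if cls in list(self.clf.classes_):
                out[:, j] = proba[:, list(self.clf.classes_).index(cls)]
        return out

    def predict(self, vm_values) -> np.ndarray:
        X = np.asarray(vm_values, dtype=float).reshape(-1, 1)
        return self.clf.predict(X)


def _check_epochs(epochs: pd.DataFrame) -> pd.DataFrame:
    required = {"vm_value", "intensity"}
    if not required.issubset(epochs.columns):
        raise ValueError(f"epochs need columns {sorted(required)}")
    out = epochs.dropna(subset=["vm_value"]).copy()
    bad = set(out["intensity"]) - set(INTENSITIES)
    if bad:
        raise ValueError(f"unknown intensity labels: {sorted(bad)}")
    return out


def train(
    epochs: pd.DataFrame,
    mode: str = "multiclass",
    target: str | None = None,
    min_leaf: int = 20,
    max_depth: int = 8,
    seed: int = 0,
) -> TreeModel:
    """Grow a Gini CART on the VM feature alone.

    ``mode='one_vs_all'`` requires ``target`` (the positive class);
    single-class inputs are rejected.
    """
    epochs = _check_epochs(epochs)
    X = epochs["vm_value"].to_numpy(float).reshape(-1, 1)
    if mode == "one_vs_all":
        if target not in INTENSITIES:
            raise ValueError(f"target must be one of {INTENSITIES}")
        y = (epochs["intensity"] == target).to_numpy()
    elif mode == "multiclass":
        y = epochs["intensity"].to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf,
        max_depth=max_depth,
        random_state=seed,
    )
    clf.fit(X, y)
    return TreeModel(
        mode=mode,
        target=target,
        clf=clf,
        classes=tuple(clf.classes_),
        min_leaf=min_leaf,
        max_depth=max_depth,
        seed=seed,
    )


@dataclass
class ClassMetrics:
    auc: float | None
    auc_ci: tuple[float, float] | None
    sensitivity: float | None
    specificity: float | None
    n_positive: int
    n_negative: int


@dataclass
class EvaluationReport:
    mode: str
    per_class: dict[str, ClassMetrics]
    confusion: pd.DataFrame | None   # multiclass only; rows = observed
    n_epochs: int

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "n_epochs": self.n_epochs,
            "per_class": {
                cls: {
                    "auc": m.auc,
                    "auc_ci": list(m.auc_ci) if m.auc_ci else None,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "n_positive": m.n_positive,
                    "n_negative": m.n_negative,
                }
                for cls, m in self.per_class.items()
            },
            "confusion": None
            if self.confusion is None
            else self.confusion.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path  # noqa: PLC0415

            Path(path).write_text(text)
        return text


def _binary_metrics(y_true, score, y_hat, n_boot, rng) -> ClassMetrics:
    npos = int(np.sum(y_true))
    nneg = int(np.size(y_true) - npos)
    if npos == 0 or nneg == 0:
        return ClassMetrics(None, None, None, None, npos, nneg)
    auc = float(roc_auc_score(y_true, score))
    n = len(y_true)
    boots = np.empty(n_boot)
    y_arr = np.asarray(y_true)
    s_arr = np.asarray(score, dtype=float)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y_arr[idx]
        if yb.all() or not yb.any():
            boots[b] = np.nan
            continue
        boots[b] = roc_auc_score(yb, s_arr[idx])
    ok = boots[np.isfinite(boots)]
    ci = (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))
    tp = int(np.sum(y_arr & y_hat))
    fn = int(np.sum(y_arr & ~y_hat))
    tn = int(np.sum(~y_arr & ~y_hat))
    fp = int(np.sum(~y_arr & y_hat))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ClassMetrics(auc, ci, sens, spec, npos, nneg)


def evaluate(
    model: TreeModel,
    epochs: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Score labeled epochs with a trained tree.

    Bootstrap CIs resample epochs with replacement (seeded); a class with
    no members in ``epochs`` reports missing metrics.
    """
    epochs = _check_epochs(epochs)
    vm = epochs["vm_value"].to_numpy(float)
    labels = epochs["intensity"].to_numpy()
    rng = np.random.default_rng(seed)
    per_class: dict[str, ClassMetrics] = {}
    confusion = None
    if model.mode == "one_vs_all":
        y = labels == model.target
        score = model.scores(vm)
        y_hat = model.predict(vm)
        per_class[model.target] = _binary_metrics(y, score, y_hat, n_boot, rng)
    else:
        scores = model.scores(vm)
        pred = model.predict(vm)
        for j, cls in enumerate(INTENSITIES):
            y = labels == cls
            per_class[cls] = _binary_metrics(y, scores[:, j], pred == cls, n_boot, rng)
        cm = confusion_matrix(labels, pred, labels=list(INTENSITIES))
        confusion = pd.DataFrame(
            cm,
            index=[f"obs_{c}" for c in INTENSITIES],
            columns=[f"est_{c}" for c in INTENSITIES],
        )
    return EvaluationReport(
        mode=model.mode,
        per_class=per_class,
        confusion=confusion,
        n_epochs=len(epochs),
    )


def train_cart_suite(
    epochs: pd.DataFrame,
    min_leaf: int = 20,
    max_depth: int = 8,
    seed: int = 0,
) -> dict:
    """Train the full study suite: three one-vs-all trees plus one MCART."""
    suite = {
        f"cart_{cls}": train(
            epochs, "one_vs_all", cls, min_leaf=min_leaf, max_depth=max_depth, seed=seed
        )
        for cls in INTENSITIES
    }
    suite["mcart"] = train(
        epochs, "multiclass", min_leaf=min_leaf, max_depth=max_depth, seed=seed
    )
    return suite


def model_to_json(model: TreeModel, path=None) -> str:
    """Serialize the fitted tree (thresholds + leaf posteriors)."""
    t = model.clf.tree_
    nodes = []
    for i in range(t.node_count):
        nodes.append(
            {
                "left": int(t.children_left[i]),
                "right": int(t.children_right[i]),
                "threshold": float(t.threshold[i]) if t.children_left[i] != -1 else None,
                "value": t.value[i].ravel().tolist(),
            }
        )
    payload = {
        "mode": model.mode,
        "target": model.target,
        "classes": [str(c) for c in model.classes],
        "min_leaf": model.min_leaf,
        "max_depth": model.max_depth,
        "seed": model.seed,
        "nodes": nodes,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        from pathlib import Path  # noqa: PLC0415

        Path(path).write_text(text)
    return text
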