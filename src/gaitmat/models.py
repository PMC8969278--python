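"""Grouped cross-validated training and evaluation of LR / SVM / XGB classifiers.

Rows (footfalls) sharing a visit id always stay in the same fold, both in
the outer evaluation split and in the inner grid-search and size-selection
splits, so a subject's data never appears in train and test simultaneously.
Hyperparameters come from an exhaustive grid search over the default grids
below; metrics are pooled over the outer folds (micro-averaged confusion
counts), and ROC / precision-recall curves are built from the pooled
decision scores (probability for LR, margin for SVM and XGB).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .exceptions import CurveError, ParameterError
from .preprocess import (FEATURE_SETS, FeatureSelector, FeatureSetSpec, ZScaler,
                         _balance_lenient, grouped_folds, normalize_by_height)

logger = logging.getLogger(__name__)

#: default hyperparameter grids.  The LR grid is the Cartesian product of
#: solvers {newton-cg, lbfgs, liblinear}, penalties {l1, l2} and six C
#: values, restricted to solver/penalty pairs the optimizer supports
#: (l1 requires liblinear here; elasticnet needs a solver outside the grid
#: and is omitted).
DEFAULT_GRIDS = {
    "lr": {
        "solver": ["newton-cg", "lbfgs", "liblinear"],
        "penalty": ["l1", "l2"],
        "C": [1000, 100, 10, 1.0, 0.1, 0.01],
    },
    "svm": {
        "kernel": ["poly", "rbf", "sigmoid"],
        "C": [5, 3, 1.0, 0.5, 0.1],
        "degree": [3, 4, 5],
    },
    "xgb": {
        "max_depth": [2, 3],
        "eta": [0.3, 0.4],
        "objective": ["binary:logistic", "binary:logitraw", "binary:hinge"],
    },
}

_LR_VALID = {("newton-cg", "l2"), ("lbfgs", "l2"), ("liblinear", "l1"),
             ("liblinear", "l2")}


def grid_combinations(algorithm: str, grid: dict | None = None) -> list[dict]:
    """Expand a grid dict into an ordered list of valid parameter dicts."""
    grid = grid or DEFAULT_GRIDS[algorithm]
    names = list(grid)
    combos = [dict(zip(names, values))
              for values in itertools.product(*(grid[n] for n in names))]
    if algorithm == "lr":
        combos = [c for c in combos if (c["solver"], c["penalty"]) in _LR_VALID]
    if not combos:
        raise ParameterError("empty hyperparameter grid")
    return combos


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate a classifier for one grid combination."""
    if algorithm == "lr":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if algorithm == "svm":
        return SVC(random_state=seed, **params)
    if algorithm == "xgb":
        p = dict(params)
        eta = p.pop("eta", 0.3)
        return XGBClassifier(learning_rate=eta, n_estimators=100,
                             random_state=seed, verbosity=0, **p)
    raise ParameterError(f"unknown algorithm {algorithm!r}")


def decision_scores(algorithm: str, model, X: np.ndarray) -> np.ndarray:
    """Continuous decision values for ROC/PR sweeps."""
    if algorithm == "svm":
        return model.decision_function(X)
    if algorithm == "xgb":
        return np.asarray(model.predict(X, output_margin=True), float)
    return model.predict_proba(X)[:, 1]


@dataclass
class ModelConfig:
    """One algorithm plus its hyperparameter grid."""

    algorithm: str  # "lr" | "svm" | "xgb"
    grid: dict | None = None
    seed: int = 0

    def combinations(self) -> list[dict]:
        return grid_combinations(self.algorithm, self.grid)


# ---------------------------------------------------------------------------
# cross-validation primitives
# ---------------------------------------------------------------------------

def grouped_kfold(groups, k: int, seed=0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded grouped k-fold partition (see :func:`preprocess.grouped_folds`)."""
    return list(grouped_folds(groups, k, seed))


def _cv_accuracy(X: pd.DataFrame, y, groups, factory, folds=5, seed=0, smote_k=5):
    """Mean grouped-CV accuracy with per-fold SMOTE balancing and scaling."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    accs = []
    for tr, te in grouped_folds(groups, folds, rng):
        if len(np.unique(y[tr])) < 2:
            continue  # degenerate grouped fold on tiny cohorts
        Xtr, ytr = _balance_lenient(X.iloc[tr].to_numpy(float), y[tr], smote_k, rng)
        scaler = ZScaler().fit(Xtr)
        clf = factory()
        clf.fit(scaler.transform(Xtr), ytr)
        pred = clf.predict(scaler.transform(X.iloc[te].to_numpy(float)))
        accs.append(float(np.mean(pred == y[te])))
    if not accs:
        raise ParameterError("every inner fold was single-class")
    return float(np.mean(accs))


def grid_search(config: ModelConfig, X: pd.DataFrame, y, groups,
                inner_folds: int = 5, seed: int = 0, smote_k: int = 5) -> dict:
    """Exhaustive grouped-CV grid search; returns the best parameter dict.

    Every combination is evaluated with the same inner folds; the highest
    mean accuracy wins, ties going to the first combination in grid order.
    Combinations that fail to fit are skipped with a warning; if all fail an
    error lists the failures.
    """
    combos = config.combinations()
    folds = min(inner_folds, len(np.unique(groups)))
    best, best_acc, failures = None, -np.inf, []
    for params in combos:
        try:
            acc = _cv_accuracy(X, y, groups,
                               lambda: make_estimator(config.algorithm, params, seed),
                               folds=folds, seed=seed, smote_k=smote_k)
        except Exception as exc:  # noqa: BLE001 - collected and reported
            failures.append((params, str(exc)))
            continue
        if acc > best_acc:
            best, best_acc = params, acc
    if best is None:
        raise ParameterError(f"every grid combination failed: {failures}")
    if failures:
        logger.warning("%d grid combinations failed to fit", len(failures))
    return best


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy / precision / recall / F1 in percent from confusion counts.

    A metric with a zero denominator is reported as None (missing), not 0.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ParameterError("confusion counts must be nonnegative")
    if sum(counts) == 0:
        raise ParameterError("confusion counts are all zero")
    total = tp + tn + fp + fn
    acc = (tn + tp) / total * 100.0
    prec = tp / (tp + fp) * 100.0 if (tp + fp) > 0 else None
    rec = tp / (tp + fn) * 100.0 if (tp + fn) > 0 else None
    if prec is not None and rec is not None and (prec + rec) > 0:
        f1 = 2.0 * prec * rec / (prec + rec)
    else:
        f1 = None
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def roc_pr_curves(scores, labels) -> dict:
    """ROC and PR threshold sweeps with their areas.

    AUROC is the trapezoidal area under the ROC sweep (equivalently the
    concordance probability); AUPRC is the step-wise average precision.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if len(np.unique(labels)) < 2:
        raise CurveError("both classes must be present to sweep a curve")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    return {
        "roc_points": np.column_stack([fpr, tpr]),
        "pr_points": np.column_stack([rec, prec]),
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
    }


@dataclass
class EvalReport:
    """Pooled evaluation of one (feature set, algorithm) combination."""

    feature_set: str
    algorithm: str
    tp: int
    tn: int
    fp: int
    fn: int
    metrics: dict
    auroc: float
    auprc: float
    roc_points: np.ndarray
    pr_points: np.ndarray
    fold_metrics: list = field(default_factory=list)
    chosen_params: list = field(default_factory=list)
    selections: list = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set, "algorithm": self.algorithm,
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "metrics": self.metrics,
            "auroc": self.auroc, "auprc": self.auprc,
            "roc_points": np.asarray(self.roc_points).tolist(),
            "pr_points": np.asarray(self.pr_points).tolist(),
            "fold_metrics": self.fold_metrics,
            "chosen_params": self.chosen_params,
            "selections": self.selections,
        }


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def run_experiment(features: pd.DataFrame,
                   feature_sets=("standard", "augmented"),
                   algorithms=("lr", "svm", "xgb"),
                   grids: dict | None = None,
                   seed: int = 0,
                   outer_folds: int = 5,
                   inner_folds: int = 5,
                   smote_k: int = 5,
                   corr_threshold: float = 0.8) -> dict:
    """Full grouped-CV experiment over feature sets and algorithms.

    ``features`` is the table from
    :func:`gaitmat.features.assemble_feature_rows` (``class_label`` in
    {patient, control}; ``visit_id`` is the group key).  For each outer
    fold: height normalization, then the selection chain fit on the training
    rows only, grid search over grouped inner folds, a final model fit on
    the balanced training matrix, and prediction of the untouched test rows.

    Returns ``{"reports": {(set, algo): EvalReport}, "deltas": {...},
    "n_rows": int}``; deltas are augmented-minus-standard differences per
    algorithm and metric.  Fully reproducible under ``seed``.
    """
    rows = normalize_by_height(features)
    specs = [FEATURE_SETS[s] if isinstance(s, str) else s for s in feature_sets]
    needed = sorted({f for spec in specs for f in spec.all_features})
    rows = rows.dropna(subset=[c for c in needed if c in rows.columns]).reset_index(drop=True)
    y = (rows["class_label"] == "patient").astype(int).to_numpy()
    groups = rows["visit_id"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes must be present")

    outer = grouped_kfold(groups, min(outer_folds, len(np.unique(groups))), seed)
    reports: dict = {}
    for spec in specs:
        per_algo = {a: {"true": [], "pred": [], "score": [], "fold": [],
                        "params": [], "selections": []} for a in algorithms}
        for fold_no, (tr, te) in enumerate(outer):
            selector = FeatureSelector(feature_set=spec, corr_threshold=corr_threshold,
                                       smote_k=smote_k, cv=inner_folds,
                                       random_state=seed + fold_no)
            selector.fit(rows.iloc[tr], y[tr], groups=groups[tr])
            Xtr_bal, ytr_bal = selector.training_matrix()
            Xte = selector.transform(rows.iloc[te])

            final_numeric = [f for f in selector.final_features_
                             if f in selector.numeric_features_]
            cat = [f for f in selector.final_features_ if f not in final_numeric]
            from .preprocess import encode_categoricals
            Xsearch = encode_categoricals(rows.iloc[tr], spec)[final_numeric + cat]

            for algo in algorithms:
                cfg = ModelConfig(algorithm=algo,
                                  grid=None if grids is None else grids.get(algo))
                best = grid_search(cfg, Xsearch, y[tr], groups[tr],
                                   inner_folds=inner_folds, seed=seed + fold_no,
                                   smote_k=smote_k)
                model = make_estimator(algo, best, seed=seed + fold_no)
                model.fit(Xtr_bal, ytr_bal)
                pred = np.asarray(model.predict(Xte)).astype(int)
                score = decision_scores(algo, model, Xte)
                bucket = per_algo[algo]
                bucket["true"].append(y[te])
                bucket["pred"].append(pred)
                bucket["score"].append(score)
                bucket["fold"].append(fold_no)
                bucket["params"].append(best)
                bucket["selections"].append(selector.selection_.to_dict())

        for algo in algorithms:
            b = per_algo[algo]
            yt = np.concatenate(b["true"])
            yp = np.concatenate(b["pred"])
            sc = np.concatenate(b["score"])
            tp = int(np.sum((yt == 1) & (yp == 1)))
            tn = int(np.sum((yt == 0) & (yp == 0)))
            fp = int(np.sum((yt == 0) & (yp == 1)))
            fn = int(np.sum((yt == 1) & (yp == 0)))
            curves = roc_pr_curves(sc, yt)
            fold_metrics = []
            for f, (ti, pi) in enumerate(zip(b["true"], b["pred"])):
                fold_metrics.append({
                    "fold": f,
                    "accuracy": float(np.mean(pi == ti)) * 100.0,
                })
            reports[(spec.name, algo)] = EvalReport(
                feature_set=spec.name, algorithm=algo,
                tp=tp, tn=tn, fp=fp, fn=fn,
                metrics=confusion_metrics(tp, tn, fp, fn),
                auroc=curves["auroc"], auprc=curves["auprc"],
                roc_points=curves["roc_points"], pr_points=curves["pr_points"],
                fold_metrics=fold_metrics, chosen_params=b["params"],
                selections=b["selections"])

    deltas: dict = {}
    names = [s.name for s in specs]
    if "standard" in names and "augmented" in names:
        for algo in algorithms:
            std = reports[("standard", algo)]
            aug = reports[("augmented", algo)]
            deltas[algo] = {
                m: (None if std.metrics[m] is None or aug.metrics[m] is None
                    else aug.metrics[m] - std.metrics[m])
                for m in ("accuracy", "precision", "recall", "f1")
            }
            deltas[algo]["auroc"] = aug.auroc - std.auroc
            deltas[algo]["auprc"] = aug.auprc - std.auprc
    return {"reports": reports, "deltas": deltas, "n_rows": int(len(rows))}


def plot_curves(reports: dict, path_prefix) -> None:
    """Save ROC and PR curve plots for a set of evaluation reports."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for kind, xlab, ylab in (("roc", "False positive rate", "True positive rate"),
                             ("pr", "Recall", "Precision")):
        fig, ax = plt.subplots(figsize=(5, 4))
        for (set_name, algo), rep in reports.items():
            pts = rep.roc_points if kind == "roc" else rep.pr_points
            area = rep.auroc if kind == "roc" else rep.auprc
            ax.plot(pts[:, 0], pts[:, 1],
                    label=f"{algo.upper()} {set_name} ({area:.2f})", lw=1.2)
        if kind == "roc":
            ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        ax.legend(fontsize=7)
        fig.savefig(f"{path_prefix}_{kind}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
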