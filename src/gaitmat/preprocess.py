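"""Class balancing, scaling, correlation filtering and ANOVA feature selection.

The modelling pipeline applied to each training fold is:

  height normalization -> SMOTE balancing -> z-scaling (train statistics)
  -> Pearson correlation filter (|r| >= 0.8 removes the lower-ANOVA member)
  -> ANOVA-F ranking -> cross-validated choice of the subset size
  -> reintroduction of the categorical features.

Categorical features (foot type; toe direction in the augmented set) bypass
every numeric step and are appended to the final list.  All statistics are
computed on training data only; test rows are transformed with the fitted
training statistics.

:class:`FeatureSelector` wraps the whole chain as a scikit-learn style
estimator (``fit``/``transform``, fitted attributes with a trailing
underscore) so it composes with the grouped cross-validation driver in
:mod:`gaitmat.models`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import f_classif
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

#: features divided by subject height before modelling
HEIGHT_NORMALIZED = ("foot_length", "foot_width", "foot_area", "hull_area")


@dataclass(frozen=True)
class FeatureSetSpec:
    """Named feature set: ordered numeric columns plus categorical columns."""

    name: str
    numeric_features: tuple
    categorical_features: tuple

    @property
    def all_features(self) -> tuple:
        return self.numeric_features + self.categorical_features


_STANDARD_NUMERIC = (
    "step_time", "stride_time", "step_velocity", "stride_velocity",
    "single_support_time", "double_support_time", "stance_time",
    "toe_angle_signed", "step_length", "step_width",
    "stride_length", "stride_width", "base_width",
)

#: conventional spatiotemporal parameters plus the signed toe angle
STANDARD_SET = FeatureSetSpec(
    name="standard",
    numeric_features=_STANDARD_NUMERIC,
    categorical_features=("foot_type",),
)

#: the standard set with the signed toe angle split into magnitude +
#: direction, plus the geometric additions (foot dimensions, hull/BOS areas,
#: LOP deviation angle)
AUGMENTED_SET = FeatureSetSpec(
    name="augmented",
    numeric_features=tuple(f for f in _STANDARD_NUMERIC if f != "toe_angle_signed") + (
        "toe_angle_unsigned", "foot_length", "foot_width", "foot_area",
        "hull_area", "bos_area", "lop_deviation_angle",
    ),
    categorical_features=("foot_type", "toe_direction"),
)

FEATURE_SETS = {"standard": STANDARD_SET, "augmented": AUGMENTED_SET}


@dataclass
class SelectionResult:
    """Record of one feature-selection run on a training fold."""

    dropped_by_correlation: list = field(default_factory=list)  # (feature, partner, r)
    anova_scores: dict = field(default_factory=dict)
    chosen_size: int = 0
    size_accuracies: list = field(default_factory=list)
    final_features: list = field(default_factory=list)

    def to_dict(self):
        return {
            "dropped_by_correlation": [(f, p, float(r)) for f, p, r in self.dropped_by_correlation],
            "anova_scores": {k: float(v) for k, v in self.anova_scores.items()},
            "chosen_size": int(self.chosen_size),
            "size_accuracies": [float(a) for a in self.size_accuracies],
            "final_features": list(self.final_features),
        }


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def normalize_by_height(rows: pd.DataFrame, columns=HEIGHT_NORMALIZED) -> pd.DataFrame:
    """Divide anthropometric features by the subject's height (cm).

    Only the named columns present in ``rows`` are transformed; everything
    else is untouched.  Raises :class:`ParameterError` on missing or
    non-positive heights.
    """
    if "height_cm" not in rows.columns:
        raise ParameterError("rows lack a height_cm column")
    h = rows["height_cm"].to_numpy(float)
    if np.any(~np.isfinite(h)) or np.any(h <= 0):
        bad = rows.index[~np.isfinite(h) | (h <= 0)][0]
        raise ParameterError(f"missing or non-positive height at row {bad}")
    out = rows.copy()
    for col in columns:
        if col in out.columns:
            out[col] = out[col] / h
    return out


def smote_balance(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                  seed=0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling until the two classes are balanced.

    Each synthetic sample lies on the segment between a randomly chosen
    minority sample and one of its ``k_neighbors`` nearest minority
    neighbours (both choices random).  Already-balanced input is returned
    unchanged.  Deterministic under ``seed``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ParameterError("SMOTE balancing expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    Xmin = X[y == minority]
    n_needed = int(abs(counts[0] - counts[1]))
    if len(Xmin) <= k_neighbors:
        raise ParameterError(
            f"minority class has {len(Xmin)} samples <= k_neighbors={k_neighbors}; "
            "use a smaller k")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)
    neighbours = idx[:, 1:]  # drop self
    base = rng.integers(0, len(Xmin), size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    gaps = rng.uniform(0.0, 1.0, size=n_needed)
    partners = neighbours[base, pick]
    synthetic = Xmin[base] + gaps[:, None] * (Xmin[partners] - Xmin[base])
    Xb = np.vstack([X, synthetic])
    yb = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return Xb, yb


def _balance_lenient(X, y, k_neighbors, rng):
    """SMOTE for inner-CV folds: shrink k to fit a tiny minority, pass
    through unbalanced when the fold cannot support synthesis at all."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2 or counts[0] == counts[1]:
        return np.asarray(X, float), y
    k = min(k_neighbors, int(counts.min()) - 1)
    return smote_balance(X, y, k_neighbors=k, seed=rng)


class ZScaler:
    """Column-wise z-scaling with training statistics (population sd).

    Zero-variance columns are centred but not divided (scale 1) and listed
    in ``zero_variance_``.
    """

    def fit(self, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.zero_variance_ = list(np.flatnonzero(sd == 0.0))
        if self.zero_variance_:
            logger.warning("zero-variance columns %s centred but not scaled",
                           self.zero_variance_)
        self.scale_ = np.where(sd == 0.0, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def anova_rank(X: pd.DataFrame, y) -> pd.Series:
    """One-way ANOVA F score per feature, sorted descending.

    For two classes F equals the squared pooled two-sample t statistic.  A
    feature with zero within-group variance but distinct group means gets an
    infinite score and ranks first.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ParameterError("ANOVA ranking expects two classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with np.errstate(divide="ignore", invalid="ignore"):
            F, _ = f_classif(X.to_numpy(float), y)
    F = np.asarray(F, float)
    # separate "no within-group variance" (perfect separation -> +inf) from
    # "no variance at all" (uninformative -> 0)
    for j, col in enumerate(X.columns):
        if not np.isfinite(F[j]):
            v = X[col].to_numpy(float)
            means = [v[y == c].mean() for c in np.unique(y)]
            wss = sum(((v[y == c] - m) ** 2).sum() for c, m in zip(np.unique(y), means))
            F[j] = np.inf if (wss == 0.0 and means[0] != means[1]) else 0.0
            if np.isinf(F[j]):
                logger.warning("feature %s separates the classes perfectly", col)
    return pd.Series(F, index=X.columns).sort_values(ascending=False, kind="stable")


def correlation_filter(X: pd.DataFrame, threshold: float = 0.8,
                       priority: pd.Series | None = None):
    """Drop numeric features until no retained pair has |Pearson r| >= threshold.

    Features are visited in priority order (descending ANOVA F when given,
    otherwise column order); a feature correlated at |r| >= threshold with an
    already-retained one is dropped.  NaN correlations (constant columns)
    count as 0 with a warning.

    Returns ``(retained, drop_log)`` with ``drop_log`` entries
    ``(dropped, retained_partner, r)``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("correlation threshold must be in (0, 1]")
    corr = X.corr(method="pearson")
    if corr.isna().any().any():
        logger.warning("NaN correlations (constant column?) treated as 0")
        corr = corr.fillna(0.0)
    order = list(priority.index) if priority is not None else list(X.columns)
    retained, drop_log = [], []
    for feat in order:
        partner = None
        for kept in retained:
            r = corr.at[feat, kept]
            if abs(r) >= threshold:
                partner = (kept, float(r))
                break
        if partner is None:
            retained.append(feat)
        else:
            drop_log.append((feat, partner[0], partner[1]))
    return retained, drop_log


def grouped_folds(groups, k: int, seed=0):
    """Seeded k-fold partition of group labels, balanced in group counts (+-1).

    Yields ``(train_idx, test_idx)`` row-index arrays; no group ever
    straddles a fold boundary.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if k > len(uniq):
        raise ParameterError(f"k={k} exceeds the number of groups ({len(uniq)})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    folds = np.array_split(perm, k)
    idx = np.arange(len(groups))
    for fold_groups in folds:
        test = np.isin(groups, fold_groups)
        yield idx[~test], idx[test]


def select_size(X: pd.DataFrame, y, groups, ranked_features,
                folds: int = 5, seed: int = 0, smote_k: int = 5,
                estimator_factory=None):
    """Cross-validated choice of the ANOVA subset size.

    For every candidate size ``s`` (1..len(ranked_features)), a grouped
    k-fold CV with a default-configuration SVM measures the mean accuracy of
    the top-``s`` features; each inner training fold is SMOTE-balanced and
    z-scaled independently.  Returns ``(chosen_size, accuracies)``; ties go
    to the smallest size.
    """
    ranked_features = list(ranked_features)
    if not ranked_features:
        raise ParameterError("no features to select from")
    if estimator_factory is None:
        estimator_factory = lambda: SVC()
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    splits = list(grouped_folds(groups, folds, rng))
    accuracies = []
    for s in range(1, len(ranked_features) + 1):
        cols = ranked_features[:s]
        accs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                continue  # degenerate grouped fold on tiny cohorts
            Xtr, ytr = _balance_lenient(X.iloc[tr][cols].to_numpy(float), y[tr],
                                        smote_k, rng)
            scaler = ZScaler().fit(Xtr)
            clf = estimator_factory()
            clf.fit(scaler.transform(Xtr), ytr)
            pred = clf.predict(scaler.transform(X.iloc[te][cols].to_numpy(float)))
            accs.append(float(np.mean(pred == y[te])))
        if not accs:
            raise ParameterError("every inner fold was single-class; "
                                 "too few groups per class")
        accuracies.append(float(np.mean(accs)))
    chosen = int(np.argmax(accuracies)) + 1  # argmax takes the first (smallest) max
    return chosen, accuracies


def finalize_features(survivors, spec: FeatureSetSpec) -> list:
    """Append the spec's categorical features to the numeric survivors."""
    if not survivors:
        logger.warning("no numeric survivors; final set is categorical only")
    return list(survivors) + list(spec.categorical_features)


# ---------------------------------------------------------------------------
# sklearn-style wrapper
# ---------------------------------------------------------------------------

def encode_categoricals(X: pd.DataFrame, spec: FeatureSetSpec) -> pd.DataFrame:
    """Numeric view of the spec's columns (foot_type mapped to 0/1)."""
    out = X[list(spec.all_features)].copy()
    if "foot_type" in out.columns and out["foot_type"].dtype == object:
        out["foot_type"] = (out["foot_type"] == "right").astype(float)
    return out.astype(float)


class FeatureSelector(BaseEstimator, TransformerMixin):
    """Fit the balancing/scaling/selection chain on a training fold.

    Parameters
    ----------
    feature_set : str or FeatureSetSpec, default "standard"
    corr_threshold : float, default 0.8
    smote_k : int, default 5
    cv : int, default 5
        Inner grouped folds for the subset-size search.
    random_state : int, default 0

    Attributes (after ``fit``)
    --------------------------
    selection_ : SelectionResult
    final_features_ : list of retained column names (numeric + categorical)
    scaler_ : ZScaler fitted on the balanced training numerics
    balanced_X_, balanced_y_ : the SMOTE-balanced training matrix over all
        spec columns (categoricals encoded), for downstream model fitting
    """

    def __init__(self, feature_set="standard", corr_threshold=0.8, smote_k=5,
                 cv=5, random_state=0):
        self.feature_set = feature_set
        self.corr_threshold = corr_threshold
        self.smote_k = smote_k
        self.cv = cv
        self.random_state = random_state

    def _spec(self) -> FeatureSetSpec:
        if isinstance(self.feature_set, FeatureSetSpec):
            return self.feature_set
        return FEATURE_SETS[self.feature_set]

    def fit(self, X: pd.DataFrame, y, groups=None):
        spec = self._spec()
        y = np.asarray(y)
        if groups is None:
            groups = np.arange(len(y))
        M = encode_categoricals(X, spec)
        numeric = list(spec.numeric_features)

        Xb, yb = smote_balance(M.to_numpy(float), y, k_neighbors=self.smote_k,
                               seed=self.random_state)
        Mb = pd.DataFrame(Xb, columns=M.columns)
        self.scaler_ = ZScaler().fit(Xb[:, [M.columns.get_loc(c) for c in numeric]])
        scaled = pd.DataFrame(self.scaler_.transform(
            Xb[:, [M.columns.get_loc(c) for c in numeric]]), columns=numeric)

        scores = anova_rank(scaled, yb)
        retained, drop_log = correlation_filter(scaled, self.corr_threshold,
                                                priority=scores)
        ranked = [f for f in scores.index if f in retained]
        chosen, accs = select_size(M[numeric], y, groups, ranked,
                                   folds=min(self.cv, len(np.unique(groups))),
                                   seed=self.random_state, smote_k=self.smote_k)
        survivors = ranked[:chosen]
        final = finalize_features(survivors, spec)

        self.selection_ = SelectionResult(
            dropped_by_correlation=drop_log,
            anova_scores={k: float(v) for k, v in scores.items()},
            chosen_size=chosen, size_accuracies=accs, final_features=final)
        self.final_features_ = final
        self.numeric_features_ = numeric
        self.balanced_X_ = Mb
        self.balanced_y_ = yb
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Scale the final numeric features with the fitted training statistics
        and append the categorical columns."""
        check_is_fitted(self, "final_features_")
        spec = self._spec()
        M = encode_categoricals(X, spec)
        return self._transform_encoded(M)

    def _transform_encoded(self, M: pd.DataFrame) -> np.ndarray:
        spec = self._spec()
        numeric_final = [f for f in self.final_features_
                         if f in self.numeric_features_]
        cat_final = [f for f in self.final_features_
                     if f in spec.categorical_features]
        scaled_all = self.scaler_.transform(M[self.numeric_features_].to_numpy(float))
        scaled = pd.DataFrame(scaled_all, columns=self.numeric_features_,
                              index=M.index)
        parts = [scaled[numeric_final].to_numpy(float)]
        if cat_final:
            parts.append(M[cat_final].to_numpy(float))
        return np.hstack(parts)

    def training_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """The balanced, transformed training design matrix and labels."""
        check_is_fitted(self, "final_features_")
        return self._transform_encoded(self.balanced_X_), self.balanced_y_
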