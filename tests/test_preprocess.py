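"""Balancing, scaling, correlation filtering and ANOVA selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitmat import (AUGMENTED_SET, STANDARD_SET, FeatureSelector,
                     ParameterError, ZScaler, anova_rank, correlation_filter,
                     finalize_features, normalize_by_height, select_size,
                     smote_balance)
from gaitmat.preprocess import grouped_folds


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

class TestSmote:
    def test_balances_sixty_against_ten(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(4, 1, (10, 3))])
        y = np.array([0] * 60 + [1] * 10)
        Xb, yb = smote_balance(X, y, seed=0)
        assert (yb == 0).sum() == (yb == 1).sum() == 60
        assert len(Xb) == 120

    def test_balanced_input_unchanged(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        y = np.array([0, 1] * 5)
        Xb, yb = smote_balance(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_synthetic_points_lie_on_minority_segments(self):
        # 1-D minority {0, 1, 2}; every synthetic value must be a convex
        # combination of a minority point and one of its 2 nearest neighbours
        X = np.array([[0.0], [1.0], [2.0]] + [[10.0]] * 12)
        y = np.array([1, 1, 1] + [0] * 12)
        Xb, yb = smote_balance(X, y, k_neighbors=2, seed=0)
        synth = Xb[len(X):][:, 0]
        assert len(synth) == 9
        assert ((synth >= 0.0) & (synth <= 2.0)).all()
        minority = np.array([0.0, 1.0, 2.0])
        for v in synth:
            on_segment = any(
                min(a, b) - 1e-9 <= v <= max(a, b) + 1e-9
                for a in minority for b in minority if a != b)
            assert on_segment

    def test_segment_membership_in_higher_dimensions(self):
        rng = np.random.default_rng(3)
        Xmin = rng.normal(0, 1, (8, 4))
        X = np.vstack([Xmin, rng.normal(5, 1, (30, 4))])
        y = np.array([1] * 8 + [0] * 30)
        Xb, yb = smote_balance(X, y, k_neighbors=5, seed=1)
        for s in Xb[len(X):]:
            # collinearity with some minority pair to 1e-9
            ok = False
            for i in range(len(Xmin)):
                for j in range(len(Xmin)):
                    if i == j:
                        continue
                    d = Xmin[j] - Xmin[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    t = float((s - Xmin[i]) @ d) / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.allclose(Xmin[i] + t * d, s, atol=1e-9):
                        ok = True
            assert ok

    def test_tiny_minority_raises_with_guidance(self):
        X = np.arange(24, dtype=float).reshape(12, 2)
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ParameterError, match="smaller k"):
            smote_balance(X, y, k_neighbors=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (9, 2))])
        y = np.array([0] * 30 + [1] * 9)
        a = smote_balance(X, y, seed=7)[0]
        b = smote_balance(X, y, seed=7)[0]
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# scaling and height normalization
# ---------------------------------------------------------------------------

class TestZScaler:
    def test_scales_to_zero_mean_unit_sd(self):
        X = np.array([[1.0], [2.0], [3.0]])
        z = ZScaler().fit_transform(X)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9
        # population sd of {1,2,3} is sqrt(2/3)
        assert np.allclose(z[:, 0], np.array([-1, 0, 1]) / np.sqrt(2 / 3))

    def test_constant_column_centred_not_divided(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        sc = ZScaler().fit(X)
        assert sc.zero_variance_ == [0]
        out = sc.transform(X)
        assert np.allclose(out[:, 0], 0.0)

    def test_test_rows_scaled_with_train_statistics(self):
        train = np.arange(10, dtype=float)[:, None]
        test = train + 5.0
        sc = ZScaler().fit(train)
        assert abs(sc.transform(train).mean()) < 1e-9
        assert sc.transform(test).mean() > 1.0  # shifted split keeps its shift


class TestHeightNormalization:
    def _rows(self):
        return pd.DataFrame({
            "height_cm": [160.0, 200.0],
            "foot_length": [24.0, 24.0], "foot_width": [9.0, 9.0],
            "foot_area": [240.0, 240.0], "hull_area": [230.0, 230.0],
            "step_length": [60.0, 60.0],
        })

    def test_divides_the_four_anthropometric_columns(self):
        out = normalize_by_height(self._rows())
        assert out.at[0, "foot_length"] == pytest.approx(24.0 / 160.0)
        assert out.at[1, "foot_length"] == pytest.approx(24.0 / 200.0)
        # identical feet, heights 200 vs 150-style ratio check
        assert (out.at[0, "foot_area"] / out.at[1, "foot_area"]
                == pytest.approx(200.0 / 160.0))

    def test_step_length_untouched(self):
        out = normalize_by_height(self._rows())
        assert (out["step_length"] == 60.0).all()

    def test_missing_or_zero_height_rejected(self):
        rows = self._rows()
        rows.at[0, "height_cm"] = 0.0
        with pytest.raises(ParameterError):
            normalize_by_height(rows)


# ---------------------------------------------------------------------------
# correlation filter and ANOVA ranking
# ---------------------------------------------------------------------------

class TestCorrelationFilter:
    def test_perfectly_correlated_pair_loses_one(self):
        x = np.arange(50.0)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        retained, dropped = correlation_filter(X, 0.8)
        assert len(retained) == 1
        assert len(dropped) == 1
        assert abs(dropped[0][2]) == pytest.approx(1.0)

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (2000, 6)),
                         columns=[f"f{i}" for i in range(6)])
        retained, dropped = correlation_filter(X, 0.8)
        assert len(retained) == 6 and not dropped

    def test_priority_rule_drops_lower_scoring_member(self):
        # stride ~ 2 x step: the pair is collinear; with step ranked higher
        # the stride member must be the one dropped
        rng = np.random.default_rng(1)
        step = rng.normal(60, 5, 400)
        stride = 2 * step + rng.normal(0, 0.5, 400)
        other = rng.normal(0, 1, 400)
        X = pd.DataFrame({"step_length": step, "stride_length": stride,
                          "other": other})
        priority = pd.Series([3.0, 2.0, 1.0],
                             index=["step_length", "stride_length", "other"])
        retained, dropped = correlation_filter(X, 0.8, priority=priority)
        assert "step_length" in retained
        assert dropped[0][0] == "stride_length"
        assert dropped[0][1] == "step_length"

    def test_no_retained_pair_exceeds_threshold(self, noisy_table):
        X = noisy_table[list(STANDARD_SET.numeric_features)].dropna()
        retained, _ = correlation_filter(X, 0.8)
        corr = X[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.8


class TestAnovaRank:
    def test_hand_computed_two_group_f(self):
        # groups A={0,1}, B={2,3}: F = MSB/MSW = 8/1 = 8
        X = pd.DataFrame({"f": [0.0, 1.0, 2.0, 3.0]})
        scores = anova_rank(X, np.array([0, 0, 1, 1]))
        assert scores["f"] == pytest.approx(8.0)

    def test_mirrored_groups_score_zero(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 0.0, 1.0]})
        scores = anova_rank(X, np.array([0, 0, 1, 1]))
        assert scores["f"] < 1e-9

    def test_f_equals_squared_t_on_random_columns(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 40)
        X = pd.DataFrame(rng.normal(0, 1, (40, 10)),
                         columns=[f"f{i}" for i in range(10)])
        scores = anova_rank(X, y)
        for col in X.columns:
            t = stats.ttest_ind(X[col][y == 0], X[col][y == 1], equal_var=True)
            assert scores[col] == pytest.approx(t.statistic ** 2, rel=1e-9)

    def test_perfect_separator_ranks_first_with_infinite_score(self):
        X = pd.DataFrame({"sep": [0.0, 0.0, 1.0, 1.0],
                          "noise": [0.5, 0.1, 0.4, 0.2]})
        scores = anova_rank(X, np.array([0, 0, 1, 1]))
        assert np.isinf(scores["sep"])
        assert scores.index[0] == "sep"


# ---------------------------------------------------------------------------
# size selection and finalization
# ---------------------------------------------------------------------------

class TestSelectSize:
    def _data(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({
            "signal": y * 4.0 + rng.normal(0, 0.3, n),
            "noise1": rng.normal(0, 1, n),
            "noise2": rng.normal(0, 1, n),
        })
        groups = np.arange(n) // 4
        return X, y, groups

    def test_single_informative_feature_selects_size_one(self):
        X, y, groups = self._data()
        chosen, accs = select_size(X, y, groups, ["signal", "noise1", "noise2"],
                                   folds=5, seed=0)
        assert chosen == 1
        assert accs[0] > 0.95

    def test_identical_copies_tie_break_to_smallest(self):
        X, y, groups = self._data()
        X = pd.DataFrame({"a": X["signal"], "b": X["signal"], "c": X["signal"]})
        chosen, accs = select_size(X, y, groups, ["a", "b", "c"], folds=5, seed=0)
        assert chosen == 1
        assert accs[0] == max(accs)

    def test_empty_ranking_is_an_error(self):
        X, y, groups = self._data()
        with pytest.raises(ParameterError):
            select_size(X, y, groups, [], folds=5, seed=0)


def test_finalize_reintroduces_categoricals():
    nine = [f"n{i}" for i in range(9)]
    assert len(finalize_features(nine, STANDARD_SET)) == 10
    thirteen = [f"n{i}" for i in range(13)]
    assert len(finalize_features(thirteen, AUGMENTED_SET)) == 15
    assert finalize_features([], STANDARD_SET) == ["foot_type"]


def test_feature_set_specs_are_consistent():
    std = set(STANDARD_SET.numeric_features) - {"toe_angle_signed"}
    assert std <= set(AUGMENTED_SET.numeric_features)
    assert "toe_angle_unsigned" in AUGMENTED_SET.numeric_features
    assert "toe_direction" in AUGMENTED_SET.categorical_features
    for spec in (STANDARD_SET, AUGMENTED_SET):
        assert len(set(spec.all_features)) == len(spec.all_features)


# ---------------------------------------------------------------------------
# grouped folds and the fitted selector
# ---------------------------------------------------------------------------

def test_grouped_folds_partition_groups():
    groups = np.repeat(np.arange(10), 3)
    folds = list(grouped_folds(groups, 5, seed=0))
    assert len(folds) == 5
    seen = []
    for tr, te in folds:
        assert set(groups[tr]).isdisjoint(set(groups[te]))
        assert len(set(groups[te])) == 2
        seen.extend(groups[te])
    assert sorted(set(seen)) == list(range(10))


def test_selector_fits_and_transforms(noisy_table):
    rows = normalize_by_height(noisy_table).dropna(
        subset=list(AUGMENTED_SET.numeric_features)).reset_index(drop=True)
    y = (rows["class_label"] == "patient").astype(int).to_numpy()
    sel = FeatureSelector(feature_set="augmented", random_state=0, cv=3, smote_k=3)
    sel.fit(rows, y, groups=rows["visit_id"].to_numpy())
    assert sel.selection_.chosen_size >= 1
    assert set(sel.final_features_) <= set(AUGMENTED_SET.all_features)
    assert "foot_type" in sel.final_features_ and "toe_direction" in sel.final_features_
    Xt = sel.transform(rows)
    assert Xt.shape == (len(rows), len(sel.final_features_))
    Xb, yb = sel.training_matrix()
    assert (yb == 0).sum() == (yb == 1).sum()
    # every retained pair respects the correlation threshold on the
    # balanced training matrix
    numeric = [f for f in sel.final_features_ if f in sel.numeric_features_]
    corr = sel.balanced_X_[numeric].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert corr.max() < 0.8 + 1e-12


def test_selector_statistics_ignore_test_rows(noisy_table):
    """Shuffling labels outside the training fold changes nothing fitted."""
    rows = normalize_by_height(noisy_table).dropna(
        subset=list(STANDARD_SET.numeric_features)).reset_index(drop=True)
    y = (rows["class_label"] == "patient").astype(int).to_numpy()
    groups = rows["visit_id"].to_numpy()
    train = np.flatnonzero(groups != groups[-1])
    sel_a = FeatureSelector(feature_set="standard", random_state=0, cv=2, smote_k=3)
    sel_a.fit(rows.iloc[train], y[train], groups=groups[train])
    y_shuffled = y.copy()
    y_shuffled[groups == groups[-1]] = 1 - y_shuffled[groups == groups[-1]]
    sel_b = FeatureSelector(feature_set="standard", random_state=0, cv=2, smote_k=3)
    sel_b.fit(rows.iloc[train], y_shuffled[train], groups=groups[train])
    assert sel_a.selection_.to_dict() == sel_b.selection_.to_dict()
    assert np.allclose(sel_a.scaler_.mean_, sel_b.scaler_.mean_)
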