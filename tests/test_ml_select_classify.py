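"""Feature selection, subset search, ROC identities, leakage guard."""

import numpy as np
import pandas as pd
import pytest

from ckdmrm import (
    exhaustive_subset_search,
    make_binary_labels,
    pool_top_k,
    rank_by_effect_size,
    rank_by_pvalue,
    rank_by_tree_importance,
    roc_curve,
    screen_single_features,
)
from ckdmrm.ml_select_classify import (
    FeatureRanking,
    nested_cv_best_feature_auc,
)


def _labeled_data(seed=0, n_per=20, n_noise=6, effect=3.0):
    """Balanced two-class data with one planted feature of Cohen's d ~= effect."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    y = pd.Series([0] * n_per + [1] * n_per, index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise + 1)),
        index=y.index,
        columns=[f"P{j}" for j in range(n_noise + 1)],
    )
    X.loc[y == 1, "P0"] += effect
    return X, y


class TestLabels:
    def test_mild_severe_composition(self):
        groups = pd.Series(
            {"a": "control", "b": "MCD", "c": "mFSGS", "d": "sFSGS", "e": "MN"}
        )
        y = make_binary_labels(groups)
        assert "a" not in y.index  # controls excluded
        assert y.to_dict() == {"b": 0, "c": 0, "d": 1, "e": 1}


class TestRankings:
    def test_planted_feature_ranks_first(self):
        X, y = _labeled_data()
        assert rank_by_pvalue(X, y).proteins[0] == "P0"
        assert rank_by_effect_size(X, y).proteins[0] == "P0"

    def test_single_feature_matrix(self):
        X, y = _labeled_data(n_noise=0)
        assert rank_by_pvalue(X, y).proteins == ("P0",)

    def test_identical_columns_tie_broken_by_name(self):
        X, y = _labeled_data(n_noise=0)
        X2 = X.copy()
        X2["A0"] = X2["P0"]
        r = rank_by_effect_size(X2, y)
        assert r.proteins == ("A0", "P0")

    def test_single_class_rejected(self):
        X, y = _labeled_data()
        with pytest.raises(ValueError, match="single class"):
            rank_by_pvalue(X, y * 0)


class TestTreeRanking:
    def test_perfect_separator_at_depth_one(self):
        X, y = _labeled_data(effect=10.0)
        ranking, depth = rank_by_tree_importance(X, y)
        assert depth == 1
        assert ranking.proteins[0] == "P0"
        assert ranking.scores[0] == pytest.approx(1.0)
        assert all(s == 0.0 for s in ranking.scores[1:])

    def test_xor_structure_needs_depth_two(self):
        """An XOR-type feature pair (with unequal cell sizes, so the greedy
        first split has gain) is solved exactly at depth 2 and both
        features receive nonzero importance."""
        cells = [  # (a, b, label, count)
            (0.0, 0.0, 0, 40), (0.0, 1.0, 1, 60),
            (1.0, 0.0, 1, 20), (1.0, 1.0, 0, 40),
        ]
        a = np.concatenate([[ca] * n for ca, _, _, n in cells])
        b = np.concatenate([[cb] * n for _, cb, _, n in cells])
        lab = np.concatenate([[cl] * n for _, _, cl, n in cells])
        idx = [f"s{i}" for i in range(len(lab))]
        y = pd.Series(lab, index=idx)
        X = pd.DataFrame({"A": a, "B": b}, index=idx)
        ranking, depth = rank_by_tree_importance(X, y)
        assert depth == 2
        assert all(s > 0 for s in ranking.scores)

    def test_unseparable_labels_hit_cap_with_warning(self):
        y = pd.Series([0, 1, 0, 1], index=list("abcd"))
        X = pd.DataFrame({"P0": [1.0, 1.0, 1.0, 1.0]}, index=y.index)
        with pytest.warns(UserWarning, match="did not reach"):
            _, depth = rank_by_tree_importance(X, y, max_depth_cap=3)
        assert depth == 3


class TestPooling:
    def _ranking(self, names):
        return FeatureRanking("pvalue", tuple(names), tuple(range(len(names))))

    def test_identical_rankings_pool_to_k(self):
        r = self._ranking("abcdefg")
        assert pool_top_k([r, r, r], k=5) == set("abcde")

    def test_disjoint_rankings_pool_to_3k(self):
        rs = [self._ranking(names) for names in ("abcde", "fghij", "klmno")]
        assert len(pool_top_k(rs, k=5)) == 15

    def test_short_ranking_rejected(self):
        with pytest.raises(ValueError, match="entries"):
            pool_top_k([self._ranking("abc")], k=5)


class TestScreening:
    def test_perfect_feature_gets_auc_one(self):
        X, y = _labeled_data(effect=10.0)
        table, selected = screen_single_features(X, y, list(X.columns), seed=1)
        assert table.iloc[0].protein_id == "P0"
        assert table.iloc[0].cv_auc_mean == pytest.approx(1.0)
        assert "P0" in selected and len(selected) == 4

    def test_noise_features_near_chance(self):
        """Pure-noise single-feature CV AUCs stay in a band around 0.5."""
        aucs = []
        for seed in range(8):
            X, y = _labeled_data(seed=seed, effect=0.0, n_noise=0)
            table, _ = screen_single_features(X, y, ["P0"], seed=seed, top=1)
            aucs.append(table.cv_auc_mean.iloc[0])
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_missing_pool_protein_rejected(self):
        X, y = _labeled_data()
        with pytest.raises(ValueError, match="not in matrix"):
            screen_single_features(X, y, ["nope"], seed=0)


class TestSubsetSearch:
    def test_subset_count_is_two_to_n_minus_one(self):
        X, y = _labeled_data(n_noise=3)
        results, _ = exhaustive_subset_search(
            X, y, list(X.columns), algorithms=("logistic_regression",), seed=0
        )
        assert len(results) == 15  # 2^4 - 1 subsets for one algorithm

    def test_deterministic_under_seed(self):
        X, y = _labeled_data(n_noise=2)
        r1, _ = exhaustive_subset_search(X, y, list(X.columns),
                                         algorithms=("kNN",), seed=5)
        r2, _ = exhaustive_subset_search(X, y, list(X.columns),
                                         algorithms=("kNN",), seed=5)
        assert [(r.protein_subset, r.cv_auc_mean) for r in r1] == [
            (r.protein_subset, r.cv_auc_mean) for r in r2
        ]

    def test_results_sorted_auc_then_parsimony(self):
        X, y = _labeled_data(n_noise=2)
        results, _ = exhaustive_subset_search(
            X, y, list(X.columns), algorithms=("logistic_regression",), seed=0
        )
        keys = [(-r.cv_auc_mean, len(r.protein_subset)) for r in results]
        assert keys == sorted(keys)

    def test_adding_noise_protein_barely_moves_auc(self):
        """Overfitting guard: appending a pure-noise protein to the best
        subset cannot raise the CV AUC by more than 0.02."""
        X, y = _labeled_data(effect=2.5, n_noise=4)
        results, _ = exhaustive_subset_search(
            X, y, ["P0", "P1"], algorithms=("logistic_regression",), seed=2
        )
        best_single = next(r for r in results if r.protein_subset == ("P0",))
        with_noise = next(r for r in results if r.protein_subset == ("P0", "P1"))
        assert with_noise.cv_auc_mean <= best_single.cv_auc_mean + 0.02

    def test_empty_and_oversized_candidate_sets_rejected(self):
        X, y = _labeled_data(n_noise=12)
        with pytest.raises(ValueError, match="empty"):
            exhaustive_subset_search(X, y, [], seed=0)
        with pytest.raises(ValueError, match="capped"):
            exhaustive_subset_search(X, y, list(X.columns), seed=0)


class TestRocCurve:
    def test_perfect_and_inverted(self):
        y = [0, 0, 1, 1]
        _, auc = roc_curve(y, [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        _, auc = roc_curve(y, [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 1000 + [1] * 1000)
        _, auc = roc_curve(y, rng.normal(size=2000))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 1], [0.1, 0.2])

    def test_auc_equals_mann_whitney_identity(self):
        """Trapezoid AUC equals U/(n1*n2) on tie-free instances."""
        from ckdmrm import mann_whitney

        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, size=2)
            scores = rng.permutation(np.arange(n1 + n2, dtype=float))
            y = np.array([1] * n1 + [0] * n2)
            _, auc = roc_curve(y, scores)
            u, _ = mann_whitney(scores[y == 1], scores[y == 0])
            assert abs(auc - u / (n1 * n2)) < 1e-12


class TestLeakageGuard:
    def test_leaky_selection_scores_higher_on_null_data(self):
        """Selecting the best feature on the full data before CV inflates
        the AUC on pure-noise data relative to fold-safe nested selection."""
        leaky, safe = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            y = pd.Series([0] * 25 + [1] * 25, index=[f"s{i}" for i in range(50)])
            X = pd.DataFrame(
                rng.normal(size=(50, 40)),
                index=y.index, columns=[f"P{j}" for j in range(40)],
            )
            leaky.append(nested_cv_best_feature_auc(X, y, seed=seed, leaky=True))
            safe.append(nested_cv_best_feature_auc(X, y, seed=seed, leaky=False))
        assert np.mean(leaky) > np.mean(safe)
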