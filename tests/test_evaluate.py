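import math

import numpy as np
import pytest
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from gazescreen.evaluate import (
    ProtocolConfig,
    ProtocolResult,
    TrainerConfig,
    classification_metrics,
    compare_results,
    corrected_resampled_ttest,
    rfe_rank,
    run_protocol,
    select_random_features,
    y_randomize_training,
)
from .conftest import gaussian_problem


class TestRfeRank:
    def test_single_feature(self):
        X, y = gaussian_problem(seed=0, n_noise=0, n_informative=1)
        assert rfe_rank(X, y).tolist() == [0]

    def test_noise_eliminated_before_informative(self):
        # 2 strongly separating features + 2 pure-noise features
        X, y = gaussian_problem(seed=1, n_per_class=25, n_informative=2, n_noise=2, shift=3.0)
        ranking = rfe_rank(X, y)
        assert set(ranking[:2]) == {0, 1}
        # independent oracle: at the first step the eliminated feature must
        # carry the smallest squared SVM weight of a directly fitted model
        w2 = np.ravel(SVC(kernel="linear", C=1.0).fit(X, y).coef_) ** 2
        assert ranking[-1] == int(np.argmin(w2)) or w2[ranking[-1]] == w2.min()

    def test_matches_sklearn_rfe_elimination_order(self):
        X, y = gaussian_problem(seed=2, n_per_class=20, n_noise=8, shift=1.5)
        ours = rfe_rank(X, y)
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1).fit(X, y)
        assert ours.tolist() == np.argsort(ref.ranking_).tolist()

    def test_identical_columns_follow_tie_break_order(self):
        # all-equal weights: the larger index is removed first each round
        X = np.tile(np.linspace(-1, 1, 12)[:, None], (1, 5))
        y = np.array(["HR"] * 6 + ["LR"] * 6)
        assert rfe_rank(X, y).tolist() == [0, 1, 2, 3, 4]

    def test_degenerate_labels_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError):
            rfe_rank(X, np.array(["HR"] * 4))


class TestRandomSelection:
    def test_full_set(self):
        assert select_random_features(168, 168, seed=0).tolist() == list(range(168))

    def test_same_seed_same_subset(self):
        a = select_random_features(10, 168, seed=42)
        b = select_random_features(10, 168, seed=42)
        assert np.array_equal(a, b)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_random_features(0, 168, seed=0)
        with pytest.raises(ValueError):
            select_random_features(169, 168, seed=0)

    def test_uniformity_chi_square(self):
        rng = np.random.default_rng(7)
        counts = np.zeros(168)
        draws = 100_000
        for _ in range(draws):
            counts[select_random_features(1, 168, rng)[0]] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestYRandomization:
    def test_half_of_each_class_swaps(self):
        labels = np.array(["HR"] * 10 + ["LR"] * 10)
        permuted = y_randomize_training(labels, seed=3)
        assert (permuted != labels).sum() == 10
        assert (permuted == "HR").sum() == 10  # floor rule preserves equal totals

    def test_floor_rule_with_odd_classes(self):
        labels = np.array(["HR"] * 5 + ["LR"] * 7)
        permuted = y_randomize_training(labels, seed=1)
        assert (permuted[:5] != "HR").sum() == 2
        assert (permuted[5:] != "LR").sum() == 3

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            y_randomize_training(np.array(["HR", "LR", "LR"]), seed=0)


class TestMetrics:
    def test_all_correct(self):
        t = np.array(["HR", "LR", "HR"])
        m = classification_metrics(t, t)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (100.0, 100.0, 100.0)

    def test_hand_confusion_counts(self):
        # TP=3, FN=1, TN=2, FP=2
        truth = np.array(["HR"] * 4 + ["LR"] * 4)
        pred = np.array(["HR", "HR", "HR", "LR", "HR", "HR", "LR", "LR"])
        m = classification_metrics(truth, pred)
        assert m["sensitivity"] == 75.0
        assert m["specificity"] == 50.0
        assert m["accuracy"] == 62.5

    def test_single_class_cohort_reports_missing(self):
        truth = np.array(["HR", "HR"])
        m = classification_metrics(truth, truth)
        assert m["specificity"] is None


class TestCorrectedTtest:
    def test_zero_differences(self):
        assert corrected_resampled_ttest(np.zeros(10), 0.1) == (0.0, 1.0)

    def test_closed_form_example(self):
        d = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        t, p = corrected_resampled_ttest(d, test_fraction=0.1)
        var = 2.5 / 9.0  # sample variance of five 1s and five 2s
        expected = 1.5 / math.sqrt((1 / 10 + (0.1 / 0.9)) * var)
        assert t == pytest.approx(expected)
        assert p == pytest.approx(2 * stats.t.sf(expected, df=9))

    def test_correction_shrinks_t(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 1.0, 30)
        t_corr, _ = corrected_resampled_ttest(d, test_fraction=0.1)
        t_std = d.mean() / math.sqrt(d.var(ddof=1) / len(d))
        assert abs(t_corr) <= abs(t_std)

    def test_zero_variance_nonzero_mean(self):
        t, p = corrected_resampled_ttest(np.full(5, 2.0), 0.1)
        assert math.isinf(t) and t > 0 and p == 0.0


def _protocol(**kw):
    kw.setdefault("folds", 5)
    kw.setdefault("repetitions", 3)
    kw.setdefault("n_features_grid", (2, 5, 20))
    kw.setdefault("seed", 11)
    return ProtocolConfig(**kw)


class TestRunProtocol:
    def test_each_subject_tested_once_per_repetition(self):
        X, y = gaussian_problem(seed=3)
        res = run_protocol(X, y, protocol=_protocol())
        for rep in range(res.protocol.repetitions):
            tested = np.concatenate(
                [fr.test_idx for fr in res.fold_records if fr.repetition == rep]
            )
            assert sorted(tested.tolist()) == list(range(len(y)))

    def test_folds_are_stratified(self):
        X, y = gaussian_problem(seed=4, n_per_class=25)
        res = run_protocol(X, y, protocol=_protocol())
        ratio = (y == "HR").mean()
        for fr in res.fold_records:
            n_hr = (y[fr.test_idx] == "HR").sum()
            assert abs(n_hr - ratio * len(fr.test_idx)) <= 1

    def test_reproducibility(self):
        X, y = gaussian_problem(seed=5)
        a = run_protocol(X, y, protocol=_protocol())
        b = run_protocol(X, y, protocol=_protocol())
        assert a.curve().equals(b.curve())
        for fa, fb in zip(a.fold_records, fb_list := b.fold_records):
            assert np.array_equal(fa.test_idx, fb.test_idx)
            for n in fa.predictions:
                assert np.array_equal(fa.predictions[n], fb.predictions[n])

    def test_rfe_at_full_dimension_equals_plain_svm(self):
        X, y = gaussian_problem(seed=6)
        a = run_protocol(X, y, protocol=_protocol(fs_method="rfe"))
        b = run_protocol(X, y, protocol=_protocol(fs_method="none"))
        n_full = X.shape[1]
        for fa, fb in zip(a.fold_records, b.fold_records):
            assert np.array_equal(fa.predictions[n_full], fb.predictions[n_full])

    def test_null_features_are_chance_level(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 20))
        y = np.array(["HR"] * 60 + ["LR"] * 60)
        res = run_protocol(X, y, protocol=_protocol(fs_method="none", n_features_grid=(20,), repetitions=5))
        acc = res.curve().loc[20, "accuracy_mean"]
        assert 40.0 <= acc <= 60.0

    def test_y_randomized_accuracy_converges_to_chance(self):
        X, y = gaussian_problem(seed=7, n_per_class=50, shift=3.0)
        res = run_protocol(
            X, y,
            protocol=_protocol(fs_method="none", n_features_grid=(20,),
                               repetitions=10, y_randomize=True),
        )
        acc = res.curve().loc[20, "accuracy_mean"]
        sd = res.rep_scores[20]["accuracy"].std(ddof=1)
        assert abs(acc - 50.0) <= max(5.0, 3.0 * sd / math.sqrt(10))

    def test_single_class_cohort_rejected(self):
        X = np.zeros((20, 4))
        y = np.array(["LR"] * 20)
        with pytest.raises(ValueError):
            run_protocol(X, y, protocol=_protocol())

    def test_rfe_beats_or_ties_random_at_small_n(self):
        # many noise features, few informative: paired over seeds
        wins = 0
        for seed in range(3):
            X, y = gaussian_problem(seed=seed, n_per_class=30, n_noise=38, shift=1.5)
            pr = _protocol(n_features_grid=(2,), repetitions=2, seed=seed)
            acc_rfe = run_protocol(X, y, protocol=ProtocolConfig(**{**pr.__dict__, "fs_method": "rfe"})).curve().loc[2, "accuracy_mean"]
            acc_rnd = run_protocol(X, y, protocol=ProtocolConfig(**{**pr.__dict__, "fs_method": "random"})).curve().loc[2, "accuracy_mean"]
            wins += acc_rfe >= acc_rnd
        assert wins == 3

    def test_compare_results_pairs_folds(self):
        X, y = gaussian_problem(seed=8, n_per_class=30, shift=3.0)
        a = run_protocol(X, y, protocol=_protocol(fs_method="rfe", n_features_grid=(2,), repetitions=5))
        b = run_protocol(X, y, protocol=_protocol(fs_method="none", n_features_grid=(2,), y_randomize=True, repetitions=5))
        t, p = compare_results(a, b, n_a=2, n_b=2)
        assert t > 0 and p < 0.05

    def test_result_json_round_trip(self, tmp_path):
        X, y = gaussian_problem(seed=10)
        res = run_protocol(X, y, protocol=_protocol(repetitions=2))
        path = str(tmp_path / "result.json")
        res.to_json(path)
        back = ProtocolResult.from_json(path)
        assert back.curve().equals(res.curve())
        assert back.protocol == res.protocol
        assert back.best_n == res.best_n
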