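"""Fisher selection, LOOCV SVM decoding, hemisphere pairing, summaries."""

import numpy as np
import pytest

import nirsloc as nl
from nirsloc.decoding import Condition, ContrastSpec, fisher_scores, select_top
from nirsloc.features import FeatureDescriptor, FeatureTable


def _table(values, labels):
    values = np.asarray(values, dtype=float)
    desc = [FeatureDescriptor(1, (2, 4), f"f{j}") for j in range(values.shape[1])]
    return FeatureTable(values=values, descriptors=desc, labels=labels)


class TestFisherScores:
    def test_zero_variance_separation_is_inf(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_scores(x, y)[0] == np.inf

    def test_identical_distributions_score_zero(self):
        x = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_scores(x, y)[0] == 0.0

    def test_matches_brute_force_formula(self, rng):
        x = rng.normal(size=(30, 50))
        y = np.array([0] * 15 + [1] * 15)
        scores = fisher_scores(x, y)
        for k in range(50):
            a, b = x[y == 0, k], x[y == 1, k]
            expected = (a.mean() - b.mean()) ** 2 / (a.var(ddof=1) + b.var(ddof=1))
            assert scores[k] == pytest.approx(expected, rel=1e-10)
        # ranking identical to brute-force
        brute = sorted(range(50), key=lambda k: (-scores[k], k))
        np.testing.assert_array_equal(select_top(scores, 50), brute)

    def test_single_class_rejected(self):
        with pytest.raises(nl.ValidationError):
            fisher_scores(np.zeros((4, 2)), np.zeros(4))


class TestSelectTop:
    def test_top_two(self):
        np.testing.assert_array_equal(select_top(np.array([3.0, 1.0, 2.0]), 2), [0, 2])

    def test_tie_break_by_index(self):
        np.testing.assert_array_equal(select_top(np.ones(5), 2), [0, 1])

    def test_matches_sort_oracle(self, rng):
        scores = rng.normal(size=40)
        got = select_top(scores, 7)
        expected = sorted(range(40), key=lambda k: (-scores[k], k))[:7]
        np.testing.assert_array_equal(got, expected)

    def test_invalid_dim_rejected(self):
        with pytest.raises(nl.ValidationError):
            select_top(np.ones(5), 0)


class TestLoocvSvm:
    def _contrast(self):
        return ContrastSpec(Condition(-90, 58), Condition(0, 58), name="-90/0@58")

    def test_high_snr_fixture_decodes_perfectly(self, high_snr_features):
        res = nl.loocv_svm(high_snr_features, self._contrast())
        assert res.best_accuracy >= 0.95
        assert res.n_obs == 20

    def test_accuracy_granularity_multiples_of_one_over_n(self, high_snr_features):
        res = nl.loocv_svm(high_snr_features, self._contrast())
        for acc in res.per_dim_accuracy.values():
            assert (acc * 20) == pytest.approx(round(acc * 20), abs=1e-9)

    def test_fold_training_excludes_held_out_trial(self, high_snr_features):
        """Fold 0 reproduced by hand from the 19 training trials alone."""
        from sklearn.svm import SVC

        ft = high_snr_features
        contrast = self._contrast()
        rows_a, rows_b = contrast.split(ft.labels)
        rows = rows_a + rows_b
        y = np.array([0] * len(rows_a) + [1] * len(rows_b))
        dim = 5
        res = nl.loocv_svm(ft, contrast, dims=[dim])
        X = ft.values[rows]
        train = np.arange(1, len(rows))
        mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
        ok = sd > 0
        Xs = np.where(ok, (X - mu) / np.where(ok, sd, 1.0), 0.0)
        cols = select_top(fisher_scores(Xs[train], y[train]), dim)
        clf = SVC(kernel="linear", C=1.0).fit(Xs[train][:, cols], y[train])
        assert clf.predict(Xs[:1, cols])[0] == res.fold_predictions[0]

    def test_permutation_null_is_unbiased(self):
        """Label-shuffled decoding stays near chance when selection is per fold."""
        rng = np.random.default_rng(7)
        accs = []
        vals = rng.normal(size=(20, 100))
        desc = [FeatureDescriptor(1, (2, 4), f"f{j}") for j in range(100)]
        for _ in range(30):
            labels = [(-90, 58)] * 10 + [(0, 58)] * 10
            perm = rng.permutation(20)
            ft = FeatureTable(values=vals, descriptors=desc,
                              labels=[labels[i] for i in perm])
            res = nl.loocv_svm(ft, self._contrast(), dims=range(1, 11))
            accs.append(np.mean(list(res.per_dim_accuracy.values())))
        assert 0.40 <= np.mean(accs) <= 0.60

    def test_global_selection_inflates_null_accuracy(self):
        """Regression guard: selection outside the folds leaks and overfits."""
        rng = np.random.default_rng(3)
        per_fold, global_ = [], []
        desc = [FeatureDescriptor(1, (2, 4), f"f{j}") for j in range(300)]
        labels = [(-90, 58)] * 10 + [(0, 58)] * 10
        for _ in range(10):
            ft = FeatureTable(values=rng.normal(size=(20, 300)),
                              descriptors=desc, labels=labels)
            per_fold.append(nl.loocv_svm(ft, self._contrast(), dims=[3]).best_accuracy)
            global_.append(
                nl.loocv_svm(ft, self._contrast(), dims=[3], selection="global").best_accuracy
            )
        assert np.mean(global_) > np.mean(per_fold) + 0.1

    def test_empty_class_rejected(self, high_snr_features):
        bad = ContrastSpec(Condition(-90, 58), Condition(None, 33) if False else Condition(0, 48))
        # restrict to trials of one class only
        rows = [i for i, lab in enumerate(high_snr_features.labels) if lab == (-90, 58)]
        sub = high_snr_features.select_trials(rows)
        with pytest.raises(nl.ValidationError):
            nl.loocv_svm(sub, bad)

    def test_best_dim_tie_prefers_smallest(self):
        vals = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
        desc = [FeatureDescriptor(1, (2, 4), f"f{j}") for j in range(3)]
        ft = FeatureTable(values=vals, descriptors=desc,
                          labels=[(-90, 58)] * 5 + [(0, 58)] * 5)
        res = nl.loocv_svm(ft, self._contrast(), dims=[1, 2, 3])
        assert res.best_accuracy == 1.0
        assert res.best_dim == 1


class TestPairHemispheres:
    def _lateral_tensor(self, data, labels):
        return nl.TrialTensor(data=data, labels=labels, fs_hz=13.3,
                              unit_kind="roi", unit_ids=list(range(1, 11)))

    def test_ipsi_takes_stimulated_side(self):
        data = np.zeros((2, 10, 5))
        data[:, :5, :] = 1.0   # left ROIs
        data[:, 5:, :] = 2.0   # right ROIs
        tt = self._lateral_tensor(data, [(-90, 58), (90, 58)])
        ipsi = nl.pair_hemispheres(tt, side="ipsi")
        assert ipsi.n_units == 5
        np.testing.assert_allclose(ipsi.data[0], 1.0)  # -90: left
        np.testing.assert_allclose(ipsi.data[1], 2.0)  # +90: right
        contra = nl.pair_hemispheres(tt, side="contra")
        np.testing.assert_allclose(contra.data[0], 2.0)
        np.testing.assert_allclose(contra.data[1], 1.0)

    def test_non_lateral_trials_rejected(self):
        tt = self._lateral_tensor(np.zeros((1, 10, 5)), [(0, 58)])
        with pytest.raises(nl.ValidationError):
            nl.pair_hemispheres(tt, side="ipsi")

    def test_mirror_symmetric_data_is_undecodable(self, rng):
        """If -90 and +90 evoke mirrored patterns, the paired decoder is at chance."""
        curve = np.sin(np.linspace(0, np.pi, 133))
        data = np.zeros((20, 10, 133))
        labels = []
        for i in range(20):
            loc = -90 if i < 10 else 90
            labels.append((loc, 58))
            contra_rois = range(5, 10) if loc == -90 else range(0, 5)
            for r in contra_rois:
                data[i, r] = curve
            data[i] += rng.normal(0, 0.3, size=(10, 133))
        tt = self._lateral_tensor(data, labels)
        contrast = ContrastSpec(Condition(-90, 58), Condition(90, 58))
        accs = []
        for side in ("ipsi", "contra"):
            paired = nl.pair_hemispheres(tt, side=side)
            ft = nl.extract_features(paired)
            res = nl.loocv_svm(ft, contrast)
            accs.append(np.mean(list(res.per_dim_accuracy.values())))
        assert all(a <= 0.75 for a in accs)


class TestSoundLevel:
    def test_injected_level_effect_localizes_to_roi(self):
        cfg = nl.SimulationConfig(seed=21, effect=nl.intensity_effect(roi_id=4, amplitude=0.3))
        rec, _, _ = nl.simulate_session(cfg)
        tt = nl.preprocess_recording(rec)
        ft = nl.extract_features(tt)
        per_roi = nl.sound_level_decoding(ft, location_deg=0)
        assert set(per_roi) == set(range(1, 11))
        acc4 = per_roi[4].best_accuracy
        assert all(acc4 > r.best_accuracy for roi, r in per_roi.items() if roi != 4)

    def test_single_intensity_class_rejected(self, high_snr_features):
        rows = [i for i, (loc, db) in enumerate(high_snr_features.labels) if db == 58]
        sub = high_snr_features.select_trials(rows)
        with pytest.raises(nl.ValidationError):
            nl.sound_level_decoding(sub, location_deg=0)


class TestSummaries:
    def test_mean_and_threshold_count(self):
        accs = {f"S{i}": a for i, a in enumerate([0.80, 0.70, 0.65, 0.60])}
        mean_pct, n_above, n = nl.summarize_accuracies(accs)
        assert mean_pct == 68.75
        assert n_above == 2  # threshold is inclusive
        assert n == 4

    def test_all_at_threshold_counted(self):
        accs = {f"S{i}": 0.70 for i in range(5)}
        _, n_above, n = nl.summarize_accuracies(accs)
        assert n_above == n == 5

    def test_wilcoxon_identical_vectors_p_one(self):
        stat, p = nl.compare_conditions([0.7, 0.8], [0.7, 0.8],
                                        test="wilcoxon_signed_rank")
        assert p == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.9, 0.01, size=20)
        b = rng.normal(0.5, 0.01, size=20)
        _, p = nl.compare_conditions(a, b, test="anova_oneway")
        assert p < 1e-3

    def test_anova_type_one_error_calibrated(self):
        """Same-distribution groups reject at ~alpha under repeated sampling."""
        rng = np.random.default_rng(1)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            _, p = nl.compare_conditions(a, b, test="anova_oneway")
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07
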