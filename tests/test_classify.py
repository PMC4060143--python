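"""Feature assembly, KCCA dependency, thinning, normalization, SVM."""

import numpy as np
import pytest

from medisig import (
    FeatureSet,
    TimeFrequencyMap,
    build_joint_features,
    downsample_features,
    extract_features,
    kcca_dependency,
    kcca_lag_curve,
    minmax_normalize,
    select_downsampling_factor,
    train_eval_svm,
)

from .oracles import kcca_naive


def _fake_map(amp, freqs, fs=64.0, channel=""):
    amp = np.asarray(amp, dtype=float)
    return TimeFrequencyMap(amp.astype(complex), np.asarray(freqs), fs,
                            channel=channel)


class TestExtractFeatures:
    def test_single_channel_ordering(self):
        amp = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])  # 3 freqs x 2 t
        fs = extract_features([_fake_map(amp, [4.0, 5.0, 6.0])])
        assert fs.X.shape == (2, 3)
        np.testing.assert_array_equal(fs.X[0], [1.0, 3.0, 5.0])

    def test_full_eeg_grid_dimension(self):
        """32 channels x 113 frequencies ([4,32] @ 0.25 Hz) -> 3616 dims."""
        freqs = 4.0 + 0.25 * np.arange(113)
        maps = [_fake_map(np.zeros((113, 4)), freqs, channel=f"ch{i}")
                for i in range(32)]
        fs = extract_features(maps)
        assert fs.n_features == 3616

    def test_tone_frequency_dominates(self):
        freqs = np.array([8.0, 10.0, 12.0])
        amp = np.array([[0.1] * 10, [5.0] * 10, [0.2] * 10])
        fs = extract_features([_fake_map(amp, freqs)])
        assert (np.argmax(fs.X, axis=1) == 1).all()

    def test_grid_mismatch_rejected(self):
        a = _fake_map(np.zeros((2, 5)), [4.0, 5.0])
        b = _fake_map(np.zeros((2, 5)), [4.0, 6.0])
        with pytest.raises(ValueError):
            extract_features([a, b])


class TestKccaDependency:
    def test_identical_variables_near_one(self, rng):
        x = rng.standard_normal((100, 3))
        idx = kcca_dependency(x, x, kappa=0.02, seed=0)
        assert idx.value >= 0.95

    def test_matches_explicit_eigensolver(self, rng):
        x = rng.standard_normal((40, 2))
        y = x + 0.3 * rng.standard_normal((40, 2))
        fast = kcca_dependency(x, y, kappa=0.05, kernel_width=1.5, seed=0)
        slow = kcca_naive(x, y, 0.05, 1.5, 1.5)
        assert fast.value == pytest.approx(slow, abs=1e-6)

    def test_independent_below_dependent_and_kappa_monotone(self, rng):
        dep, indep = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal((200, 2))
            dep.append(kcca_dependency(x, x, kappa=0.02, seed=seed).value)
            y = r.standard_normal((200, 2))
            indep.append(kcca_dependency(x, y, kappa=0.02, seed=seed).value)
        assert np.mean(dep) - np.mean(indep) > 0.3
        # stronger regularization shrinks the independent-case index
        strong = [kcca_dependency(np.random.default_rng(s).standard_normal((200, 2)),
                                  np.random.default_rng(s + 100).standard_normal((200, 2)),
                                  kappa=1.0, seed=s).value for s in range(5)]
        weak = [kcca_dependency(np.random.default_rng(s).standard_normal((200, 2)),
                                np.random.default_rng(s + 100).standard_normal((200, 2)),
                                kappa=0.01, seed=s).value for s in range(5)]
        assert np.mean(strong) < np.mean(weak)

    def test_huge_kappa_drives_index_to_zero(self, rng):
        x = rng.standard_normal((80, 2))
        idx = kcca_dependency(x, x, kappa=1e6, seed=0)
        assert idx.value < 0.05

    def test_constant_input_warns_and_returns_zero(self):
        x = np.ones((50, 2))
        y = np.random.default_rng(0).standard_normal((50, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            idx = kcca_dependency(x, y)
        assert idx.value == 0.0

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError):
            kcca_dependency(rng.standard_normal((30, 2)),
                            rng.standard_normal((31, 2)))

    def test_self_lag_zero_is_maximal(self, rng):
        """I(0) dominates every positive lag for a stationary sequence."""
        n = 300
        x = np.zeros((n, 2))
        r = np.random.default_rng(3)
        for t in range(1, n):
            x[t] = 0.7 * x[t - 1] + r.standard_normal(2)
        fs = FeatureSet(X=x)
        curve = kcca_lag_curve(fs, max_lag=4, max_n=200, seed=0)
        assert curve[0] == max(curve.values())


class TestDownsamplingFactor:
    @staticmethod
    def _ar_features(coef, n=400, d=4, seed=0):
        r = np.random.default_rng(seed)
        x = np.zeros((n, d))
        for t in range(1, n):
            x[t] = coef * x[t - 1] + r.standard_normal(d)
        return FeatureSet(X=x)

    def test_iid_sequence_selects_one(self, rng):
        fs = FeatureSet(X=rng.standard_normal((400, 4)))
        L, curve = select_downsampling_factor(fs, max_lag=6, max_n=350, seed=0)
        assert L == 1
        plateau = [curve[l] for l in range(1, 7)]
        assert max(plateau) < 0.5 < curve[0]

    def test_stronger_autocorrelation_larger_factor(self):
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            slow, _ = select_downsampling_factor(
                self._ar_features(0.9, n=700, seed=seed), max_lag=10,
                max_n=250, seed=seed)
            fast, _ = select_downsampling_factor(
                self._ar_features(0.5, n=700, seed=seed), max_lag=10,
                max_n=250, seed=seed)
            wins += slow >= fast
        assert wins >= round(0.9 * n_seeds)

    def test_retained_subset_size(self):
        fs = FeatureSet(X=np.random.default_rng(0).standard_normal((1000, 2)))
        thin = downsample_features(fs, 7)
        assert thin.n_samples == 142  # floor(1000 / 7)
        assert thin.downsampling_factor == 7

    def test_label_proportions_preserved(self):
        labels = np.array(["a", "b"] * 300)
        fs = FeatureSet(X=np.zeros((600, 1)), labels=labels)
        thin = downsample_features(fs, 3)
        counts = dict(zip(*np.unique(thin.labels, return_counts=True)))
        assert abs(counts["a"] - counts["b"]) <= 1

    def test_no_local_minimum_warns(self):
        # a dependency curve still falling steeply at the horizon has no
        # local minimum within it; the factor falls back to max_lag
        fs = self._ar_features(0.8, n=300, seed=1)
        with pytest.warns(UserWarning, match="no local minimum"):
            L, _ = select_downsampling_factor(fs, max_lag=2, max_n=150, seed=0)
        assert L == 2


class TestMinMaxNormalize:
    def test_printed_formula(self):
        fs = FeatureSet(X=np.array([[2.0], [4.0], [6.0]]))
        out = minmax_normalize(fs)
        np.testing.assert_allclose(out.X.ravel(), [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero_with_warning(self):
        fs = FeatureSet(X=np.full((4, 2), 3.3))
        with pytest.warns(UserWarning, match="zero-range"):
            out = minmax_normalize(fs)
        np.testing.assert_array_equal(out.X, 0.0)

    def test_per_group_uses_own_extremes(self):
        X = np.array([[0.0], [10.0], [100.0], [200.0]])
        groups = np.array(["train", "train", "test", "test"])
        out = minmax_normalize(FeatureSet(X=X), groups, mode="per-group")
        np.testing.assert_allclose(out.X.ravel(), [0.0, 1.0, 0.0, 1.0])

    def test_train_bounds_applied_to_test(self):
        X = np.array([[0.0], [10.0], [5.0], [20.0]])
        groups = np.array(["train", "train", "test", "test"])
        out = minmax_normalize(FeatureSet(X=X), groups, mode="train-bounds")
        np.testing.assert_allclose(out.X.ravel(), [0.0, 1.0, 0.5, 2.0])


class TestSvm:
    @staticmethod
    def _gaussian_classes(n, sep, d=5, seed=0):
        r = np.random.default_rng(seed)
        X = np.vstack([
            r.standard_normal((n // 2, d)),
            r.standard_normal((n // 2, d)) + sep / np.sqrt(d),
        ])
        labels = np.array(["control"] * (n // 2) + ["meditation"] * (n // 2))
        block = np.r_[np.arange(n // 2) % 10, 10 + np.arange(n // 2) % 10]
        return FeatureSet(X=X, labels=labels, block=block.astype(str))

    def test_well_separated_classes_near_perfect(self):
        fs = self._gaussian_classes(200, sep=8.0)
        report = train_eval_svm(fs, folds=5,
                                sigma_factors=np.array([0.5, 1.0, 2.0]),
                                c_grid=np.array([1.0, 10.0]), seed=0)
        assert report.accuracy >= 0.99
        # decision values separate the classes in sign
        med = report.decision_values[fs.labels == "meditation"]
        ctl = report.decision_values[fs.labels == "control"]
        assert med.mean() > ctl.mean()

    def test_shuffled_labels_at_chance(self):
        accs = []
        for seed in range(8):
            fs = self._gaussian_classes(160, sep=8.0, seed=seed)
            rng = np.random.default_rng(seed)
            shuffled = fs.labels.copy()
            # permute block labels jointly so blocks stay label-pure
            blocks = np.unique(fs.block)
            lab_of = {b: rng.choice(["meditation", "control"]) for b in blocks}
            shuffled = np.array([lab_of[b] for b in fs.block])
            if len(set(shuffled)) < 2:
                continue
            fs2 = FeatureSet(X=fs.X, labels=shuffled, block=fs.block)
            try:
                r = train_eval_svm(fs2, folds=4,
                                   sigma_factors=np.array([1.0]),
                                   c_grid=np.array([1.0]), seed=seed)
            except ValueError:
                continue  # a training fold lost a class
            accs.append(r.accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_feature_permutation_invariance(self):
        fs = self._gaussian_classes(120, sep=3.0)
        perm = np.random.default_rng(1).permutation(fs.n_features)
        fs_perm = FeatureSet(X=fs.X[:, perm], labels=fs.labels,
                             block=fs.block)
        a = train_eval_svm(fs, folds=4, sigma_factors=np.array([1.0]),
                           c_grid=np.array([4.0]), seed=0)
        b = train_eval_svm(fs_perm, folds=4, sigma_factors=np.array([1.0]),
                           c_grid=np.array([4.0]), seed=0)
        assert a.accuracy == pytest.approx(b.accuracy)

    def test_single_class_rejected(self):
        fs = FeatureSet(X=np.zeros((40, 2)),
                        labels=np.array(["meditation"] * 40))
        with pytest.raises(ValueError):
            train_eval_svm(fs, folds=4)

    def test_more_folds_than_samples_rejected(self):
        fs = self._gaussian_classes(8, sep=2.0)
        with pytest.raises(ValueError):
            train_eval_svm(fs, folds=20)


class TestJointFeatures:
    def test_dimension_arithmetic(self):
        eeg = FeatureSet(X=np.zeros((10, 3616)))
        resp = FeatureSet(X=np.zeros((10, 256)))
        joint = build_joint_features(eeg, resp)
        assert joint.n_features == 3872

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_joint_features(FeatureSet(X=np.zeros((0, 4))),
                                 FeatureSet(X=np.zeros((10, 4))))

    def test_unalignable_counts_rejected(self):
        with pytest.raises(ValueError, match="unalignable"):
            build_joint_features(FeatureSet(X=np.zeros((100, 4))),
                                 FeatureSet(X=np.zeros((60, 4))))

    def test_label_disagreement_rejected(self):
        a = FeatureSet(X=np.zeros((4, 2)),
                       labels=np.array(["meditation"] * 4))
        b = FeatureSet(X=np.zeros((4, 2)),
                       labels=np.array(["control"] * 4))
        with pytest.raises(ValueError, match="disagree"):
            build_joint_features(a, b)

    def test_uninformative_extra_features_keep_accuracy(self):
        fs = TestSvm._gaussian_classes(160, sep=6.0)
        zeros = FeatureSet(X=np.zeros((160, 10)), labels=fs.labels,
                           block=fs.block)
        with pytest.warns(UserWarning, match="zero-range"):
            joint = build_joint_features(fs, zeros)
            a = train_eval_svm(fs, folds=4, sigma_factors=np.array([1.0]),
                               c_grid=np.array([4.0]), seed=0)
            b = train_eval_svm(joint, folds=4, sigma_factors=np.array([1.0]),
                               c_grid=np.array([4.0]), seed=0)
        assert abs(a.accuracy - b.accuracy) <= 0.05
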