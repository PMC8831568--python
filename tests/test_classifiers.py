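"""Pattern nets, grouped training schemes, aggregation, and SVM baselines."""

import numpy as np
import pytest

from conftest import make_recording
from mearaster.classifiers import (
    FeatureDataset,
    LeakageError,
    PatternNetSpec,
    aggregate_drug_id,
    aggregate_risk,
    compute_timeseries_features,
    make_split,
    multiclass_svm_drug_id,
    one_class_risk_baseline,
    predict_windows,
    run_holdout,
    run_leave_one_well_out,
    train_linear_svm,
    train_pattern_net,
)
from mearaster.features import FEATURE_DIM


def separable_dataset(n_per_class=100, n_wells=6, margin=10.0, seed=0, dim=FEATURE_DIM):
    """Two Gaussian clusters separated by ``margin`` s.d., spread over wells."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n_per_class, dim)).astype(np.float32)
    X[:n_per_class] += margin / np.sqrt(dim)  # separation spread over dimensions
    labels = np.array(["positive"] * n_per_class + ["negative"] * n_per_class, dtype=object)
    wells = np.array(
        [f"P{i % (n_wells // 2)}" for i in range(n_per_class)]
        + [f"N{i % (n_wells // 2)}" for i in range(n_per_class)],
        dtype=object,
    )
    compounds = np.where(labels == "positive", "drugA", "vehicle").astype(object)
    concs = np.where(labels == "positive", 10.0, 0.1)
    is_veh = labels == "negative"
    return FeatureDataset(X, labels, wells, compounds, concs, is_veh)


class TestPatternNet:
    def test_separable_training_accuracy_100(self):
        ds = separable_dataset()
        idx = np.arange(ds.n)
        rng = np.random.default_rng(1)
        rng.shuffle(idx)
        spec = PatternNetSpec(seed=1)
        model = train_pattern_net(ds.X, ds.labels, idx[:150], idx[150:], spec)
        pred = predict_windows(model, ds.X[idx[:150]]).argmax(axis=1)
        truth = np.array([model.classes.index(l) for l in ds.labels[idx[:150]]])
        assert (pred == truth).mean() == 1.0
        # independent cross-check: projecting on the known separation
        # direction splits the classes perfectly at the midpoint
        direction = np.ones(FEATURE_DIM) / np.sqrt(FEATURE_DIM)
        proj = ds.X @ direction
        midpoint = 5.0
        assert ((proj > midpoint) == (ds.labels == "positive")).all()

    def test_same_seed_identical_weights(self):
        ds = separable_dataset()
        idx = np.arange(ds.n)
        spec = PatternNetSpec(seed=7)
        a = train_pattern_net(ds.X, ds.labels, idx[:150], idx[150:], spec)
        b = train_pattern_net(ds.X, ds.labels, idx[:150], idx[150:], spec)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)

    def test_shuffled_labels_chance_validation(self):
        rng = np.random.default_rng(2)
        ds = separable_dataset(n_per_class=200, seed=2)
        labels = ds.labels.copy()
        rng.shuffle(labels)
        idx = rng.permutation(ds.n)
        model = train_pattern_net(ds.X, labels, idx[:300], idx[300:], PatternNetSpec(seed=2))
        va = idx[300:]
        pred = predict_windows(model, ds.X[va]).argmax(axis=1)
        truth = np.array([model.classes.index(l) for l in labels[va]])
        assert abs((pred == truth).mean() - 0.5) <= 0.10

    def test_class_absent_from_training_rejected(self):
        ds = separable_dataset()
        pos = np.flatnonzero(ds.labels == "positive")
        neg = np.flatnonzero(ds.labels == "negative")
        with pytest.raises(ValueError, match="absent"):
            train_pattern_net(ds.X, ds.labels, pos, neg, PatternNetSpec())

    def test_nonfinite_features_rejected(self):
        ds = separable_dataset(n_per_class=10)
        X = ds.X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_pattern_net(X, ds.labels, np.arange(15), np.arange(15, 20), PatternNetSpec())

    def test_probabilities_normalized_and_finite(self):
        ds = separable_dataset(n_per_class=30)
        idx = np.arange(ds.n)
        model = train_pattern_net(ds.X, ds.labels, idx[:40], idx[40:], PatternNetSpec(seed=3))
        probs = predict_windows(model, np.zeros((3, FEATURE_DIM), dtype=np.float32))
        assert np.all(np.isfinite(probs))
        assert probs.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        ds = separable_dataset(n_per_class=20)
        idx = np.arange(ds.n)
        model = train_pattern_net(ds.X, ds.labels, idx[:30], idx[30:], PatternNetSpec(seed=4))
        with pytest.raises(ValueError, match="features"):
            predict_windows(model, np.zeros((2, 100), dtype=np.float32))


class TestAggregation:
    def test_all_windows_certain(self):
        r = aggregate_risk(np.ones(6), ["w1"] * 3 + ["w2"] * 3, [10.0] * 6)
        assert r.per_concentration[10.0] == 1.0
        assert r.call[10.0] is True

    def test_proportion_vs_mean_prob(self):
        probs = np.array([0.2, 0.4, 0.6])
        prop = aggregate_risk(probs, ["w"] * 3, [1.0] * 3, mode="proportion")
        mean = aggregate_risk(probs, ["w"] * 3, [1.0] * 3, mode="mean_prob")
        assert prop.per_well[(1.0, "w")] == pytest.approx(1 / 3)
        assert mean.per_well[(1.0, "w")] == pytest.approx(0.4)

    def test_concentration_mean_over_wells(self):
        probs = np.array([0.4, 0.8])
        r = aggregate_risk(probs, ["a", "b"], [1.0, 1.0], mode="mean_prob")
        assert r.per_concentration[1.0] == pytest.approx(0.6)
        assert r.call[1.0] is True

    def test_window_order_invariance(self):
        rng = np.random.default_rng(3)
        probs = rng.uniform(0, 1, 30)
        wells = rng.choice(["a", "b", "c"], 30)
        concs = rng.choice([1.0, 3.0], 30)
        perm = rng.permutation(30)
        a = aggregate_risk(probs, wells, concs)
        b = aggregate_risk(probs[perm], wells[perm], concs[perm])
        assert a.per_concentration == b.per_concentration

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_risk(np.array([]), [], [])


class TestHoldout:
    def test_separable_test_wells_classified(self):
        ds = separable_dataset(margin=20.0)
        model, probs, test_idx = run_holdout(ds, PatternNetSpec(seed=5), ["P2", "N2"])
        pred = probs.argmax(axis=1)
        truth = np.array([model.classes.index(l) for l in ds.labels[test_idx]])
        assert (pred == truth).mean() == 1.0

    def test_train_fraction_one_rejected(self):
        ds = separable_dataset()
        with pytest.raises(ValueError, match="train_fraction"):
            run_holdout(ds, PatternNetSpec(), ["P2"], train_fraction=1.0)

    def test_injected_leakage_hard_failure(self):
        ds = separable_dataset()
        with pytest.raises(LeakageError):
            run_holdout(ds, PatternNetSpec(), ["P0"], train_wells=["P0", "N0"])

    def test_split_fractions_honored(self):
        ds = separable_dataset()
        split = make_split(ds, ["P2", "N2"], train_fraction=0.75, seed=0)
        pool = split.train_idx.size + split.val_idx.size
        assert abs(split.train_idx.size - 0.75 * pool) <= 1
        test_wells = set(ds.wells[np.isin(ds.wells, list(split.test_wells))])
        used = set(ds.wells[split.train_idx]) | set(ds.wells[split.val_idx])
        assert not (used & test_wells)


class TestLeaveOneWellOut:
    def test_model_count_w_times_r(self):
        ds = separable_dataset(n_per_class=30, n_wells=6)
        res = run_leave_one_well_out(ds, PatternNetSpec(seed=6), replicates=2)
        assert res.n_models == 6 * 2

    def test_held_out_distribution_is_replicate_mean(self):
        ds = separable_dataset(n_per_class=30, n_wells=4)
        res = run_leave_one_well_out(ds, PatternNetSpec(seed=7), replicates=3)
        for w, probs in res.well_probs.items():
            assert probs == pytest.approx(np.mean(res.per_model_probs[w], axis=0))
            assert probs.sum(axis=1) == pytest.approx(np.ones(len(probs)), abs=1e-9)

    def test_replicates_below_one_rejected(self):
        with pytest.raises(ValueError):
            run_leave_one_well_out(separable_dataset(n_per_class=10), PatternNetSpec(), replicates=0)

    def test_aggregate_drug_id_argmax(self):
        ds = separable_dataset(n_per_class=30, n_wells=4)
        res = run_leave_one_well_out(ds, PatternNetSpec(seed=8), replicates=1)
        table = aggregate_drug_id(res, ds)
        for (compound, _), (pred, dist) in table.items():
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)
            assert pred == res.classes[int(np.argmax(dist))]


class TestLinearSvm:
    def test_separable_holdout_accuracy(self):
        ds = separable_dataset()
        model, scores, test_idx = train_linear_svm(ds, ["P2", "N2"], "positive")
        pred = scores > 0
        truth = ds.labels[test_idx] == "positive"
        assert (pred == truth).mean() == 1.0

    def test_weight_direction_matches_analytic_sign(self):
        # all information in dimension 0: the max-margin direction is +e0
        ds = separable_dataset(n_per_class=20)
        rng = np.random.default_rng(26)
        X = np.zeros_like(ds.X)
        X[:, 0] = np.where(ds.labels == "positive", 5.0, -5.0) + rng.normal(0, 0.3, ds.n)
        ds = FeatureDataset(X, ds.labels, ds.wells, ds.compounds, ds.concentrations, ds.is_vehicle)
        model, _, _ = train_linear_svm(ds, ["P2", "N2"], "positive")
        w = model.coef_.ravel()
        assert w[0] > 0
        assert np.abs(w[1:]).max() < 1e-6

    def test_deterministic_scores(self):
        ds = separable_dataset()
        _, a, _ = train_linear_svm(ds, ["P2"], "positive", seed=0)
        _, b, _ = train_linear_svm(ds, ["P2"], "positive", seed=0)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        ds = separable_dataset()
        only_pos = ds.subset(np.flatnonzero(ds.labels == "positive"))
        with pytest.raises(ValueError, match="single-class"):
            train_linear_svm(only_pos, ["P2"], "positive")


class TestTimeseriesFeatures:
    def test_empty_well(self):
        v = compute_timeseries_features(make_recording())
        assert v.shape == (34,)
        assert v[0] == 0.0  # pooled rate
        assert v[1] == 600.0  # pooled ISI missing-coded as duration

    def test_regular_1hz_arithmetic(self):
        spikes = {e: np.arange(0.5 + e * 0.001, 600, 1.0) for e in range(16)}
        rec = make_recording(spikes)
        v = compute_timeseries_features(rec)
        assert v[0] == pytest.approx(16.0, rel=0.01)  # pooled rate
        for e in range(16):
            assert v[2 + 2 * e] == pytest.approx(1.0, rel=0.01)  # per-electrode rate
            assert v[3 + 2 * e] == pytest.approx(1.0, rel=0.01)  # per-electrode ISI


class TestOneClassBaseline:
    def test_centroid_is_inlier_and_far_point_outlier(self):
        rng = np.random.default_rng(23)
        train = rng.normal(0, 1, (200, 34))
        centroid = train.mean(axis=0, keepdims=True)
        far = centroid + 10.0
        scores, flags = one_class_risk_baseline(train, np.r_[centroid, far])
        assert not flags[0]  # centroid: inlier
        assert flags[1]  # 10 s.d. away: outlier = at-risk
        assert scores[0] > scores[1]

    def test_deterministic(self):
        rng = np.random.default_rng(24)
        train = rng.normal(0, 1, (50, 5))
        test = rng.normal(0, 1, (10, 5))
        a, _ = one_class_risk_baseline(train, test)
        b, _ = one_class_risk_baseline(train, test)
        assert np.array_equal(a, b)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            one_class_risk_baseline(np.empty((0, 5)), np.zeros((1, 5)))


class TestMulticlassSvm:
    @staticmethod
    def three_class_data():
        rng = np.random.default_rng(25)
        X, labels, wells = [], [], []
        for ci, c in enumerate("ABC"):
            for w in range(3):
                for _ in range(10):
                    x = rng.normal(0, 0.5, 8)
                    x[ci] += 10.0
                    X.append(x)
                    labels.append(c)
                    wells.append(f"{c}{w}")
        X = np.array(X)
        labels = np.array(labels, dtype=object)
        wells = np.array(wells, dtype=object)
        return X, labels, wells

    def test_full_heldout_recovery(self):
        X, labels, wells = self.three_class_data()
        table, n_models = multiclass_svm_drug_id(X, labels, wells, labels, np.ones(len(X)))
        assert n_models == 9  # W x 1, no replicates
        for (compound, _), (pred, _) in table.items():
            assert pred == compound

    def test_tie_breaks_by_class_order(self):
        dist = np.array([0.4, 0.4, 0.2])
        assert int(np.argmax(dist)) == 0  # first maximal index convention
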