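import numpy as np
import pytest
from scipy import stats

from landmarkov import (
    DriverSpec,
    SampleSet,
    SyntheticScenario,
    TrainingSettings,
    backwards_stepwise,
    draw_samples,
    evolve,
    generate_t1,
    predict_potentials,
    train_submodel,
)
from landmarkov.mlp import submodel_from_json, submodel_to_json

from conftest import make_cat, make_cont

FAST = TrainingSettings(max_epochs=400, patience=50, learning_rate=0.1)


def make_sampleset(features, labels, seed=0, origin=1):
    """Hand-built SampleSet with per-label half/half split."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    split = np.empty(len(labels), dtype=object)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        half = (len(idx) + 1) // 2
        split[idx[:half]] = "train"
        split[idx[half:]] = "validate"
    names = [f"v{i}" for i in range(features.shape[1])]
    return SampleSet(features, labels, split, names, origin, seed)


def separable_set(n=2000, n_noise=0, seed=0, flip=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, size=(n, 1 + n_noise))
    labels = np.where(x[:, 0] > 0, 2, 1)
    if flip:
        swap = rng.random(n) < flip
        labels[swap] = 3 - labels[swap]
    return make_sampleset(x, labels, seed=seed)


class TestDrawSamples:
    def _landscape(self, seed=0):
        spec = SyntheticScenario(
            seed=seed, shape=(80, 80), shares=(0.5, 0.3, 0.2), autocorr_length=3.0,
            P_true=np.array([[0.6, 0.25, 0.15], [0.1, 0.85, 0.05], [0.1, 0.1, 0.8]]),
            drivers=[DriverSpec("a", "smoothed-noise"), DriverSpec("b", "smooth-gradient")],
        )
        t1, drivers = generate_t1(spec)
        t2 = evolve(t1, spec, drivers)
        return t1, t2, drivers

    def test_equal_stratification_and_half_split(self):
        t1, t2, drivers = self._landscape()
        s = draw_samples(t1, t2, origin=1, variables=drivers, n=600, seed=1)
        labels = np.unique(s.labels)
        per_label = 600 // len(labels)
        for lab in labels:
            n_lab = int((s.labels == lab).sum())
            assert n_lab <= per_label
            n_train = int(((s.labels == lab) & s.train_mask).sum())
            n_val = n_lab - n_train
            assert abs(n_train - n_val) <= 1

    def test_scarce_label_fully_taken_others_unchanged(self, legend3):
        # counting oracle on a constructed map: label 3 has exactly 20 pixels
        t1 = make_cat(np.ones((30, 30), dtype=int), legend=legend3)
        t2_vals = np.ones((30, 30), dtype=int)
        t2_vals[0, :20] = 3          # 20 pixels 1 -> 3
        t2_vals[5:15, :] = 2         # 300 pixels 1 -> 2
        t2 = make_cat(t2_vals, legend=legend3)
        drivers = {"x": make_cont(np.random.default_rng(0).random((30, 30)))}
        s = draw_samples(t1, t2, origin=1, variables=drivers, n=300, seed=0)
        assert int((s.labels == 3).sum()) == 20      # all 20 taken
        assert int((s.labels == 2).sum()) == 100     # 300 // 3 labels
        assert int((s.labels == 1).sum()) == 100

    def test_same_seed_bit_identical(self):
        t1, t2, drivers = self._landscape(seed=2)
        a = draw_samples(t1, t2, 1, drivers, n=500, seed=42)
        b = draw_samples(t1, t2, 1, drivers, n=500, seed=42)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.split, b.split)
        c = draw_samples(t1, t2, 1, drivers, n=500, seed=43)
        assert not np.array_equal(a.pixel_index, c.pixel_index)

    def test_absent_origin_rejected(self, legend3):
        t1 = make_cat(np.ones((5, 5), dtype=int), legend=legend3)
        with pytest.raises(ValueError, match="absent"):
            draw_samples(t1, t1, origin=3, variables={"x": make_cont(np.zeros((5, 5)))},
                         n=10, seed=0)

    def test_single_label_rejected(self, legend3):
        t1 = make_cat(np.ones((5, 5), dtype=int), legend=legend3)
        with pytest.raises(ValueError, match="2 labels"):
            draw_samples(t1, t1, origin=1, variables={"x": make_cont(np.zeros((5, 5)))},
                         n=10, seed=0)


class TestTrainSubmodel:
    def test_linearly_separable_accuracy_at_least_95(self):
        model = train_submodel(separable_set(), FAST)
        assert model.accuracy >= 95.0
        assert model.good

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.uniform(size=(n, 2))
        labels = np.repeat([1, 2], n // 2)
        rng.shuffle(labels)
        model = train_submodel(make_sampleset(x, labels), FAST)
        assert model.accuracy == pytest.approx(50.0, abs=5.0)
        assert not model.good

    def test_good_flag_threshold(self):
        model = train_submodel(separable_set(), FAST)
        assert model.good == (model.accuracy >= 75.0)

    def test_deterministic_accuracy(self):
        a = train_submodel(separable_set(seed=3), FAST)
        b = train_submodel(separable_set(seed=3), FAST)
        assert a.accuracy == b.accuracy
        assert all(np.array_equal(w1, w2) for w1, w2 in
                   zip(a.classifier.coefs_, b.classifier.coefs_))

    def test_single_label_rejected(self):
        s = make_sampleset(np.random.default_rng(0).random((20, 1)), np.ones(20, int))
        with pytest.raises(ValueError, match="single label"):
            train_submodel(s, FAST)

    def test_train_accuracy_dominates_validation_on_average(self):
        # an over-parameterized net memorizes pure-noise labels on the
        # training half, so the train/validate gap is positive on average
        gaps = []
        memorize = TrainingSettings(hidden_nodes=24, learning_rate=0.1,
                                    max_epochs=2000, patience=2000)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=(200, 5))
            labels = np.tile([1, 2], 100)
            rng.shuffle(labels)
            model = train_submodel(make_sampleset(x, labels, seed=seed), memorize)
            gaps.append(model.train_accuracy - model.accuracy)
        assert np.mean(gaps) > 0.0

    def test_json_roundtrip_preserves_predictions(self):
        model = train_submodel(separable_set(seed=5), FAST)
        clone = submodel_from_json(submodel_to_json(model))
        x = np.random.default_rng(1).uniform(-1, 1, size=(50, 1))
        assert np.allclose(model.predict_proba(x), clone.predict_proba(x))
        assert clone.accuracy == model.accuracy


class TestBackwardsStepwise:
    def test_noise_variables_dropped_informative_kept(self):
        rng = np.random.default_rng(0)
        n = 1200
        x = rng.uniform(-1, 1, size=(n, 4))
        labels = np.where(x[:, 0] > 0, 2, 1)
        s = make_sampleset(x, labels)
        selected, trace = backwards_stepwise(s, tolerance=1.0, settings=FAST)
        assert "v0" in selected
        assert set(selected) <= {"v0"} or len(selected) < 4
        assert trace[0]["dropped"] is None
        assert all(t["dropped"] for t in trace[1:])

    def test_single_variable_returned_unchanged(self):
        s = separable_set(n=400)
        selected, trace = backwards_stepwise(s, variables=["v0"], settings=FAST)
        assert selected == ["v0"]

    def test_collinear_duplicate_dropped_at_zero_tolerance(self):
        rng = np.random.default_rng(2)
        x0 = rng.uniform(0.2, 1, size=(800, 1)) * rng.choice([-1, 1], size=(800, 1))
        x = np.hstack([x0, x0.copy()])  # perfectly collinear pair, wide margin
        labels = np.where(x0[:, 0] > 0, 2, 1)
        s = make_sampleset(x, labels)
        selected, _ = backwards_stepwise(s, tolerance=0.0, settings=FAST)
        assert len(selected) == 1


class TestPredictPotentials:
    def _overfit_fixture(self):
        legend_vals = np.ones((6, 6), dtype=int)
        legend_vals[3:, :] = 2
        t1 = make_cat(np.ones((6, 6), dtype=int))
        driver = np.zeros((6, 6))
        driver[3:, :] = 1.0
        t2 = make_cat(legend_vals)
        drivers = {"d": make_cont(driver)}
        s = draw_samples(t1, t2, origin=1, variables=drivers, n=36, seed=0)
        model = train_submodel(s, TrainingSettings(max_epochs=3000, patience=500,
                                                   learning_rate=0.1))
        return t1, drivers, model

    def test_saturated_model_recovers_labels(self):
        t1, drivers, model = self._overfit_fixture()
        stack = predict_potentials(model, drivers, t1)
        pot_change = stack[(1, 2)].values
        assert pot_change[5, 0] > 0.9      # driver=1 region transitioned
        assert pot_change[0, 0] < 0.1      # driver=0 region persisted

    def test_non_origin_pixels_zero(self):
        t1, drivers, model = self._overfit_fixture()
        mixed = t1.copy()
        mixed.values[0, 0] = 2
        stack = predict_potentials(model, drivers, mixed)
        assert stack[(1, 2)].values[0, 0] == 0.0

    def test_potential_monotone_in_single_covariate(self):
        spec = SyntheticScenario(
            seed=11, shape=(120, 120), shares=(0.6, 0.4), autocorr_length=3.0,
            P_true=np.array([[0.7, 0.3], [0.05, 0.95]]),
            drivers=[DriverSpec("z", "smoothed-noise", beta=2.0)],
        )
        t1, drivers = generate_t1(spec)
        t2 = evolve(t1, spec, drivers)
        s = draw_samples(t1, t2, origin=1, variables=drivers, n=4000, seed=3)
        model = train_submodel(s, FAST)
        stack = predict_potentials(model, drivers, t1)
        origin = (t1.values == 1)
        rho = stats.spearmanr(drivers["z"].values[origin],
                              stack[(1, 2)].values[origin]).statistic
        assert rho >= 0.9

    def test_nodata_propagates(self):
        t1, drivers, model = self._overfit_fixture()
        masked = t1.copy()
        masked.values[0, 0] = masked.nodata
        stack = predict_potentials(model, drivers, masked)
        assert stack[(1, 2)].mask[0, 0]
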