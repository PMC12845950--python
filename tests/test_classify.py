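"""Sample extraction, stratified split, random forest, experiments."""

import numpy as np
import pytest
from shapely.geometry import box

from cropsar.classify import (
    CropClassifier,
    extract_samples,
    normalized_importance,
    predict_map,
    stratified_split,
    temporal_experiment,
    train_random_forest,
)
from cropsar.cube import BandMeta, FeatureCube
from cropsar.samples import FieldPolygon, LabeledSamples, SamplePolygons


def toy_cube(values, features=None, date="20240228"):
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    features = features or [f"f{i}" for i in range(n)]
    meta = [BandMeta(sensor="SAR", date=date, feature=f) for f in features]
    return FeatureCube(values, meta)


def polys(grid, *specs):
    return SamplePolygons(
        polygons=[FieldPolygon(code, box(*b)) for code, b in specs],
        grid_shape=grid,
    )


def separable_samples(n_per_class=40, seed=0, n_classes=2):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for c in range(n_classes):
        xs.append(rng.normal(loc=10.0 * c, scale=0.1, size=(n_per_class, 3)))
        ys.append(np.full(n_per_class, c + 1))
    x = np.vstack(xs)
    y = np.concatenate(ys).astype(np.int16)
    return LabeledSamples(pixel_ids=np.arange(len(y)), x=x, y=y)


class TestExtractSamples:
    def test_area_count(self):
        cube = toy_cube(np.zeros((20, 20, 2)))
        s = extract_samples(cube, polys((20, 20), (1, (0, 0, 10, 10)), (2, (12, 12, 16, 16))))
        assert len(s) == 100 + 16
        assert s.class_counts() == {1: 100, 2: 16}

    def test_overlap_different_classes_rejected(self):
        cube = toy_cube(np.zeros((20, 20, 2)))
        with pytest.raises(ValueError, match="overlap"):
            extract_samples(
                cube, polys((20, 20), (1, (0, 0, 10, 10)), (2, (5, 5, 12, 12)))
            )

    def test_empty_intersection_rejected(self):
        cube = toy_cube(np.zeros((20, 20, 2)))
        with pytest.raises(ValueError, match="no pixel"):
            extract_samples(cube, polys((20, 20)))

    def test_features_taken_from_cube(self, rng):
        values = rng.uniform(size=(10, 10, 3))
        cube = toy_cube(values)
        s = extract_samples(cube, polys((10, 10), (1, (2, 3, 5, 6))))
        rr, cc = np.divmod(s.pixel_ids, 10)
        np.testing.assert_array_equal(s.x, values[rr, cc])


class TestStratifiedSplit:
    @pytest.mark.parametrize("n, n_train", [(10, 7), (403, 282), (4, 3)])
    def test_round_half_up(self, n, n_train):
        s = LabeledSamples(
            pixel_ids=np.arange(n),
            x=np.zeros((n, 1)),
            y=np.ones(n, dtype=np.int16),
        )
        out = stratified_split(s, 0.7, seed=0)
        assert int(out.train_mask.sum()) == n_train
        assert int(out.test_mask.sum()) == n - n_train

    def test_per_class_conservation(self):
        s = separable_samples(n_per_class=33, n_classes=4)
        out = stratified_split(s, 0.7, seed=1)
        for c in np.unique(s.y):
            n_tr = int((out.train_mask & (out.y == c)).sum())
            n_te = int((out.test_mask & (out.y == c)).sum())
            assert n_tr + n_te == 33
            assert abs(n_tr - 0.7 * 33) <= 1

    def test_deterministic(self):
        s = separable_samples()
        a = stratified_split(s, 0.7, seed=9)
        b = stratified_split(s, 0.7, seed=9)
        np.testing.assert_array_equal(a.split, b.split)

    def test_tiny_class_rejected(self):
        s = LabeledSamples(
            pixel_ids=np.arange(3),
            x=np.zeros((3, 1)),
            y=np.array([1, 1, 2], dtype=np.int16),
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(s, 0.7, seed=0)


class TestRandomForest:
    def test_separable_classes_perfect_accuracy(self):
        s = stratified_split(separable_samples(), 0.7, seed=0)
        model = train_random_forest(s, n_trees=150, seed=0)
        pred = model.predict(s.x[s.test_mask])
        assert (pred == s.y[s.test_mask]).all()

    def test_deterministic_predictions(self, rng):
        s = stratified_split(separable_samples(), 0.7, seed=0)
        grid = rng.normal(size=(50, 3))
        a = train_random_forest(s, seed=4).predict(grid)
        b = train_random_forest(s, seed=4).predict(grid)
        np.testing.assert_array_equal(a, b)

    def test_label_permutation_null(self):
        """Permuted labels on balanced 2-class data give chance accuracy."""
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            s = separable_samples(n_per_class=150, seed=seed)
            y_perm = rng.permutation(s.y)
            s = LabeledSamples(pixel_ids=s.pixel_ids, x=s.x, y=y_perm)
            s = stratified_split(s, 0.7, seed=seed)
            model = train_random_forest(s, n_trees=50, seed=seed)
            pred = model.predict(s.x[s.test_mask])
            accs.append((pred == s.y[s.test_mask]).mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        s = LabeledSamples(
            pixel_ids=np.arange(10),
            x=np.zeros((10, 1)),
            y=np.ones(10, dtype=np.int16),
        )
        s = stratified_split(s, 0.7, seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            train_random_forest(s)


class TestPredictMap:
    def test_band_order_invariance(self, rng):
        values = rng.normal(size=(12, 12, 4))
        cube = toy_cube(values)
        s = extract_samples(cube, polys((12, 12), (1, (0, 0, 6, 6)), (2, (6, 6, 12, 12))))
        s = stratified_split(s, 0.7, seed=0)
        model = train_random_forest(s, n_trees=30, seed=0)
        base = predict_map(model, cube, cube.band_names)
        perm = [2, 0, 3, 1]
        permuted = FeatureCube(
            cube.values[:, :, perm], [cube.meta[i] for i in perm]
        )
        np.testing.assert_array_equal(
            predict_map(model, permuted, cube.band_names), base
        )

    def test_band_mismatch_lists_names(self, rng):
        cube = toy_cube(rng.normal(size=(12, 12, 4)))
        s = stratified_split(separable_samples(), 0.7, seed=0)
        model = train_random_forest(s, n_trees=10, seed=0)
        with pytest.raises(ValueError, match="missing"):
            predict_map(model, cube, ["20240228_zzz"])


class TestImportance:
    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 300
        x = rng.normal(size=(n, 4))
        y = (x[:, 2] > 0).astype(np.int16) + 1
        s = LabeledSamples(pixel_ids=np.arange(n), x=x, y=y)
        s = stratified_split(s, 0.7, seed=0)
        model = train_random_forest(s, n_trees=100, seed=0)
        names = [f"2024022{i}_f{i}" for i in range(4)]
        table = normalized_importance(model, names)
        assert table.index[0] == "f2"
        assert table["normalized_importance"].iloc[0] == 1.0
        assert table["normalized_importance"].max() == 1.0

    def test_importance_summed_across_dates(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=(n, 4))
        y = ((x[:, 0] + x[:, 2]) > 0).astype(np.int16) + 1
        s = stratified_split(
            LabeledSamples(pixel_ids=np.arange(n), x=x, y=y), 0.7, seed=0
        )
        model = train_random_forest(s, n_trees=50, seed=0)
        # same feature name on two dates -> one aggregated row
        names = ["20240228_mv", "20240228_H", "20240311_mv", "20240311_H"]
        table = normalized_importance(model, names)
        assert sorted(table.index) == ["H", "mv"]
        raw_mv = table.loc["mv", "raw_importance"]
        assert raw_mv == pytest.approx(
            model.feature_importances_[0] + model.feature_importances_[2]
        )


class TestModelResults:
    def test_fit_returns_evaluated_result(self, rng):
        values = rng.normal(size=(20, 20, 3))
        values[:10] += 8.0  # classes separable by location
        cube = toy_cube(values)
        result = CropClassifier(
            cube,
            polygons=polys((20, 20), (1, (0, 0, 20, 10)), (2, (0, 10, 20, 20))),
            n_trees=30,
        ).fit(seed=0)
        assert result.oa == pytest.approx(100.0)
        assert result.kappa == pytest.approx(1.0)
        assert "OA" in result.summary()
        pred = result.predict_map(cube)
        assert pred.shape == (20, 20)

    def test_end_to_end_determinism(self, rng):
        values = rng.normal(size=(16, 16, 3))
        cube = toy_cube(values)
        p = polys((16, 16), (1, (0, 0, 16, 8)), (2, (0, 8, 16, 16)))
        a = CropClassifier(cube, polygons=p, n_trees=40).fit(seed=5)
        b = CropClassifier(cube, polygons=p, n_trees=40).fit(seed=5)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)
        assert a.oa == b.oa


class TestTemporalExperiment:
    def test_table_shape_and_prefix_growth(self, rng):
        dates = ["20240228", "20240311", "20240323"]
        cubes = [
            toy_cube(rng.normal(size=(16, 16, 2)), ["VV_dB", "VH_dB"], d)
            for d in dates
        ]
        from cropsar.cube import stack_temporal

        cube = stack_temporal(cubes)
        p = polys((16, 16), (1, (0, 0, 16, 8)), (2, (0, 8, 16, 16)))
        table = temporal_experiment(cube, p, seed=0, n_trees=20)
        assert len(table) == 3
        assert list(table["n_bands"]) == [2, 4, 6]
        assert {"OA", "Kappa"} <= set(table.columns)
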