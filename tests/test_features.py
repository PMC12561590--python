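import numpy as np
import pytest

from gaitrep import features as ft
from gaitrep.gaitmaps import GaitMap


def _color_map(rng, shape=(20, 12)):
    return GaitMap(kind="cGEI", pixels=rng.random((*shape, 3)), n_frames=5)


class TestColorPermutations:
    def test_six_distinct_orderings_for_color_map(self, rng):
        imgs = ft.color_permutations(_color_map(rng))
        assert len(imgs) == 6
        keys = [tuple(img[0, 0]) for img in imgs]
        assert len(set(keys)) == 6

    def test_fixed_block_order_second_is_rbg(self, rng):
        m = _color_map(rng)
        imgs = ft.color_permutations(m)
        a, b, c = m.pixels[..., 0], m.pixels[..., 1], m.pixels[..., 2]
        assert np.array_equal(imgs[1][..., 0], a)
        assert np.array_equal(imgs[1][..., 1], c)
        assert np.array_equal(imgs[1][..., 2], b)

    def test_grayscale_replicates_to_identical_images(self, rng):
        m = GaitMap(kind="GEI", pixels=rng.random((10, 8)), n_frames=3)
        imgs = ft.color_permutations(m)
        for img in imgs[1:]:
            assert np.array_equal(img, imgs[0])


class TestExtractFeatures:
    def test_builtin_extractor_dimensions(self, rng):
        ex = ft.PooledGridExtractor()
        fv = ft.features_from_map(_color_map(rng), ex)
        assert ex.dim == 3 * (16 * 16 + 16)
        assert fv.total_dim == 6 * ex.dim
        assert fv.per_perm_dim == ex.dim

    def test_reference_dim_4096_gives_24576(self, rng):
        ex = ft.FunctionExtractor(lambda img: np.full(4096, img.mean()), dim=4096)
        fv = ft.features_from_map(_color_map(rng), ex)
        assert fv.total_dim == 24_576

    def test_small_extractor_gives_192(self, rng):
        ex = ft.FunctionExtractor(lambda img: img.ravel()[:32], dim=32)
        fv = ft.features_from_map(_color_map(rng), ex)
        assert fv.total_dim == 192

    def test_grayscale_map_duplicates_blocks(self, rng):
        m = GaitMap(kind="tGBI", pixels=rng.random((15, 9)), n_frames=4)
        ex = ft.PooledGridExtractor()
        fv = ft.features_from_map(m, ex)
        blocks = fv.values.reshape(6, ex.dim)
        for b in blocks[1:]:
            assert np.array_equal(b, blocks[0])

    def test_extractor_failure_names_permutation(self, rng):
        ex = ft.FunctionExtractor(lambda img: np.zeros(3), dim=5)
        with pytest.raises(RuntimeError, match="permutation 0"):
            ft.features_from_map(_color_map(rng), ex)

    def test_extractor_deterministic(self, rng):
        m = _color_map(rng)
        ex = ft.PooledGridExtractor()
        a = ft.features_from_map(m, ex).values
        b = ft.features_from_map(m, ex).values
        assert np.array_equal(a, b)


class TestFitReducer:
    def test_reduced_dimension_six_classes_p15(self, rng):
        X = rng.normal(size=(6 * 20, 40))
        labels = np.repeat([f"c{i}" for i in range(6)], 20)
        model = ft.fit_reducer(X, labels, P=15)
        assert model.reduced_dim == 90
        v = ft.reduce_features(X[0], model)
        assert v.shape == (90,)

    def test_components_match_covariance_eigendecomposition(self, rng):
        """Per-class PCA directions equal covariance eigenvectors up to sign."""
        X = rng.normal(size=(20, 50))
        model = ft.fit_reducer(X, ["a"] * 20, P=5)
        cov = np.cov(X, rowvar=False, bias=False)
        w, v = np.linalg.eigh(cov)
        top = v[:, np.argsort(w)[::-1][:5]].T
        for comp, ev in zip(model.components["a"], top):
            assert abs(float(comp @ ev)) == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_class_has_unit_explained_variance(self, rng):
        base = rng.normal(size=30)
        X = np.outer(rng.normal(size=8), base)
        model = ft.fit_reducer(X, ["a"] * 8, P=1)
        assert model.explained_variance_fraction["a"] == pytest.approx(1.0)

    def test_p_clamped_with_warning(self, rng):
        X = rng.normal(size=(4, 10))
        with pytest.warns(UserWarning, match="clamped"):
            model = ft.fit_reducer(X, ["a"] * 4, P=15)
        assert model.components["a"].shape[0] == 3

    def test_class_with_one_sample_errors(self, rng):
        X = rng.normal(size=(3, 5))
        with pytest.raises(ValueError, match="'b'"):
            ft.fit_reducer(X, ["a", "a", "b"], P=2)

    def test_components_orthonormal(self, rng):
        X = rng.normal(size=(25, 30))
        model = ft.fit_reducer(X, ["a"] * 25, P=6)
        C = model.components["a"]
        assert np.allclose(C @ C.T, np.eye(6), atol=1e-10)

    def test_sample_order_invariance_up_to_sign(self, rng):
        X = rng.normal(size=(15, 12))
        m1 = ft.fit_reducer(X, ["a"] * 15, P=4)
        perm = rng.permutation(15)
        m2 = ft.fit_reducer(X[perm], ["a"] * 15, P=4)
        dots = np.abs(np.sum(m1.components["a"] * m2.components["a"], axis=1))
        assert np.allclose(dots, 1.0, atol=1e-8)


class TestReduce:
    def test_class_mean_projects_to_zero_block(self, rng):
        X = rng.normal(size=(12, 20))
        labels = ["a"] * 6 + ["b"] * 6
        model = ft.fit_reducer(X, labels, P=3)
        mu_a = X[:6].mean(axis=0)
        r = ft.reduce_features(mu_a, model)
        assert np.allclose(r[:3], 0.0, atol=1e-10)

    def test_four_classes_p15_gives_60(self, rng):
        X = rng.normal(size=(4 * 20, 30))
        labels = np.repeat(list("abcd"), 20)
        model = ft.fit_reducer(X, labels, P=15)
        assert ft.reduce_features(X[0], model).shape == (60,)

    def test_matches_direct_matrix_product(self, rng):
        X = rng.normal(size=(10, 15))
        model = ft.fit_reducer(X, ["a"] * 5 + ["b"] * 5, P=2)
        v = rng.normal(size=15)
        r = ft.reduce_features(v, model)
        expected = np.concatenate(
            [model.components[c] @ (v - model.means[c]) for c in model.class_order]
        )
        assert np.allclose(r, expected)

    def test_dimension_mismatch_errors(self, rng):
        X = rng.normal(size=(6, 10))
        model = ft.fit_reducer(X, ["a"] * 6, P=2)
        with pytest.raises(ValueError, match="mismatch"):
            ft.reduce_features(np.zeros(7), model)


class TestReducerPersistence:
    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(16, 12))
        labels = ["a"] * 8 + ["b"] * 8
        model = ft.fit_reducer(X, labels, P=3)
        model.save(tmp_path / "reducer.npz")
        loaded = ft.ReducerModel.load(tmp_path / "reducer.npz")
        assert loaded.class_order == model.class_order
        v = rng.normal(size=12)
        assert np.allclose(ft.reduce_features(v, loaded), ft.reduce_features(v, model))
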