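"""Patch codes, layer shape oracles, pooling coverage, training behaviour."""

import numpy as np
import pytest

from p300grid import cnn

# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation's arithmetic
# ---------------------------------------------------------------------------

def conv2_loops(plane, kernel):
    """Sliding-window valid cross-correlation, written as plain loops."""
    H, W = plane.shape
    h, w = kernel.shape
    out = np.empty((H - h + 1, W - w + 1))
    for i in range(H - h + 1):
        for j in range(W - w + 1):
            out[i, j] = (plane[i : i + h, j : j + w] * kernel).sum()
    return out


def pool_windows(plane_shape, patch, stride):
    """Enumerate window origins: every origin inside the map, truncated."""
    H, W = plane_shape
    rows = [r for r in range(0, H, stride[0])]
    cols = [c for c in range(0, W, stride[1])]
    return rows, cols


def pool_loops(plane, patch, stride):
    rows, cols = pool_windows(plane.shape, patch, stride)
    out = np.empty((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            out[i, j] = plane[r : r + patch[0], c : c + patch[1]].max()
    return out


ALL_STRIDE_TUPLES = {"default": None, "1x1": (1, 1), "1x2": (1, 2),
                     "1x3": (1, 3), "2x2": (2, 2), "2x3": (2, 3)}


class TestPatchCodes:
    @pytest.mark.parametrize(
        "code,conv,pool",
        [("24", (3, 2), (2, 3)), ("00", (3, 3), (2, 2)), ("52", (1, 4), (1, 2))],
    )
    def test_table_lookup(self, code, conv, pool):
        cfg = cnn.decode_patch_code(code)
        assert cfg.conv_patch == conv
        assert cfg.pool_patch == pool
        assert cfg.pool_stride == pool  # default stride = pool patch

    def test_explicit_stride(self):
        assert cnn.decode_patch_code("00", "1x3").pool_stride == (1, 3)

    @pytest.mark.parametrize("bad", ["60", "05", "9", "abc", "2x"])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            cnn.decode_patch_code(bad)

    def test_thirty_codes(self):
        assert len(cnn.PATCH_CODES) == 30
        assert len(set(cnn.PATCH_CODES)) == 30


class TestEnumerateGrid:
    def test_full_study_grid_is_4860(self):
        assert len(cnn.enumerate_grid()) == 4860

    def test_single_cell_factors(self):
        assert len(cnn.enumerate_grid(1, (500.0,), ("default",))) == 30
        assert len(cnn.enumerate_grid(1, (500.0,))) == 180

    def test_deterministic_order(self):
        assert cnn.enumerate_grid() == cnn.enumerate_grid()


class TestConvPerSlice:
    def test_shape_matches_sliding_window_oracle(self, rng):
        x = rng.normal(size=(2, 10, 11, 28))
        k = rng.normal(size=(3, 3))
        out = cnn.conv_per_slice(x, k)
        assert out.shape == (2, 8, 9, 28)
        for b in (0, 1):
            for t in (0, 13, 27):
                np.testing.assert_allclose(
                    out[b, :, :, t], conv2_loops(x[b, :, :, t], k), atol=1e-12
                )

    def test_delta_kernel_crops_input(self, rng):
        x = rng.normal(size=(1, 10, 11, 28))
        k = np.zeros((2, 2))
        k[0, 0] = 1.0
        out = cnn.conv_per_slice(x, k)
        np.testing.assert_array_equal(out, x[:, :9, :10, :])

    def test_zero_input_gives_bias_maps(self):
        out = cnn.conv_per_slice(np.zeros((1, 10, 11, 28)), np.ones((3, 3)), bias=2.5)
        assert (out == 2.5).all()

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError, match="larger than"):
            cnn.conv_per_slice(np.zeros((1, 10, 11, 28)), np.ones((11, 3)))

    def test_per_slice_kernels(self, rng):
        x = rng.normal(size=(1, 5, 5, 3))
        k = rng.normal(size=(3, 2, 2))
        out = cnn.conv_per_slice(x, k)
        for t in range(3):
            np.testing.assert_allclose(
                out[0, :, :, t], conv2_loops(x[0, :, :, t], k[t]), atol=1e-12
            )


class TestMaxPool:
    def test_default_stride_example_shape(self, rng):
        pooled = cnn.max_pool(rng.normal(size=(1, 8, 9, 2)), (2, 2))
        assert pooled.shape == (1, 4, 5, 2)

    def test_identity_pool(self, rng):
        x = rng.normal(size=(1, 6, 7, 3))
        np.testing.assert_array_equal(cnn.max_pool(x, (1, 1), (1, 1)), x)

    @pytest.mark.parametrize("code", cnn.PATCH_CODES)
    @pytest.mark.parametrize("stride", cnn.POOL_STRIDES)
    def test_all_family_shapes_match_window_origin_oracle(self, code, stride, rng):
        cfg = cnn.decode_patch_code(code, stride)
        map_shape = cnn.conv_output_shape((10, 11), cfg.conv_patch)
        rows, cols = pool_windows(map_shape, cfg.pool_patch, cfg.pool_stride)
        assert cnn.pool_output_shape(map_shape, cfg.pool_stride) == (len(rows), len(cols))
        plane = rng.normal(size=map_shape)
        np.testing.assert_array_equal(
            cnn.max_pool(plane[None, :, :, None], cfg.pool_patch, cfg.pool_stride)[0, :, :, 0],
            pool_loops(plane, cfg.pool_patch, cfg.pool_stride),
        )

    @pytest.mark.parametrize("code", cnn.PATCH_CODES)
    @pytest.mark.parametrize("stride", cnn.POOL_STRIDES)
    def test_coverage_and_overlap_iff_stride_below_patch(self, code, stride):
        cfg = cnn.decode_patch_code(code, stride)
        map_shape = cnn.conv_output_shape((10, 11), cfg.conv_patch)
        counts = cnn.pool_coverage(map_shape, cfg.pool_patch, cfg.pool_stride)
        fully_spanned = (
            cfg.pool_stride[0] <= cfg.pool_patch[0]
            and cfg.pool_stride[1] <= cfg.pool_patch[1]
        )
        if fully_spanned:
            assert (counts >= 1).all()  # the whole input is spanned
        else:
            assert (counts == 0).any()  # stride > patch skips areas
        # overlap happens exactly when the stride undercuts the patch on an axis
        overlap_expected = (
            cfg.pool_stride[0] < cfg.pool_patch[0]
            or cfg.pool_stride[1] < cfg.pool_patch[1]
        )
        assert (counts > 1).any() == overlap_expected

    def test_overlap_along_one_axis(self):
        # pool [2x3] stride [1x2] on 8x9: adjacent windows overlap along rows
        counts = cnn.pool_coverage((8, 9), (2, 3), (1, 2))
        assert (counts >= 1).all()
        assert (counts > 1).any()

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cnn.max_pool(np.zeros((1, 4, 4, 1)), (5, 2))


class TestTraining:
    def _separable_set(self, rng, n=120):
        # high-SNR bump at fixed grid cells for targets
        X = rng.normal(scale=0.3, size=(n, 10, 11, 28))
        y = (np.arange(n) % 2).astype(np.int64)
        bump = np.zeros((10, 11, 28))
        bump[4:7, 4:7, 10:16] = 3.0
        X[y == 1] += bump
        return X, y

    def test_learns_separable_data_and_matches_logistic_oracle(self, rng):
        from sklearn.linear_model import LogisticRegression

        X, y = self._separable_set(rng)
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("00"))
        net = cnn.train(spec, X, y, cnn.TrainConfig(n_epochs=100, seed=0))
        pred = net.predict(X)
        tp = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
        tn = ((pred == 0) & (y == 0)).sum() / (y == 0).sum()
        assert tp * tn > 0.95
        oracle = LogisticRegression(max_iter=1000).fit(X.reshape(len(X), -1), y)
        assert oracle.score(X.reshape(len(X), -1), y) >= 0.95

    def test_seeded_training_is_deterministic(self, rng):
        X, y = self._separable_set(rng, n=40)
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("22", "1x2"))
        a = cnn.train(spec, X, y, cnn.TrainConfig(n_epochs=5, seed=9))
        b = cnn.train(spec, X, y, cnn.TrainConfig(n_epochs=5, seed=9))
        assert np.array_equal(a.Wc, b.Wc)
        assert np.array_equal(a.W1, b.W1)
        assert np.array_equal(a.W2, b.W2)

    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        X, y = self._separable_set(rng, n=40)
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("00"))
        net = cnn.ConvNet(spec, cnn.TrainConfig(learning_rate=0.0, n_epochs=3, seed=1))
        before = net.W1.copy()
        net.fit(X, y)
        assert np.array_equal(net.W1, before)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 10, 11, 28))
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("00"))
        with pytest.raises(ValueError, match="single class"):
            cnn.train(spec, X, np.ones(10, dtype=int))

    def test_loss_trend_decreases(self, rng):
        X, y = self._separable_set(rng)
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("24"))
        net = cnn.ConvNet(spec, cnn.TrainConfig(n_epochs=30, seed=2))
        losses = net.fit(X, y)
        assert np.mean(losses[-5:]) < np.mean(losses[:5])


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        X = rng.normal(size=(7, 10, 11, 28))
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("31", "2x2"))
        net = cnn.ConvNet(spec, cnn.TrainConfig(seed=0))
        p = net.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert ((p >= 0) & (p <= 1)).all()

    def test_duplicated_inputs_get_identical_outputs(self, rng):
        x = rng.normal(size=(1, 10, 11, 28))
        X = np.concatenate([x, x])
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("00"))
        p = cnn.ConvNet(spec, cnn.TrainConfig(seed=3)).predict_proba(X)
        np.testing.assert_array_equal(p[0], p[1])

    def test_zeroed_output_layer_gives_uniform_probabilities(self, rng):
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("00"))
        net = cnn.ConvNet(spec, cnn.TrainConfig(seed=0))
        net.W2[:] = 0.0
        net.b2[:] = 0.0
        p = net.predict_proba(rng.normal(size=(5, 10, 11, 28)))
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("00"))
        net = cnn.ConvNet(spec, cnn.TrainConfig(seed=0))
        with pytest.raises(ValueError, match="input shape"):
            net.predict(rng.normal(size=(2, 64, 28)))

    def test_2d_input_kind(self, rng):
        spec = cnn.ModelSpec(patches=cnn.decode_patch_code("52"), input_kind="2d")
        net = cnn.ConvNet(spec, cnn.TrainConfig(seed=0))
        p = net.predict_proba(rng.normal(size=(3, 64, 28)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_model_spec_rejects_oversized_patches():
    too_tall = cnn.PatchConfig(
        code="xx", conv_patch=(11, 3), pool_patch=(2, 2), pool_stride=(2, 2)
    )
    with pytest.raises(ValueError, match="exceeds input plane"):
        cnn.ModelSpec(patches=too_tall)
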