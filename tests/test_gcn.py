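"""Graph construction, forward/backward correctness, and weak supervision.

The network is checked against an independently coded dense oracle (explicit
loops, no shared code) and against finite-difference gradients.
"""

import numpy as np
import pytest

from supergrid import (
    MultimodalFeatureMap,
    SpotExpression,
    SpotLayout,
    SpotPatch,
    SuperpixelGrid,
    build_adjacency,
    build_spot_patches,
    compute_patch_span,
    gcn_forward,
    infer_superres,
    export_gcn_features,
    train,
    weak_supervision_loss,
)
from supergrid import nn as sgnn
from supergrid.superres import TrainConfig


def dense_adjacency_oracle(D, normalization="sym"):
    """4-nearest-by-physical-distance adjacency built from scratch."""
    coords = [(m, n) for m in range(D) for n in range(D)]
    N = D * D
    A = np.zeros((N, N))
    for u, (mu, nu) in enumerate(coords):
        for v, (mv, nv) in enumerate(coords):
            if abs(mu - mv) + abs(nu - nv) == 1:
                A[u, v] = 1.0
    if normalization == "none":
        return A
    At = A + np.eye(N)
    deg = At.sum(1)
    if normalization == "sym":
        return At / np.sqrt(np.outer(deg, deg))
    return At / deg[:, None]


def forward_oracle(params, A, X):
    """Explicit-loop forward pass (matrix chain written out long-hand)."""
    N = A.shape[0]
    H0 = X.astype(float)
    S = np.zeros_like(H0)
    for i in range(N):
        for j in range(N):
            S[i] += A[i, j] * H0[j]
    H1 = np.maximum(S @ params.W0, 0)
    S = np.zeros_like(H1)
    for i in range(N):
        for j in range(N):
            S[i] += A[i, j] * H1[j]
    H2 = np.maximum(S @ params.W1, 0)
    P = H2 @ params.W2 + params.b
    return np.where(P > 0, P + 1, np.exp(np.minimum(P, 0))), H2


class TestPatchSpan:
    @pytest.mark.parametrize(
        "diameter,superpixel,expected",
        [(55, 8, 7), (100, 8, 13), (8, 8, 1), (4, 8, 1)],
    )
    def test_round_half_up(self, diameter, superpixel, expected):
        assert compute_patch_span(diameter, superpixel) == expected


class TestAdjacency:
    def test_d2_every_node_has_two_neighbours(self):
        g = build_adjacency(2, "none")
        assert (g.adjacency.sum(axis=1) == 2).all()

    def test_d3_degrees(self):
        g = build_adjacency(3, "none")
        deg = g.adjacency.sum(axis=1)
        assert deg[4] == 4  # center
        assert [deg[i] for i in (0, 2, 6, 8)] == [2] * 4  # corners
        assert [deg[i] for i in (1, 3, 5, 7)] == [3] * 4  # edges

    @pytest.mark.parametrize("norm", ["sym", "row", "none"])
    def test_matches_dense_oracle(self, norm):
        g = build_adjacency(5, norm)
        np.testing.assert_allclose(g.adjacency, dense_adjacency_oracle(5, norm),
                                   atol=1e-12)

    def test_row_normalization_unit_row_sums(self):
        g = build_adjacency(4, "row")
        np.testing.assert_allclose(g.adjacency.sum(axis=1), 1.0)

    def test_symmetric(self):
        g = build_adjacency(5, "sym")
        np.testing.assert_allclose(g.adjacency, g.adjacency.T)

    def test_invalid_d(self):
        with pytest.raises(ValueError):
            build_adjacency(0)


class TestForward:
    def test_zero_weights_give_unit_output(self):
        params = sgnn.GCNParams(
            W0=np.zeros((4, 6)), W1=np.zeros((6, 6)), W2=np.zeros((6, 2)),
            b=np.zeros(2),
        )
        g = build_adjacency(3)
        out = gcn_forward(params, np.random.default_rng(0).random((3, 3, 4)), g)
        np.testing.assert_allclose(out, 1.0)  # ELU(0) + 1

    def test_output_nonnegative(self):
        r = np.random.default_rng(1)
        params = sgnn.init_params(4, 2, hidden_dim=6, seed=0, dtype=np.float64)
        params.b -= 5.0  # push pre-activations negative
        g = build_adjacency(3)
        out = gcn_forward(params, r.normal(size=(3, 3, 4)), g)
        assert (out >= 0).all()

    def test_matches_dense_oracle(self):
        r = np.random.default_rng(2)
        params = sgnn.init_params(4, 2, hidden_dim=8, seed=1, dtype=np.float64)
        g = build_adjacency(3)
        X = r.normal(size=(9, 4))
        got = sgnn.forward(params, g.adjacency, X)
        want, _ = forward_oracle(params, g.adjacency, X)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_channel_mismatch_raises(self):
        params = sgnn.init_params(4, 2, hidden_dim=8, seed=1)
        with pytest.raises(ValueError, match="channels"):
            gcn_forward(params, np.zeros((3, 3, 5)), build_adjacency(3))


class TestLoss:
    def test_exact_sum_gives_zero(self):
        pred = np.full((9, 1), 2.0)
        filt = np.zeros((3, 3), dtype=bool)
        filt[1, 1] = filt[0, 1] = True
        assert weak_supervision_loss(pred, filt, np.array([4.0])) == 0.0

    def test_squared_residual(self):
        pred = np.full((9, 1), 1.0)
        filt = np.ones((3, 3), dtype=bool)
        filt[0, 0] = False
        # in-disc sum is 8, label 10 -> (10 - 8)^2 = 4
        assert weak_supervision_loss(pred, filt, np.array([10.0])) == pytest.approx(4.0)

    def test_batch_matches_per_spot_loop(self):
        r = np.random.default_rng(3)
        params = sgnn.init_params(5, 3, hidden_dim=8, seed=0, dtype=np.float64)
        g = build_adjacency(3)
        X = r.normal(size=(6, 9, 5))
        F = r.random((6, 9)) > 0.4
        F[:, 4] = True
        G = r.gamma(2.0, 1.0, size=(6, 3))
        batched, _ = sgnn.loss_and_grads(params, g.adjacency, X, F, G)
        total = 0.0
        for b in range(6):
            Z = sgnn.forward(params, g.adjacency, X[b])
            total += weak_supervision_loss(Z, F[b], G[b])
        assert batched == pytest.approx(total, rel=1e-10)

    def test_empty_filter_warns_and_contributes_zero(self):
        with pytest.warns(UserWarning, match="empty circular filter"):
            out = weak_supervision_loss(
                np.ones((9, 1)), np.zeros((3, 3), dtype=bool), np.array([5.0])
            )
        assert out == 0.0


class TestGradients:
    def test_finite_difference_check(self):
        r = np.random.default_rng(4)
        params = sgnn.init_params(3, 2, hidden_dim=5, seed=0, dtype=np.float64)
        g = build_adjacency(2)
        X = r.normal(size=(3, 4, 3))
        F = np.ones((3, 4), dtype=bool)
        G = r.gamma(2.0, 1.0, size=(3, 2))
        _, grads = sgnn.loss_and_grads(params, g.adjacency, X, F, G)
        eps = 1e-6
        for key in ("W0", "W1", "W2", "b"):
            arr = params.arrays()[key]
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = sgnn.loss_and_grads(params, g.adjacency, X, F, G)
                arr[idx] = orig - eps
                lm, _ = sgnn.loss_and_grads(params, g.adjacency, X, F, G)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def _constant_patches(D, C, K, n_spots, v):
    feats = np.ones((D, D, C))
    filt = np.ones((D, D), dtype=bool)
    label = np.full(K, v * D * D)
    return [
        SpotPatch(features=feats, filter=filt, label=label, spot_id=j)
        for j in range(n_spots)
    ]


class TestTrain:
    def test_constant_fixture_converges_to_constant_value(self):
        """With row-normalized aggregation and constant inputs the exact
        solution is a constant field of v per superpixel; training finds it."""
        D, C, K, v = 3, 4, 2, 2.0
        patches = _constant_patches(D, C, K, 8, v)
        g = build_adjacency(D, "row")
        cfg = TrainConfig(learning_rate=5e-3, batch_size=8, epochs=800, seed=0,
                          patience=800)
        params, history = train(patches, g, cfg, hidden_dim=16)
        assert history[-1] < 1e-2 * history[0]
        Z = gcn_forward(params, patches[0].features.astype(np.float32), g)
        np.testing.assert_allclose(Z, v, rtol=0.05)

    def test_loss_decreases_and_is_deterministic(self):
        r = np.random.default_rng(5)
        D, C, K = 3, 4, 2
        patches = [
            SpotPatch(
                features=r.random((D, D, C)),
                filter=np.ones((D, D), dtype=bool),
                label=r.gamma(3.0, 2.0, size=K),
                spot_id=j,
            )
            for j in range(10)
        ]
        g = build_adjacency(D)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=4, epochs=100, seed=7,
                          patience=100)
        p1, h1 = train(patches, g, cfg, hidden_dim=16)
        p2, h2 = train(patches, g, cfg, hidden_dim=16)
        assert h1 == h2
        for key in ("W0", "W1", "W2", "b"):
            np.testing.assert_array_equal(p1.arrays()[key], p2.arrays()[key])
        assert h1[-1] < h1[0]

    def test_duplicated_gene_columns_get_matching_predictions(self):
        """Two genes with identical labels converge to near-identical
        predicted columns (no cross-gene leakage in the head)."""
        r = np.random.default_rng(6)
        D, C = 3, 4
        patches = []
        for j in range(10):
            lab = r.gamma(3.0, 2.0)
            patches.append(
                SpotPatch(
                    features=r.random((D, D, C)),
                    filter=np.ones((D, D), dtype=bool),
                    label=np.array([lab, lab]),
                    spot_id=j,
                )
            )
        g = build_adjacency(D)
        cfg = TrainConfig(learning_rate=5e-3, batch_size=10, epochs=1500, seed=0,
                          patience=1500)
        params, history = train(patches, g, cfg, hidden_dim=16)
        Z = gcn_forward(params, patches[0].features.astype(np.float32), g)
        assert np.abs(Z[:, 0] - Z[:, 1]).max() / Z.mean() < 0.1

    def test_requires_two_spots(self):
        with pytest.raises(ValueError, match="at least 2"):
            train(_constant_patches(3, 4, 2, 1, 1.0), build_adjacency(3))


def _toy_fmap(rng, R=10, Co=8, C=5):
    grid = SuperpixelGrid(n_rows=R, n_cols=Co)
    channels = rng.normal(size=(C, R, Co))
    roles = ("hist",) * C
    mask = np.ones((R, Co), dtype=bool)
    return MultimodalFeatureMap(channels=channels, channel_roles=roles,
                                grid=grid, mask=mask)


class TestSpotPatches:
    def test_d1_patch_is_single_superpixel(self, rng):
        fmap = _toy_fmap(rng)
        lay = SpotLayout(centers_um=np.array([[20.0, 36.0]]), diameter_um=8.0,
                         pitch_um=100.0)
        spots = SpotExpression(np.ones((1, 2)), ("a", "b"), lay)
        (patch,) = build_spot_patches(fmap, lay, spots, D=1)
        assert patch.filter.shape == (1, 1) and patch.filter.all()
        np.testing.assert_array_equal(patch.features[0, 0], fmap.channels[:, 4, 2])

    def test_filter_count_matches_distance_oracle(self, rng):
        fmap = _toy_fmap(rng, R=20, Co=20)
        lay = SpotLayout(centers_um=np.array([[80.0, 80.0]]))
        spots = SpotExpression(np.ones((1, 1)), ("a",), lay)
        (patch,) = build_spot_patches(fmap, lay, spots, D=7)
        count = 0
        for m in range(20):
            for n in range(20):
                if ((n + 0.5) * 8 - 80) ** 2 + ((m + 0.5) * 8 - 80) ** 2 <= 27.5**2:
                    count += 1
        assert patch.filter.sum() == count

    def test_distant_spots_share_no_superpixels(self, rng):
        fmap = _toy_fmap(rng, R=20, Co=30)
        lay = SpotLayout(
            centers_um=np.array([[40.0, 80.0], [200.0, 80.0]]), diameter_um=55.0,
            pitch_um=160.0,
        )
        spots = SpotExpression(np.ones((2, 1)), ("a",), lay)
        p1, p2 = build_spot_patches(fmap, lay, spots, D=7)
        # centers are 160 µm apart >= D * 8 = 56, so index blocks are disjoint
        assert abs(p1.spot_id - p2.spot_id) == 1
        # block columns: centers at n=9 and n=24, half-span 3 -> cols 6..12, 21..27
        assert 12 < 21

    def test_offmap_spot_skipped_with_warning(self, rng):
        fmap = _toy_fmap(rng)
        lay = SpotLayout(centers_um=np.array([[20.0, 36.0], [900.0, 900.0]]))
        spots = SpotExpression(np.ones((2, 1)), ("a",), lay)
        with pytest.warns(UserWarning, match="off the feature map"):
            patches = build_spot_patches(fmap, lay, spots, D=3)
        assert len(patches) == 1


class TestDepthNormalization:
    def test_labels_rescaled_to_median_library_size(self, rng):
        from supergrid import SuperResolutionGCN

        fmap = _toy_fmap(rng, R=20, Co=30)
        lay = SpotLayout(
            centers_um=np.array([[40.0, 80.0], [140.0, 80.0], [200.0, 80.0]]),
            diameter_um=55.0,
            pitch_um=100.0,
        )
        counts = rng.gamma(3.0, 5.0, size=(3, 4))
        spots = SpotExpression(counts, ("a", "b", "c", "d"), lay)
        model = SuperResolutionGCN(fmap, spots, normalize_depth=True)
        libs = model.spot_expr.counts.sum(axis=1)
        np.testing.assert_allclose(libs, np.median(counts.sum(axis=1)), rtol=1e-9)
        # off by default: labels untouched
        model2 = SuperResolutionGCN(fmap, spots)
        np.testing.assert_array_equal(model2.spot_expr.counts, counts)


class TestInference:
    def test_all_false_mask_zero_output(self, rng):
        fmap = _toy_fmap(rng, R=6, Co=6)
        params = sgnn.init_params(5, 3, hidden_dim=8, seed=0)
        g = build_adjacency(3)
        out = infer_superres(fmap, params, g, mask=np.zeros((6, 6), dtype=bool))
        assert (out.values == 0).all()

    def test_single_tile_equals_forward(self, rng):
        fmap = _toy_fmap(rng, R=3, Co=3)
        params = sgnn.init_params(5, 2, hidden_dim=8, seed=0)
        g = build_adjacency(3)
        out = infer_superres(fmap, params, g)
        direct = gcn_forward(
            params, np.moveaxis(fmap.channels, 0, -1).astype(np.float32), g
        )
        np.testing.assert_allclose(out.values, direct.reshape(3, 3, 2), atol=1e-6)

    def test_tiles_predicted_independently(self, rng):
        """A 3D x 2D map equals the six independent single-tile predictions."""
        D = 3
        fmap = _toy_fmap(rng, R=3 * D, Co=2 * D)
        params = sgnn.init_params(5, 2, hidden_dim=8, seed=0)
        g = build_adjacency(D)
        out = infer_superres(fmap, params, g)
        for ti in range(3):
            for tj in range(2):
                block = fmap.channels[:, D * ti : D * (ti + 1), D * tj : D * (tj + 1)]
                single = gcn_forward(
                    params, np.moveaxis(block, 0, -1).astype(np.float32), g
                ).reshape(D, D, 2)
                np.testing.assert_allclose(
                    out.values[D * ti : D * (ti + 1), D * tj : D * (tj + 1)],
                    single,
                    atol=1e-6,
                )

    def test_gcn_feature_export_shape_mask_and_oracle(self, rng):
        fmap = _toy_fmap(rng, R=3, Co=3)
        params = sgnn.init_params(5, 2, hidden_dim=8, seed=0, dtype=np.float64)
        g = build_adjacency(3)
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 0] = False
        feats = export_gcn_features(fmap, params, g, mask=mask)
        assert feats.shape == (8, 3, 3)
        assert (feats[:, 0, 0] == 0).all()
        X = np.moveaxis(fmap.channels, 0, -1).reshape(9, 5)
        _, H2 = forward_oracle(params, g.adjacency, X)
        np.testing.assert_allclose(
            feats[:, 1, 1], H2.reshape(3, 3, 8)[1, 1], atol=1e-5
        )
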