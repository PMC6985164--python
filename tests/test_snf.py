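"""SNF kernel, normalization, fusion and spectral clustering contracts."""

import numpy as np
import pytest

from omicsfuse import (
    AffinityNetwork,
    OmicsLayer,
    SNFParams,
    affinity_from_layer,
    cluster_concordance,
    estimate_k_eigengap,
    fuse,
    spectral_cluster,
    status_and_local,
)
from omicsfuse.snf import fuse_layers


def _net(W, ids=None):
    ids = ids or [f"S{i}" for i in range(W.shape[0])]
    return AffinityNetwork(sample_ids=ids, W=np.asarray(W, dtype=float))


def _block_affinity(sizes, within=1.0, between=0.0, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    W = np.full((n, n), between)
    start = 0
    for s in sizes:
        blk = within + (rng.uniform(-jitter, jitter, size=(s, s)) if jitter else 0.0)
        W[start : start + s, start : start + s] = blk
        start += s
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    return _net(W)


class TestAffinityKernel:
    def test_three_sample_kernel_hand_oracle(self):
        # pairwise distances d12=1, d13=2, d23=2; K=1, alpha=0.5.
        # mu = (1, 1, 2); eps12 = 1, eps13 = eps23 = 5/3, so
        # W12 = exp(-1/0.5) and W13 = W23 = exp(-4/(0.5*5/3)).
        X = np.array([[0.0], [1.0], [-2.0]])  # d12=1, d13=2, d23=3? no:
        # place points at 0, 1, 2 on a line: d12=1, d13=2, d23=1 — wrong.
        # use 2-D coordinates realizing (1, 2, 2):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(4 - 0.25)]])
        lay = OmicsLayer("toy", ["a", "b", "c"], ["f1", "f2"], X)
        net = affinity_from_layer(
            lay, SNFParams(n_neighbors=1, alpha=0.5), assume_standardized=True
        )
        assert net.W[0, 1] == pytest.approx(np.exp(-2.0), rel=1e-12)
        assert net.W[0, 2] == pytest.approx(np.exp(-4.8), rel=1e-12)
        assert net.W[1, 2] == pytest.approx(np.exp(-4.8), rel=1e-12)
        assert np.allclose(np.diag(net.W), 1.0)

    def test_identical_samples_maximal_affinity(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.1]])
        lay = OmicsLayer("toy", list("abcd"), ["f1", "f2"], X)
        net = affinity_from_layer(
            lay, SNFParams(n_neighbors=2, alpha=0.7), assume_standardized=True
        )
        assert net.W[0, 1] == pytest.approx(1.0)

    def test_all_identical_samples_rejected(self):
        X = np.ones((5, 3))
        lay = OmicsLayer("toy", list("abcde"), ["f1", "f2", "f3"], X)
        with pytest.raises(ValueError, match="zero"):
            affinity_from_layer(lay, SNFParams(n_neighbors=2), assume_standardized=True)

    def test_zero_variance_feature_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        X[:, 2] = 7.0
        lay = OmicsLayer("toy", [f"s{i}" for i in range(10)], list("wxyz"), X)
        with caplog.at_level("WARNING"):
            net = affinity_from_layer(lay, SNFParams(n_neighbors=3))
        assert "zero-variance" in caplog.text
        assert net.n_samples == 10


class TestStatusAndLocal:
    def test_row_normalizations(self, rng):
        W = rng.uniform(0.1, 1.0, size=(8, 8))
        W = (W + W.T) / 2
        P, S = status_and_local(_net(W), K=3)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(P), 0.5)
        np.testing.assert_allclose(np.diag(S), 0.0)

    def test_full_K_equals_row_normalized_offdiagonal(self, rng):
        W = rng.uniform(0.1, 1.0, size=(6, 6))
        W = (W + W.T) / 2
        _, S = status_and_local(_net(W), K=5)
        off = W.copy()
        np.fill_diagonal(off, 0.0)
        np.testing.assert_allclose(S, off / off.sum(axis=1, keepdims=True), atol=1e-12)

    def test_4x4_toy_local_kernel_hand_oracle(self):
        W = np.array(
            [
                [1.0, 0.8, 0.4, 0.1],
                [0.8, 1.0, 0.2, 0.3],
                [0.4, 0.2, 1.0, 0.6],
                [0.1, 0.3, 0.6, 1.0],
            ]
        )
        _, S = status_and_local(_net(W), K=2)
        # row 0 neighbours: {1 (0.8), 2 (0.4)} -> 0.8/1.2, 0.4/1.2
        np.testing.assert_allclose(S[0], [0.0, 0.8 / 1.2, 0.4 / 1.2, 0.0])
        # row 3 neighbours: {2 (0.6), 1 (0.3)} -> 0.3/0.9, 0.6/0.9
        np.testing.assert_allclose(S[3], [0.0, 0.3 / 0.9, 0.6 / 0.9, 0.0])

    def test_isolated_sample_named_in_error(self):
        W = np.eye(4)
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.0
        W[0, 2] = W[2, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.2
        with pytest.raises(ValueError, match="S3"):
            status_and_local(_net(W), K=2)


class TestFusion:
    def test_requires_two_layers_and_consistent_order(self, small_dataset, snf_params):
        lay = small_dataset.layers[0]
        with pytest.raises(ValueError, match="two layers"):
            fuse_layers([lay], snf_params)
        other = OmicsLayer(
            "x", list(reversed(lay.sample_ids)), lay.feature_ids, lay.values
        )
        with pytest.raises(ValueError, match="order mismatch"):
            fuse_layers([lay, other], snf_params)

    @pytest.mark.parametrize("t", [1, 5, 25])
    def test_identical_layers_fixed_point_labels(self, t):
        # fusing copies of the same layer must reproduce that layer's
        # spectral clustering exactly, for any iteration count
        net = _block_affinity([6, 6], within=1.0, between=0.05, jitter=0.02, seed=3)
        P, S = status_and_local(net, K=4)
        fused = fuse([(P, S), (P.copy(), S.copy())], t=t, sample_ids=net.sample_ids)
        single = spectral_cluster(net, 2, seed=0)
        merged = spectral_cluster(fused, 2, seed=0)
        ari, agreement = cluster_concordance(single, merged)
        assert ari == pytest.approx(1.0)
        assert agreement == pytest.approx(1.0)

    def test_permutation_equivariance(self, small_dataset, snf_params, rng):
        lay = small_dataset.layers[0]
        fused = fuse_layers([lay, lay], snf_params)
        perm = rng.permutation(lay.n_samples)
        lay_p = OmicsLayer(
            "x",
            [lay.sample_ids[i] for i in perm],
            lay.feature_ids,
            lay.values[perm],
        )
        fused_p = fuse_layers([lay_p, lay_p], snf_params)
        np.testing.assert_allclose(fused_p.W, fused.W[np.ix_(perm, perm)], atol=1e-10)

    def test_discordant_layers_resolved_by_fusion(self):
        # two planted-block layers with different misled samples: each
        # alone misclusters, together they recover the truth
        from omicsfuse import LayerSpec, SynthConfig, generate_multiomics

        cfg = SynthConfig(
            n_samples=40,
            layer_specs=(
                LayerSpec("a", 60, 12, 2.0, 1.0, 0.3),
                LayerSpec("b", 60, 12, 2.0, 1.0, 0.3),
                LayerSpec("c", 60, 12, 2.0, 1.0, 0.0),
            ),
            seed=4,
        )
        ds = generate_multiomics(cfg)
        params = SNFParams(n_neighbors=15, alpha=0.7, iterations=20)
        fused = fuse_layers(ds.layers, params)
        ari_fused, _ = cluster_concordance(
            spectral_cluster(fused, 2, seed=0), ds.true_labels
        )
        ari_a, _ = cluster_concordance(
            spectral_cluster(affinity_from_layer(ds.layers[0], params), 2, seed=0),
            ds.true_labels,
        )
        assert ari_fused == pytest.approx(1.0)
        assert ari_a < ari_fused


class TestSpectral:
    def test_block_diagonal_recovers_blocks(self):
        net = _block_affinity([5, 7], within=1.0, between=0.0)
        labels = spectral_cluster(net, 2, seed=0).labels
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_noisy_three_block_recovery_over_seeds(self):
        net = _block_affinity([8, 8, 8], within=1.0, between=0.05, jitter=0.05, seed=1)
        truth = np.repeat([1, 2, 3], 8)
        from omicsfuse import SubtypeAssignment

        t = SubtypeAssignment(sample_ids=net.sample_ids, labels=truth)
        for seed in range(10):
            ari, _ = cluster_concordance(spectral_cluster(net, 3, seed=seed), t)
            assert ari == pytest.approx(1.0)

    def test_k_out_of_range_rejected(self):
        net = _block_affinity([4, 4])
        with pytest.raises(ValueError):
            spectral_cluster(net, 9)
        with pytest.raises(ValueError):
            spectral_cluster(net, 1)

    def test_determinism_under_seed(self, small_dataset, snf_params):
        fused = fuse_layers([small_dataset.layers[0]] * 2, snf_params)
        a = spectral_cluster(fused, 2, seed=42).labels
        b = spectral_cluster(fused, 2, seed=42).labels
        np.testing.assert_array_equal(a, b)


class TestEigengap:
    def test_three_blocks_give_three(self):
        net = _block_affinity([7, 7, 7], within=1.0, between=0.0)
        assert estimate_k_eigengap(net, k_max=6) == 3

    def test_complete_graph_weak_gap_flagged(self, caplog):
        n = 12
        W = np.ones((n, n))
        with caplog.at_level("WARNING"):
            k = estimate_k_eigengap(_net(W), k_max=5)
        assert k == 2
        assert "weak eigengap" in caplog.text

    def test_invalid_k_max(self):
        net = _block_affinity([4, 4])
        with pytest.raises(ValueError):
            estimate_k_eigengap(net, k_max=1)
        with pytest.raises(ValueError):
            estimate_k_eigengap(net, k_max=8)
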