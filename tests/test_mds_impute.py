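"""Classical MDS and cross-network imputation: oracles and round-trips."""

import numpy as np
import pytest

from aesig.mds_impute import (DimRule, classical_mds, embed_network,
                              fit_cross_map, impute_coordinates,
                              impute_network,
                              similarity_to_squared_dissimilarity)
from aesig.synthetic import SyntheticConfig, gen_multisource_networks
from aesig.types import SimilarityNetwork


def _pairwise_sq(coords):
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(coords, metric="sqeuclidean"))


class TestConversion:
    @pytest.mark.parametrize("s,d2", [(1.0, 0.0), (0.0, 2.0), (0.5, 1.0)])
    def test_forward_values(self, s, d2):
        M = np.array([[1.0, s], [s, 1.0]])
        net = SimilarityNetwork(ids=["a", "b"], matrix=M, source="t")
        out = similarity_to_squared_dissimilarity(net)
        assert out[0, 1] == pytest.approx(d2)
        assert out[0, 0] == 0.0


class TestClassicalMDS:
    def test_line_points_oracle(self):
        # points at 0, 3, 4 on a line; direct -1/2 H D2 H arithmetic gives
        # the Gram matrix of centered coordinates (-7/3, 2/3, 5/3)
        d2 = np.array([[0.0, 9.0, 16.0], [9.0, 0.0, 1.0], [16.0, 1.0, 0.0]])
        H = np.eye(3) - np.ones((3, 3)) / 3
        C_oracle = -0.5 * H @ d2 @ H
        assert C_oracle[0, 0] == pytest.approx(49 / 9)
        emb = classical_mds(d2, ["a", "b", "c"])
        np.testing.assert_allclose(_pairwise_sq(emb.coords), d2, atol=1e-8)
        # 1-dimensional input geometry recovered
        assert emb.dim == 1
        np.testing.assert_allclose(np.abs(emb.coords[:, 0]),
                                   [7 / 3, 2 / 3, 5 / 3], atol=1e-8)

    def test_two_points_symmetric_embedding(self):
        d2 = np.array([[0.0, 4.0], [4.0, 0.0]])
        emb = classical_mds(d2, ["a", "b"])
        np.testing.assert_allclose(np.abs(emb.coords[:, 0]), [1.0, 1.0],
                                   atol=1e-10)

    def test_embedding_model_invariants(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((12, 3))
        emb = classical_mds(_pairwise_sq(pts), [f"d{i}" for i in range(12)])
        assert np.abs(emb.coords.mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose((emb.coords ** 2).sum(axis=0),
                                   emb.eigvals, rtol=1e-6)
        assert (np.diff(emb.eigvals) <= 1e-12).all()

    def test_round_trip_similarity(self):
        # similarity -> d2 -> MDS -> distances -> similarity is the identity
        # whenever the centered matrix is PSD
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((10, 3)) + 3.0
        U = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        S = U @ U.T
        np.fill_diagonal(S, 1.0)
        net = SimilarityNetwork(ids=[f"d{i}" for i in range(10)], matrix=S,
                                source="t")
        emb = embed_network(net)
        S_back = 1.0 - _pairwise_sq(emb.coords) / 2.0
        np.fill_diagonal(S_back, 1.0)
        np.testing.assert_allclose(S_back, S, atol=1e-6)

    def test_degenerate_rejected(self):
        d2 = np.zeros((3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            classical_mds(d2, ["a", "b", "c"])


class TestCrossMap:
    def _two_embeddings(self, seed=0, noise=0.0, n=50):
        rng = np.random.default_rng(seed)
        P = rng.standard_normal((n, 3))
        P -= P.mean(axis=0)
        B = rng.standard_normal((3, 3))
        Q = P @ B + rng.normal(0, noise, (n, 3))
        from aesig.mds_impute import EmbeddingModel
        ids = [f"d{i}" for i in range(n)]
        mkeig = lambda X: np.sort((X ** 2).sum(axis=0))[::-1]

        def model(X, src):
            order = np.argsort(-(X ** 2).sum(axis=0))
            Xs = X[:, order] - X[:, order].mean(axis=0)
            return EmbeddingModel(ids=ids, coords=Xs,
                                  eigvals=(Xs ** 2).sum(axis=0), source=src)
        return model(P, "p"), model(Q, "q"), B

    def test_noiseless_fit_is_exact(self):
        src, tgt, B = self._two_embeddings(noise=0.0)
        cmap = fit_cross_map(src, tgt)
        assert cmap.residual_scale < 1e-8
        pred = impute_coordinates(cmap, src.coords)
        np.testing.assert_allclose(pred, tgt.coords, atol=1e-8)

    def test_identity_map_recovered(self):
        src, _, _ = self._two_embeddings()
        cmap = fit_cross_map(src, src)
        np.testing.assert_allclose(cmap.B, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(cmap.intercept, 0.0, atol=1e-8)

    def test_noisy_coefficients_close(self):
        hits = 0
        for s in range(10):
            src, tgt, B = self._two_embeddings(seed=s, noise=0.01)
            cmap = fit_cross_map(src, tgt)
            # coordinates are permuted by eigenvalue order; compare the fit
            # via prediction error instead of raw coefficients
            pred = impute_coordinates(cmap, src.coords)
            rmse = np.sqrt(np.mean((pred - tgt.coords) ** 2))
            hits += rmse < 3 * 0.01
        assert hits >= 9

    def test_zero_input_gives_intercept(self):
        src, tgt, _ = self._two_embeddings()
        cmap = fit_cross_map(src, tgt)
        np.testing.assert_allclose(impute_coordinates(cmap, np.zeros(3)),
                                   cmap.intercept)

    def test_shared_set_too_small(self):
        src, tgt, _ = self._two_embeddings(n=50)
        tgt.ids = [f"x{i}" for i in range(46)] + tgt.ids[:4]
        with pytest.raises(ValueError, match="shared"):
            fit_cross_map(src, tgt)

    def test_length_mismatch(self):
        src, tgt, _ = self._two_embeddings()
        cmap = fit_cross_map(src, tgt)
        with pytest.raises(ValueError, match="length"):
            impute_coordinates(cmap, np.zeros(5))


class TestImputeNetwork:
    def test_full_target_passthrough(self):
        cfg = SyntheticConfig(seed=5, n_drugs=30, n_sources=2,
                              coverage=(1.0, 1.0))
        nets, _ = gen_multisource_networks(cfg)
        out = impute_network(nets[0], nets[1])
        assert out.stage == "second"
        sub = out.to_frame().loc[nets[1].ids, nets[1].ids].to_numpy()
        assert (sub == nets[1].matrix).all()

    def test_noise_free_recovery(self):
        cfg = SyntheticConfig(seed=3, n_drugs=100, latent_dim=3,
                              n_sources=2, coverage=(1.0, 0.8),
                              map_noise_sd=0.0)
        nets, truth = gen_multisource_networks(cfg)
        out = impute_network(nets[0], nets[1]).to_frame()
        T = truth.true_similarities[nets[1].source]
        masked = [d for d in nets[0].ids if d not in set(nets[1].ids)]
        diff = (out.loc[masked, nets[0].ids]
                - T.loc[masked, nets[0].ids]).to_numpy()
        assert np.abs(diff).max() < 1e-6

    def test_observed_entries_bitwise_preserved(self):
        cfg = SyntheticConfig(seed=4, n_drugs=60, n_sources=2,
                              coverage=(1.0, 0.7), map_noise_sd=0.05)
        nets, _ = gen_multisource_networks(cfg)
        out = impute_network(nets[0], nets[1]).to_frame()
        sub = out.loc[nets[1].ids, nets[1].ids].to_numpy()
        assert (sub == nets[1].matrix).all()

    def test_orphan_drug_rejected(self):
        cfg = SyntheticConfig(seed=5, n_drugs=20, n_sources=2,
                              coverage=(1.0, 0.9))
        nets, _ = gen_multisource_networks(cfg)
        small = nets[0].reindex(nets[0].ids[:15])
        with pytest.raises(ValueError, match="anchor"):
            impute_network(small, nets[1])
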