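import numpy as np
import pytest

import lnrlink as L
from oracles import ridge_column_minimizer


def random_symmetric_bipartite(rng, ln, mn):
    """A bipartite matrix with random similarity blocks and a random sparse
    interaction block."""
    A = rng.standard_normal((ln, ln))
    lsm = L.SimilarityMatrix([f"l{i}" for i in range(ln)],
                             (A + A.T) / (2 * ln) + np.eye(ln))
    B = rng.standard_normal((mn, mn))
    msm = L.SimilarityMatrix([f"m{i}" for i in range(mn)],
                             (B + B.T) / (2 * mn) + np.eye(mn))
    lmn = L.InteractionMatrix(lsm.entity_ids, msm.entity_ids,
                              (rng.random((ln, mn)) < 0.4).astype(int))
    return L.build_bipartite(lsm, msm, lmn)


class TestBuildBipartite:
    def test_single_pair_network(self):
        m = L.build_bipartite(
            L.SimilarityMatrix(["l1"], [[1.0]]),
            L.SimilarityMatrix(["m1"], [[1.0]]),
            L.InteractionMatrix(["l1"], ["m1"], [[1]]),
        )
        assert np.array_equal(m.values, np.ones((2, 2)))
        assert m.node_ids == ["l1", "m1"]

    def test_block_placement_and_symmetry(self, rng):
        m = random_symmetric_bipartite(rng, 2, 1)
        assert m.values.shape == (3, 3)
        assert np.abs(m.values - m.values.T).max() <= 1e-12
        lay = m.block_layout
        assert np.array_equal(m.values[lay.lnc, lay.mirna],
                              m.values[lay.mirna, lay.lnc].T)

    def test_zero_network_is_block_diagonal(self):
        lsm = L.SimilarityMatrix(["l1", "l2"], np.eye(2))
        msm = L.SimilarityMatrix(["m1"], [[1.0]])
        lmn = L.InteractionMatrix(["l1", "l2"], ["m1"], [[0], [0]])
        m = L.build_bipartite(lsm, msm, lmn)
        assert np.array_equal(m.values, np.eye(3))

    def test_id_mismatch_named_in_error(self):
        lsm = L.SimilarityMatrix(["lX"], [[1.0]])
        msm = L.SimilarityMatrix(["m1"], [[1.0]])
        lmn = L.InteractionMatrix(["l1"], ["m1"], [[1]])
        with pytest.raises(ValueError, match="lncRNA"):
            L.build_bipartite(lsm, msm, lmn)
        with pytest.raises(ValueError, match="miRNA"):
            L.build_bipartite(
                L.SimilarityMatrix(["l1"], [[1.0]]),
                L.SimilarityMatrix(["mX"], [[1.0]]), lmn)


class TestSolveWeights:
    def test_identity_input_halves(self):
        m = L.BipartiteMatrix(["a", "b"], np.eye(2), L.BlockLayout(1, 1))
        c = L.solve_weights(m, L.ModelConfig(alpha=1.0))
        assert np.allclose(c.values, 0.5 * np.eye(2), atol=1e-12)

    def test_vanishing_alpha_gives_zero_weights(self, rng):
        m = random_symmetric_bipartite(rng, 3, 2)
        c = L.solve_weights(m, L.ModelConfig(alpha=1e-14))
        assert np.abs(c.values).max() <= 1e-12

    def test_matches_generic_quadratic_minimizer(self, rng):
        m = random_symmetric_bipartite(rng, 4, 2)
        for alpha in (0.018, 1.0):
            C = L.solve_weights(m, L.ModelConfig(alpha=alpha)).values
            C_oracle = ridge_column_minimizer(m.values, alpha)
            assert np.linalg.norm(C - C_oracle, "fro") <= 1e-6

    def test_stationarity_of_objective_gradient(self, rng):
        m = random_symmetric_bipartite(rng, 5, 3)
        alpha = 0.018
        C = L.solve_weights(m, L.ModelConfig(alpha=alpha)).values
        gram = m.values.T @ m.values
        grad = alpha * (gram @ C - gram) + C
        assert np.linalg.norm(grad, "fro") <= 1e-8 * np.linalg.norm(gram, "fro")

    def test_spectral_shrinkage(self, rng):
        m = random_symmetric_bipartite(rng, 4, 3)
        alpha = 0.04
        C = L.solve_weights(m, L.ModelConfig(alpha=alpha)).values
        lam = np.linalg.eigvalsh(m.values.T @ m.values)
        expected = np.sort(alpha * lam / (1 + alpha * lam))
        got = np.sort(np.linalg.eigvalsh((C + C.T) / 2))
        assert np.allclose(got, expected, atol=1e-8)
        assert got.min() >= 0 and got.max() < 1

    def test_nonfinite_input_rejected(self):
        vals = np.full((2, 2), np.nan)
        m = L.BipartiteMatrix.__new__(L.BipartiteMatrix)
        m.node_ids = ["a", "b"]
        m.values = vals
        m.block_layout = L.BlockLayout(1, 1)
        with pytest.raises(ValueError, match="non-finite"):
            L.solve_weights(m, L.ModelConfig())


class TestScoreAndExtract:
    def test_swap_matrix_closed_form(self):
        # M = [[0,1],[1,0]]: M'M = I, C* = 0.5 I, S = 0.5 M
        m = L.BipartiteMatrix(["l1", "m1"], np.array([[0.0, 1], [1, 0]]),
                              L.BlockLayout(1, 1))
        c = L.solve_weights(m, L.ModelConfig(alpha=1.0))
        s = L.score_matrix(m, c)
        assert np.allclose(s.values, [[0, 0.5], [0.5, 0]], atol=1e-12)
        pred = L.extract_predictions(s, m.block_layout)
        assert pred.scores[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_weights_give_zero_scores(self, rng):
        m = random_symmetric_bipartite(rng, 3, 2)
        s = L.score_matrix(m, L.WeightMatrix(np.zeros((5, 5))))
        assert not s.values.any()

    def test_symmetry_propagates_to_scores(self, rng):
        m = random_symmetric_bipartite(rng, 6, 4)
        res = L.solve_weights(m, L.ModelConfig(alpha=0.018))
        s = L.score_matrix(m, res)
        denom = np.abs(s.values).max()
        assert np.abs(s.values - s.values.T).max() <= 1e-10 * max(denom, 1)

    def test_extraction_averages_cross_blocks(self, rng):
        m = random_symmetric_bipartite(rng, 3, 2)
        s = L.score_matrix(m, L.solve_weights(m, L.ModelConfig()))
        pred = L.extract_predictions(s, m.block_layout)
        assert np.allclose(pred.scores, s.values[:3, 3:], atol=1e-12)
        # perturb one cross entry: the output is the midpoint
        sv = s.values.copy()
        sv[0, 3] += 0.1
        pred2 = L.extract_predictions(L.ScoreMatrix(s.node_ids, sv),
                                      m.block_layout)
        assert pred2.scores[0, 0] == pytest.approx(pred.scores[0, 0] + 0.05)


class TestLimits:
    def test_scores_vanish_with_alpha(self, rng):
        m = random_symmetric_bipartite(rng, 4, 3)
        c = L.solve_weights(m, L.ModelConfig(alpha=1e-12))
        s = L.score_matrix(m, c)
        assert (np.linalg.norm(s.values, "fro")
                <= 1e-8 * np.linalg.norm(m.values, "fro"))

    def test_scores_approach_input_for_large_alpha(self, rng):
        m = random_symmetric_bipartite(rng, 4, 3)
        assert np.linalg.matrix_rank(m.values) == 7  # full rank required
        c = L.solve_weights(m, L.ModelConfig(alpha=1e6))
        s = L.score_matrix(m, c)
        rel = (np.linalg.norm(s.values - m.values, "fro")
               / np.linalg.norm(m.values, "fro"))
        assert rel <= 1e-4


class TestEndToEnd:
    def test_predict_matches_composition(self, rng):
        m = random_symmetric_bipartite(rng, 3, 2)
        lsm = L.SimilarityMatrix([f"l{i}" for i in range(3)], m.values[:3, :3])
        msm = L.SimilarityMatrix([f"m{i}" for i in range(2)], m.values[3:, 3:])
        lmn = L.InteractionMatrix(lsm.entity_ids, msm.entity_ids,
                                  m.values[:3, 3:].astype(int))
        cfg = L.ModelConfig(alpha=0.018)
        pred = L.predict(lsm, msm, lmn, cfg)
        manual = L.extract_predictions(
            L.score_matrix(m, L.solve_weights(m, cfg)), m.block_layout)
        assert np.allclose(pred.scores, manual.scores, atol=1e-12)

    def test_lnc_permutation_permutes_prediction_rows(self, rng):
        ln, mn = 5, 3
        m = random_symmetric_bipartite(rng, ln, mn)
        lsm_v, msm_v = m.values[:ln, :ln], m.values[ln:, ln:]
        lmn_v = m.values[:ln, ln:].astype(int)
        lids = [f"l{i}" for i in range(ln)]
        mids = [f"m{i}" for i in range(mn)]
        cfg = L.ModelConfig(alpha=0.02)
        base = L.predict(L.SimilarityMatrix(lids, lsm_v),
                         L.SimilarityMatrix(mids, msm_v),
                         L.InteractionMatrix(lids, mids, lmn_v), cfg)
        perm = [4, 2, 0, 1, 3]
        permuted = L.predict(
            L.SimilarityMatrix([lids[i] for i in perm],
                               lsm_v[np.ix_(perm, perm)]),
            L.SimilarityMatrix(mids, msm_v),
            L.InteractionMatrix([lids[i] for i in perm], mids, lmn_v[perm]),
            cfg)
        assert np.allclose(permuted.scores, base.scores[perm], atol=1e-10)

    def test_single_layer_equals_identity_similarities(self, rng):
        lids = [f"l{i}" for i in range(4)]
        mids = [f"m{i}" for i in range(3)]
        lmn = L.InteractionMatrix(lids, mids,
                                  (rng.random((4, 3)) < 0.5).astype(int))
        a = L.predict_single_layer(lmn)
        b = L.predict(L.SimilarityMatrix(lids, np.eye(4)),
                      L.SimilarityMatrix(mids, np.eye(3)), lmn)
        assert np.allclose(a.scores, b.scores, atol=1e-14)

    def test_single_pair_closed_form(self):
        # M = all-ones 2x2: M'M has eigenvalues {4, 0}; with alpha = 1 the
        # score on the all-ones eigenvector is 4 * (4/5) / 2... worked out,
        # every entry of S equals 0.8.
        lmn = L.InteractionMatrix(["l1"], ["m1"], [[1]])
        pred = L.predict_single_layer(lmn, L.ModelConfig(alpha=1.0))
        assert pred.scores[0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            L.ModelConfig(alpha=0)

    def test_results_summary_and_table(self, rng):
        lids = [f"l{i}" for i in range(4)]
        mids = [f"m{i}" for i in range(3)]
        lmn = L.InteractionMatrix(
            lids, mids, (rng.random((4, 3)) < 0.5).astype(int))
        res = L.LinearNeighborModel(lmn).fit()
        table = res.prediction_table()
        assert len(table) == 12
        assert (table["score"].diff().dropna() <= 1e-15).all()
        assert table["known_flag"].sum() == lmn.n_positives
        text = res.summary()
        assert "alpha" in text and "novel" in text
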