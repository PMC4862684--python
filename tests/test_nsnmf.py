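"""nsNMF: smoothing-matrix algebra, KL monotonicity, parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from clonemut.nsnmf import (
    cosine_similarity,
    explained_variance,
    hungarian_match,
    match_reference,
    nsnmf_decompose,
    sample_contributions,
    select_rank,
    smoothing_matrix,
)


def plain_kl_nmf(V, rank, max_iter, tol, seed):
    """Independent textbook Lee-Seung KL-NMF (no smoothing), same init policy."""
    rng = np.random.default_rng(seed)
    V = np.where(V == 0, 1e-9, np.asarray(V, dtype=float))
    W = rng.uniform(0, 1, size=(V.shape[0], rank))
    H = rng.uniform(0, 1, size=(rank, V.shape[1]))
    prev = np.inf
    for it in range(1, max_iter + 1):
        R = np.maximum(W @ H, 1e-12)
        H *= (W.T @ (V / R)) / np.maximum(W.sum(axis=0)[:, None], 1e-12)
        R = np.maximum(W @ H, 1e-12)
        W *= ((V / R) @ H.T) / np.maximum(H.sum(axis=1)[None, :], 1e-12)
        R = np.maximum(W @ H, 1e-12)
        mask = V > 0
        obj = np.sum(V[mask] * np.log(V[mask] / R[mask])) - V.sum() + R.sum()
        if prev - obj <= tol * max(abs(prev), 1.0) and it > 1:
            break
        prev = obj
    return W, H


def planted_signatures(rng, n_channels=48, rank=3):
    """Signatures with distinct supports (disjoint dominant channel blocks)."""
    W = np.full((n_channels, rank), 0.001)
    block = n_channels // rank
    for k in range(rank):
        W[k * block:(k + 1) * block, k] = rng.uniform(0.5, 1.5, size=block)
    return W / W.sum(axis=0)


def planted_V(rng, exposures, total_per_sample=3000, n_channels=48):
    """Poisson-noised counts from planted signatures and exposures."""
    W = planted_signatures(rng, n_channels, exposures.shape[0])
    lam = W @ (exposures * total_per_sample)
    return W, rng.poisson(lam).astype(float)


class TestSmoothingMatrix:
    def test_theta_zero_is_identity(self):
        assert np.allclose(smoothing_matrix(4, 0.0), np.eye(4))

    def test_doubly_stochastic(self):
        for theta in (0.0, 0.3, 0.5, 1.0):
            S = smoothing_matrix(5, theta)
            assert np.allclose(S.sum(axis=0), 1.0)
            assert np.allclose(S.sum(axis=1), 1.0)

    def test_theta_out_of_range(self):
        with pytest.raises(ValueError):
            smoothing_matrix(3, 1.5)


class TestDecompose:
    def test_theta_zero_equals_plain_kl_nmf(self, rng):
        V = rng.poisson(20, size=(12, 5)).astype(float)
        model = nsnmf_decompose(V, rank=2, theta=0.0, restarts=1,
                                max_iter=200, tol=1e-8, seed=5)
        W_ref, H_ref = plain_kl_nmf(V, 2, 200, 1e-8, seed=5)
        # same normalization + exposure ordering as the model applies
        colsum = W_ref.sum(axis=0)
        W_ref, H_ref = W_ref / colsum, H_ref * colsum[:, None]
        order = np.argsort(-H_ref.sum(axis=1), kind="stable")
        assert np.allclose(model.W.to_numpy(), W_ref[:, order], atol=1e-10)
        assert np.allclose(model.H.to_numpy(), H_ref[order, :], atol=1e-8)

    def test_exact_rank_one_recovered(self, rng):
        w = rng.uniform(0.1, 1.0, size=10)
        h = rng.uniform(1.0, 5.0, size=4)
        V = np.outer(w, h)
        model = nsnmf_decompose(V, rank=1, theta=0.0, restarts=2,
                                max_iter=500, seed=0)
        assert explained_variance(model) >= 0.999

    def test_objective_monotone_nonincreasing(self, rng):
        V = rng.poisson(30, size=(20, 6)).astype(float)
        model = nsnmf_decompose(V, rank=3, theta=0.5, restarts=1, seed=2)
        trace = model.objective_trace
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(np.abs(trace[:-1]), 1))

    def test_seed_determinism(self, rng):
        V = rng.poisson(10, size=(10, 4)).astype(float)
        m1 = nsnmf_decompose(V, rank=2, theta=0.5, restarts=3, seed=7)
        m2 = nsnmf_decompose(V, rank=2, theta=0.5, restarts=3, seed=7)
        assert m1.W.equals(m2.W) and m1.H.equals(m2.H)

    def test_scale_invariance(self, rng):
        V = rng.poisson(50, size=(15, 5)).astype(float) + 1.0
        m1 = nsnmf_decompose(V, rank=2, theta=0.5, restarts=2, seed=3,
                             max_iter=300, tol=0.0)
        m2 = nsnmf_decompose(7.0 * V, rank=2, theta=0.5, restarts=2, seed=3,
                             max_iter=300, tol=0.0)
        assert np.allclose(m1.W.to_numpy(), m2.W.to_numpy(), atol=1e-8)
        assert np.allclose(7.0 * m1.H.to_numpy(), m2.H.to_numpy(), rtol=1e-6)

    def test_w_columns_sum_to_one(self, rng):
        V = rng.poisson(10, size=(10, 4)).astype(float)
        model = nsnmf_decompose(V, rank=3, theta=0.5, restarts=2, seed=1)
        assert np.allclose(model.W.sum(axis=0), 1.0, atol=1e-9)
        assert (model.W.to_numpy() >= 0).all() and (model.H.to_numpy() >= 0).all()

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            nsnmf_decompose(np.array([[1.0, -1.0], [2.0, 3.0]]), rank=1)
        with pytest.raises(ValueError, match="rank"):
            nsnmf_decompose(np.ones((3, 3)), rank=5)

    def test_planted_recovery(self, rng):
        """3 planted signatures, Poisson noise: cosine >= 0.95 each."""
        exposures = np.array([
            [0.75, 0.75, 0.75, 0.05, 0.05, 0.05],
            [0.15, 0.10, 0.20, 0.70, 0.25, 0.40],
            [0.10, 0.15, 0.05, 0.25, 0.70, 0.55],
        ])
        W_true, V = planted_V(rng, exposures)
        model = nsnmf_decompose(V, rank=3, theta=0.5, restarts=10, seed=13)
        _, cos = hungarian_match(model.W.to_numpy(), W_true)
        assert (cos >= 0.95).all()


class TestExplainedVariance:
    def test_perfect_reconstruction_is_one(self, rng):
        w = rng.uniform(0.5, 1, 6)
        V = np.outer(w, [1, 2, 3.0])
        model = nsnmf_decompose(V, rank=1, theta=0.0, restarts=2,
                                max_iter=2000, seed=0)
        assert explained_variance(model) == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_value(self):
        # V=[[4,0],[0,9]], approximation [[4,0],[0,0]]: 1 - 81/97
        V = np.array([[4.0, 0.0], [0.0, 9.0]])
        R = np.array([[4.0, 0.0], [0.0, 0.0]])
        evar = 1 - np.sum((V - R) ** 2) / np.sum(V**2)
        assert evar == pytest.approx(1 - 81 / 97)
        assert evar == pytest.approx(0.16494845)

    def test_zero_reconstruction_is_zero(self):
        V = np.array([[4.0, 0.0], [0.0, 9.0]])
        model = nsnmf_decompose(V, rank=1, theta=0.0, restarts=1,
                                max_iter=1, seed=0)
        # overwrite with an all-zero fit to probe the formula directly
        model.H.iloc[:, :] = 0.0
        assert explained_variance(model, V) == pytest.approx(0.0)

    def test_all_zero_v_undefined(self, rng):
        V = rng.poisson(10, size=(4, 3)).astype(float)
        model = nsnmf_decompose(V, rank=1, theta=0.0, restarts=1, seed=0)
        with pytest.raises(ValueError, match="all-zero"):
            explained_variance(model, np.zeros((4, 3)))


class TestSampleContributions:
    def test_rank_one_all_ones(self, rng):
        V = rng.poisson(10, size=(8, 3)).astype(float)
        model = nsnmf_decompose(V, rank=1, theta=0.5, restarts=1, seed=0)
        assert np.allclose(sample_contributions(model).to_numpy(), 1.0)

    def test_columns_sum_to_one(self, rng):
        V = rng.poisson(10, size=(8, 4)).astype(float)
        model = nsnmf_decompose(V, rank=2, theta=0.5, restarts=2, seed=0)
        assert np.allclose(sample_contributions(model).sum(axis=0), 1.0, atol=1e-9)

    def test_sample_permutation_equivariance(self, rng):
        """Permuting a model's sample columns permutes contributions identically."""
        V = pd.DataFrame(rng.poisson(20, size=(10, 4)).astype(float),
                         columns=list("abcd"))
        perm = ["c", "a", "d", "b"]
        model = nsnmf_decompose(V, rank=2, theta=0.5, restarts=3, seed=4)
        c1 = sample_contributions(model)
        permuted = dataclasses.replace(model, H=model.H[perm])
        assert sample_contributions(permuted).equals(c1[perm])

    def test_smoothed_shares_confined_to_theta_band(self, rng):
        """Smoothed shares live in [theta/q, 1-theta+theta/q] by construction."""
        V = rng.poisson(30, size=(12, 5)).astype(float)
        model = nsnmf_decompose(V, rank=3, theta=0.5, restarts=3, seed=6)
        c = sample_contributions(model).to_numpy()
        assert (c >= 1 / 6 - 1e-9).all() and (c <= 2 / 3 + 1e-9).all()
        # raw exposure shares are unconstrained on the simplex
        raw = sample_contributions(model, smoothed=False).to_numpy()
        assert np.allclose(raw.sum(axis=0), 1.0)

    def test_planted_mixture_contrast_recovered(self, rng):
        """Case samples' dominant-signature share far exceeds the controls'."""
        exposures = np.array([
            [0.62, 0.60, 0.64, 0.02, 0.02, 0.02],
            [0.22, 0.18, 0.26, 0.73, 0.28, 0.43],
            [0.16, 0.22, 0.10, 0.25, 0.70, 0.55],
        ])
        W_true, V = planted_V(rng, exposures)
        model = nsnmf_decompose(V, rank=3, theta=0.5, restarts=10, seed=17)
        match, cos = hungarian_match(model.W.to_numpy(), W_true)
        assert (cos >= 0.95).all()
        contrib = sample_contributions(model).to_numpy()
        k1 = int(np.flatnonzero(match == 0)[0])
        case_share = contrib[k1, :3].mean()
        ctrl_share = contrib[k1, 3:].mean()
        assert case_share > ctrl_share + 0.3
        # within the representable band the share tracks the planted mixing
        assert abs(case_share - 0.62) <= 0.08


class TestSelectRank:
    def test_exact_rank_two_detected(self, rng):
        W = rng.uniform(0.1, 1, size=(12, 2))
        H = rng.uniform(1, 5, size=(2, 6))
        V = W @ H
        diag = select_rank(V, [1, 2, 3], theta=0.0, restarts=3, seed=1)
        assert diag.explained_variance[2] >= 0.999

    def test_evar_nondecreasing_in_rank(self, rng):
        # nested warm starts are exact at theta=0 (S does not change shape)
        V = rng.poisson(25, size=(16, 6)).astype(float)
        diag = select_rank(V, [1, 2, 3, 4], theta=0.0, restarts=3, seed=2)
        evars = [diag.explained_variance[r] for r in diag.ranks]
        assert all(b >= a - 1e-6 for a, b in zip(evars, evars[1:]))

    def test_three_signature_simulation_selects_three(self, rng):
        """Rank selection on data generated by the fitted model class."""
        exposures = np.array([
            [0.75, 0.75, 0.75, 0.05, 0.05, 0.05],
            [0.15, 0.10, 0.20, 0.70, 0.25, 0.40],
            [0.10, 0.15, 0.05, 0.25, 0.70, 0.55],
        ])
        G = planted_signatures(rng)
        W_smooth = G @ smoothing_matrix(3, 0.5)  # representable at theta=0.5
        V = rng.poisson(W_smooth @ (exposures * 20_000)).astype(float)
        diag = select_rank(V, [1, 2, 3, 4], theta=0.5, restarts=4, seed=3)
        assert diag.chosen_rank == 3
        assert diag.explained_variance[3] >= 0.99


class TestMatchReference:
    def _frame(self, cols, index=None):
        index = index or [f"ch{i}" for i in range(len(next(iter(cols.values()))))]
        return pd.DataFrame(cols, index=index)

    def test_identical_vectors_cosine_one(self):
        W = self._frame({"ES1": [0.5, 0.5, 0.0, 0.0]})
        ref = self._frame({"SBS_X": [0.5, 0.5, 0.0, 0.0]})
        out = match_reference(W, ref)
        assert out.loc["ES1", "best_match"] == "SBS_X"
        assert out.loc["ES1", "best_cosine"] == pytest.approx(1.0)

    def test_disjoint_support_cosine_zero(self):
        W = self._frame({"ES1": [1.0, 0.0, 0.0, 0.0]})
        ref = self._frame({"SBS_X": [0.0, 1.0, 0.0, 0.0]})
        assert match_reference(W, ref).loc["ES1", "best_cosine"] == 0.0

    def test_hand_computed_cosine(self):
        W = self._frame({"ES1": [0.5, 0.5, 0.0, 0.0]})
        ref = self._frame({"SBS_X": [1.0, 0.0, 0.0, 0.0]})
        assert match_reference(W, ref).loc["ES1", "best_cosine"] == \
            pytest.approx(0.7071, abs=1e-4)

    def test_channel_mismatch_raises(self):
        W = self._frame({"ES1": [1.0, 0.0]}, index=["a", "b"])
        ref = self._frame({"X": [1.0, 0.0]}, index=["a", "c"])
        with pytest.raises(ValueError, match="channel"):
            match_reference(W, ref)

    def test_cosine_similarity_zero_vector(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0
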