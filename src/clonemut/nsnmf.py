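"""Mutational-signature extraction by nonsmooth non-negative matrix factorization.

Model: V ~= W S(theta) H with V the channels x samples count matrix, W the
channels x rank signature matrix, H the rank x samples exposure matrix and

    S(theta) = (1 - theta) I + (theta / q) * 11'   (q = rank)

a doubly stochastic smoothing matrix. theta = 0 recovers plain KL-NMF;
theta > 0 smooths whichever factor the other one's update sees, which in
turn drives sparseness into both W and H (the nonsmooth trick). The fit
minimizes the generalized Kullback-Leibler divergence

    D(V || WSH) = sum_ij V_ij log(V_ij / (WSH)_ij) - V_ij + (WSH)_ij

by alternating multiplicative updates: the H update uses the smoothed basis
W S, the W update uses the smoothed coefficients S H. Each half-update is a
standard KL-NMF update with the other factor frozen, so the objective is
non-increasing at every step.

After convergence W columns are normalized to sum to one (signatures are
probability vectors over channels) with the compensating scale moved into
the rows of H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

EPS = 1e-12
PSEUDOCOUNT = 1e-9  # added to zeros of V for KL stability


@dataclass
class SignatureModel:
    """Fitted nsNMF factorization V ~= W S H."""

    W: pd.DataFrame            # channels x rank, columns sum to 1
    H: pd.DataFrame            # rank x samples, non-negative
    theta: float
    rank: int
    objective: float           # final generalized KL divergence
    objective_trace: np.ndarray
    n_iter: int
    seed: int | None
    converged: bool
    V: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def S(self) -> np.ndarray:
        return smoothing_matrix(self.rank, self.theta)

    def reconstruction(self) -> pd.DataFrame:
        R = self.W.to_numpy() @ self.S @ self.H.to_numpy()
        return pd.DataFrame(R, index=self.W.index, columns=self.H.columns)


def smoothing_matrix(rank: int, theta: float) -> np.ndarray:
    """S = (1-theta) I + (theta/q) 11'; row sums are 1 for every theta."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    return (1 - theta) * np.eye(rank) + (theta / rank) * np.ones((rank, rank))


def _kl_divergence(V: np.ndarray, R: np.ndarray) -> float:
    R = np.maximum(R, EPS)
    mask = V > 0
    d = np.sum(V[mask] * np.log(V[mask] / R[mask])) - V.sum() + R.sum()
    return float(d)


def _as_frame(V) -> pd.DataFrame:
    if isinstance(V, pd.DataFrame):
        return V
    V = np.asarray(V, dtype=float)
    return pd.DataFrame(V,
                        index=[f"ch{i}" for i in range(V.shape[0])],
                        columns=[f"s{j}" for j in range(V.shape[1])])


def _fit_once(V, rank, theta, max_iter, tol, rng, init=None):
    n, m = V.shape
    S = smoothing_matrix(rank, theta)
    if init is None:
        W = rng.uniform(0, 1, size=(n, rank))
        H = rng.uniform(0, 1, size=(rank, m))
    else:
        W, H = (x.copy() for x in init)
    trace = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # H update against the smoothed basis B = W S
        B = W @ S
        R = np.maximum(B @ H, EPS)
        H *= (B.T @ (V / R)) / np.maximum(B.sum(axis=0)[:, None], EPS)
        # W update against the smoothed coefficients C = S H
        C = S @ H
        R = np.maximum(W @ C, EPS)
        W *= ((V / R) @ C.T) / np.maximum(C.sum(axis=1)[None, :], EPS)
        obj = _kl_divergence(V, W @ S @ H)
        trace.append(obj)
        if prev - obj <= tol * max(abs(prev), 1.0) and it > 1:
            converged = True
            break
        prev = obj
    return W, H, np.array(trace), it, converged


def nsnmf_decompose(
    V,
    rank: int,
    theta: float = 0.5,
    restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> SignatureModel:
    """Fit nsNMF by multiplicative KL updates; return the best restart.

    Each restart initializes W and H uniform(0,1) from a seeded generator;
    ``warm_start`` optionally supplies one extra deterministic
    initialization (used for nested rank selection). Zeros of V receive a
    1e-9 pseudocount. The returned W is column-normalized with the scale
    moved into H; signatures are ordered by total exposure, descending.
    """
    Vdf = _as_frame(V)
    Varr = Vdf.to_numpy(dtype=float)
    if np.any(Varr < 0):
        raise ValueError("V must be non-negative")
    if not 1 <= rank <= min(Varr.shape):
        raise ValueError(f"rank must lie in [1, {min(Varr.shape)}]")
    if np.any(Varr.sum(axis=0) == 0):
        raise ValueError("V has an all-zero sample column")
    Varr = np.where(Varr == 0, PSEUDOCOUNT, Varr)

    rng = np.random.default_rng(seed)
    inits = [None] * restarts
    if warm_start is not None:
        inits = [warm_start] + inits
    best = None
    for init in inits:
        W, H, trace, n_iter, conv = _fit_once(Varr, rank, theta, max_iter, tol, rng, init)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, n_iter, conv)
    W, H, trace, n_iter, conv = best

    # presentation: signatures as probability vectors over channels
    colsum = np.maximum(W.sum(axis=0), EPS)
    W = W / colsum
    H = H * colsum[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order, :]

    sig_names = [f"ES{i+1}" for i in range(rank)]
    return SignatureModel(
        W=pd.DataFrame(W, index=Vdf.index, columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=Vdf.columns),
        theta=theta, rank=rank,
        objective=float(trace[-1]), objective_trace=trace,
        n_iter=n_iter, seed=seed, converged=conv, V=Vdf,
    )


def explained_variance(model: SignatureModel, V=None) -> float:
    """Frobenius explained variance: 1 - ||V - WSH||_F^2 / ||V||_F^2."""
    Vdf = _as_frame(V) if V is not None else model.V
    if Vdf is None:
        raise ValueError("no V available; pass it explicitly")
    Varr = Vdf.to_numpy(dtype=float)
    denom = float(np.sum(Varr**2))
    if denom == 0:
        raise ValueError("explained variance undefined for an all-zero V")
    R = model.W.to_numpy() @ model.S @ model.H.to_numpy()
    return 1.0 - float(np.sum((Varr - R) ** 2)) / denom


def sample_contributions(model: SignatureModel, smoothed: bool = True) -> pd.DataFrame:
    """Relative signature contribution per sample (columns sum to 1).

    By default exposures are smoothed (S H) before normalization, so the
    proportions reflect the effective mixture each sample's reconstruction
    uses. Note the smoothing confines every share to
    ``[theta/q, 1-theta+theta/q]``; ``smoothed=False`` returns the raw
    (sparse) exposure shares instead, which span the full simplex.
    """
    E = (model.S @ model.H.to_numpy()) if smoothed else model.H.to_numpy()
    colsum = E.sum(axis=0)
    if np.any(colsum <= 0):
        bad = [c for c, s in zip(model.H.columns, colsum) if s <= 0]
        raise ValueError(f"zero total exposure for samples: {bad}")
    return pd.DataFrame(E / colsum, index=model.H.index, columns=model.H.columns)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def hungarian_match(W: np.ndarray, W_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column pairing maximizing total cosine similarity.

    Returns (ref_index_per_column_of_W, cosine_per_column).
    """
    k, r = W.shape[1], W_ref.shape[1]
    C = np.zeros((k, r))
    for i in range(k):
        for j in range(r):
            C[i, j] = cosine_similarity(W[:, i], W_ref[:, j])
    rows, cols = linear_sum_assignment(-C)
    match = np.full(k, -1)
    cos = np.zeros(k)
    for i, j in zip(rows, cols):
        match[i] = j
        cos[i] = C[i, j]
    return match, cos


@dataclass
class FitDiagnostics:
    """Rank-selection diagnostics."""

    ranks: list[int]
    explained_variance: dict[int, float]
    cosine_stability: dict[int, float]
    chosen_rank: int
    models: dict[int, SignatureModel] = field(default_factory=dict, repr=False)


def select_rank(
    V,
    candidate_ranks,
    theta: float = 0.5,
    restarts: int = 10,
    seed: int | None = None,
    evar_threshold: float = 0.99,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FitDiagnostics:
    """Fit each candidate rank; pick the smallest whose explained variance
    exceeds ``evar_threshold`` (largest candidate if none does).

    Rank k+1 gets one warm-started restart built from the rank-k best fit
    (padded with a random column/row), so best-of-restarts explained
    variance is non-decreasing in rank. Cosine-stability per rank is the
    mean Hungarian-matched cosine between each restart's signatures and the
    best restart's.
    """
    ranks = sorted(candidate_ranks)
    Vdf = _as_frame(V)
    Varr = np.where(Vdf.to_numpy(dtype=float) == 0, PSEUDOCOUNT, Vdf.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    evars: dict[int, float] = {}
    stability: dict[int, float] = {}
    models: dict[int, SignatureModel] = {}
    prev_fit = None
    for rank in ranks:
        warm = None
        if prev_fit is not None and prev_fit[0].shape[1] == rank - 1:
            # nested warm start: embed the previous fit with a small-scale
            # extra column/row so the starting product is barely perturbed
            # (exactly nested at theta=0; approximate for theta>0 because
            # S depends on the rank)
            Wp, Hp = prev_fit
            eps_w = 1e-3 * max(Wp.mean(), EPS)
            eps_h = 1e-3 * max(Hp.mean(), EPS)
            warm = (
                np.hstack([Wp, eps_w * rng.uniform(0.5, 1, size=(Wp.shape[0], 1))]),
                np.vstack([Hp, eps_h * rng.uniform(0.5, 1, size=(1, Hp.shape[1]))]),
            )
        # keep all restart fits to score stability
        fits = []
        if warm is not None:
            fits.append(_fit_once(Varr, rank, theta, max_iter, tol, rng, warm))
        for _ in range(restarts):
            fits.append(_fit_once(Varr, rank, theta, max_iter, tol, rng, None))
        fits.sort(key=lambda f: f[2][-1])
        Wb, Hb = fits[0][0], fits[0][1]
        prev_fit = (Wb.copy(), Hb.copy())

        cosines = []
        for W, _, _, _, _ in fits[1:]:
            _, cos = hungarian_match(W, Wb)
            cosines.append(float(np.mean(cos)))
        stability[rank] = float(np.mean(cosines)) if cosines else 1.0

        model = _package(Vdf, Wb, Hb, fits[0], theta, rank, seed)
        models[rank] = model
        evars[rank] = explained_variance(model)

    chosen = next((r for r in ranks if evars[r] >= evar_threshold), ranks[-1])
    return FitDiagnostics(ranks=ranks, explained_variance=evars,
                          cosine_stability=stability, chosen_rank=chosen,
                          models=models)


def _package(Vdf, W, H, fit, theta, rank, seed) -> SignatureModel:
    _, _, trace, n_iter, conv = fit
    colsum = np.maximum(W.sum(axis=0), EPS)
    Wn, Hn = W / colsum, H * colsum[:, None]
    order = np.argsort(-Hn.sum(axis=1), kind="stable")
    Wn, Hn = Wn[:, order], Hn[order, :]
    names = [f"ES{i+1}" for i in range(rank)]
    return SignatureModel(
        W=pd.DataFrame(Wn, index=Vdf.index, columns=names),
        H=pd.DataFrame(Hn, index=names, columns=Vdf.columns),
        theta=theta, rank=rank, objective=float(trace[-1]),
        objective_trace=trace, n_iter=n_iter, seed=seed, converged=conv, V=Vdf,
    )


def match_reference(W: pd.DataFrame, reference_signatures: pd.DataFrame) -> pd.DataFrame:
    """Cosine-match extracted signatures against a reference catalog.

    Both matrices must share the channel convention (identical index).
    Returns one row per extracted signature: best-matching reference
    signature and the cosine of every reference column.
    """
    if list(W.index) != list(reference_signatures.index):
        raise ValueError("channel labels of W and the reference do not match")
    rows = []
    for sig in W.columns:
        cos = {ref: cosine_similarity(W[sig].to_numpy(),
                                      reference_signatures[ref].to_numpy())
               for ref in reference_signatures.columns}
        best = max(cos, key=cos.get)
        rows.append({"signature": sig, "best_match": best,
                     "best_cosine": cos[best], **{f"cos_{k}": v for k, v in cos.items()}})
    return pd.DataFrame(rows).set_index("signature")
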