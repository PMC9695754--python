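"""Network-constrained sparse common component analysis (NetSCCA).

Given the q regulatory-effect matrices R_l (n x p), the *common components*
are the orthonormal directions A (p x K) maximizing tr(A^T G A) with
G = sum_l R_l^T R_l — the shared principal subspace of the stack of
networks.  With a single matrix this is exactly standard PCA.

NetSCCA makes the loadings sparse and network-aware.  With Q the symmetric
PSD square root of G (Q^T Q = G), it alternates:

* a theta step: for each component, an elastic lasso with a graph-fusion
  penalty,

      min_theta ||z_k - Q theta||^2 + lambda1 ||theta||_1
                + lambda2 sum_{j<s} (theta_j - theta_s)^2 W_js,

  where z_k = Q a_k and W is the Jaccard similarity between regulator genes'
  neighbourhoods in the sample-specific networks.  The fusion term equals
  lambda2 theta^T L theta with L the weighted graph Laplacian of W, so the
  problem is solved as a quadratic-plus-L1 program by coordinate descent.
* an A step: the Procrustes update A = U V^T from the thin SVD of
  Q^T Q Theta.

The final loadings are the columns of Theta normalized to unit length.
Genes sharing many network neighbours (large W_js) are pushed toward equal
loadings, which fails when truly coupled genes carry opposite signs — a
known limitation of unsigned network fusion penalties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator

from .effects import RegulatoryEffectSet
from .exceptions import InvalidParameterError
from .network import SampleSpecificNetwork

__all__ = [
    "GeneSimilarity",
    "GramFactor",
    "CommonComponentModel",
    "jaccard_similarity",
    "neighbor_sets_from_network",
    "gram_matrix",
    "common_components_unpenalized",
    "fusion_laplacian",
    "theta_step",
    "a_step",
    "netscca_fit",
    "NetSCCA",
]


@dataclass
class GeneSimilarity:
    """Jaccard similarity W between regulator genes' network neighbourhoods."""

    W: NDArray[np.float64]
    neighbor_sets: list[set]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidParameterError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise InvalidParameterError("W must be symmetric")
        if W.min() < -1e-12 or W.max() > 1 + 1e-12:
            raise InvalidParameterError("W entries must lie in [0, 1]")
        self.W = W


def jaccard_similarity(neighbor_sets: Sequence[set]) -> GeneSimilarity:
    """W_js = |N_j n N_s| / |N_j u N_s|, with 0 for two empty sets.

    ``neighbor_sets[j]`` is the set of genes adjacent to regulator j via an
    edge in at least one sample's network.
    """
    sets = [set(s) for s in neighbor_sets]
    p = len(sets)
    W = np.zeros((p, p))
    for j in range(p):
        for s in range(j, p):
            union = sets[j] | sets[s]
            if union:
                W[j, s] = W[s, j] = len(sets[j] & sets[s]) / len(union)
    return GeneSimilarity(W, sets)


def neighbor_sets_from_network(network: SampleSpecificNetwork) -> list[set]:
    """Per-regulator sets of targets connected in at least one sample."""
    any_edge = np.any(network.coefficients != 0, axis=0)  # (p, q)
    return [
        {network.target_ids[l] for l in np.nonzero(any_edge[j])[0]}
        for j in range(any_edge.shape[0])
    ]


@dataclass
class GramFactor:
    """Aggregate Gram matrix G = sum_l R_l^T R_l and a square root Q (Q^T Q = G)."""

    G: NDArray[np.float64]
    Q: NDArray[np.float64]


def gram_matrix(effects: RegulatoryEffectSet | Sequence[ArrayLike]) -> GramFactor:
    """G = sum_l R_l^T R_l with its symmetric PSD square root.

    The square root is computed by eigendecomposition with any (numerically)
    negative eigenvalues clipped at zero; every Q with Q^T Q = G yields the
    same G-dependent quantities downstream.
    """
    mats = effects.matrices if isinstance(effects, RegulatoryEffectSet) else list(effects)
    if len(mats) < 1:
        raise InvalidParameterError("at least one effect matrix is required")
    p = np.asarray(mats[0]).shape[1]
    G = np.zeros((p, p))
    for R in mats:
        R = np.asarray(R, dtype=float)
        if not np.all(np.isfinite(R)):
            raise InvalidParameterError("non-finite entries in effect matrix")
        G += R.T @ R
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    evals = np.clip(evals, 0.0, None)
    Q = (evecs * np.sqrt(evals)) @ evecs.T
    return GramFactor(G, Q)


def _fix_signs(A: NDArray) -> NDArray:
    """Deterministic column signs: largest-magnitude entry positive."""
    A = A.copy()
    for k in range(A.shape[1]):
        col = A[:, k]
        if np.any(col != 0):
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                A[:, k] = -col
    return A


def common_components_unpenalized(G: ArrayLike, K: int) -> NDArray[np.float64]:
    """Top-K eigenvectors of G: the unpenalized common loading matrix.

    The trace objective tr(A^T G A) at the returned A equals the sum of the
    K largest eigenvalues of G.
    """
    G = np.asarray(G, dtype=float)
    p = G.shape[0]
    if not 1 <= K <= p:
        raise InvalidParameterError(f"K must satisfy 1 <= K <= p={p}")
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:K]
    return _fix_signs(evecs[:, order])


def fusion_laplacian(W: ArrayLike | GeneSimilarity) -> NDArray[np.float64]:
    """Graph Laplacian L with sum_{j<s} (t_j - t_s)^2 W_js = t^T L t.

    Diagonal entries of W (self-similarity) do not enter the fusion penalty
    and are ignored.
    """
    W = W.W if isinstance(W, GeneSimilarity) else np.asarray(W, dtype=float)
    Wo = W - np.diag(np.diag(W))
    return np.diag(Wo.sum(axis=1)) - Wo


def theta_step(
    Q: ArrayLike,
    z: ArrayLike,
    W: ArrayLike | GeneSimilarity | None,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    theta_init: ArrayLike | None = None,
) -> NDArray[np.float64]:
    """Solve min_t ||z - Q t||^2 + lambda1 ||t||_1 + lambda2 t^T L t.

    The fusion penalty is rewritten through the Laplacian of W and the
    resulting quadratic + L1 problem is solved by coordinate descent.  At
    lambda1 = 0 the closed-form ridge-Laplacian solution is returned.
    """
    Q = np.asarray(Q, dtype=float)
    z = np.asarray(z, dtype=float)
    p = Q.shape[1]
    if z.shape != (Q.shape[0],):
        raise InvalidParameterError("z must have length matching rows of Q")
    if lambda1 < 0 or lambda2 < 0:
        raise InvalidParameterError("penalties must be nonnegative")
    L = fusion_laplacian(W) if W is not None else np.zeros((p, p))
    M = Q.T @ Q + lambda2 * L
    c = Q.T @ z
    if lambda1 == 0:
        try:
            return np.linalg.solve(M, c)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(M, c, rcond=None)[0]
    theta = (
        np.zeros(p) if theta_init is None else np.asarray(theta_init, float).copy()
    )
    diag = np.diag(M).copy()
    grad_off = M @ theta - diag * theta  # sum_{s != j} M_js t_s
    half_l1 = lambda1 / 2.0
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if diag[j] <= 0:
                continue
            rho = c[j] - grad_off[j]
            new = np.sign(rho) * max(abs(rho) - half_l1, 0.0) / diag[j]
            delta = new - theta[j]
            if delta != 0.0:
                grad_off += M[:, j] * delta
                grad_off[j] -= diag[j] * delta
                theta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return theta


def a_step(Q: ArrayLike, Theta: ArrayLike) -> NDArray[np.float64]:
    """Procrustes update: A = U V^T from the thin SVD of Q^T Q Theta.

    A is orthonormal by construction; if Q^T Q Theta is rank deficient the
    SVD still yields a deterministic orthonormal completion (flagged via the
    ``rank_deficient_`` attribute on the returned array's wrapper callers).
    """
    Q = np.asarray(Q, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    if Theta.ndim == 1:
        Theta = Theta[:, None]
    Mmat = Q.T @ (Q @ Theta)
    U, s, Vt = np.linalg.svd(Mmat, full_matrices=False)
    if s.size and s[-1] <= 1e-12 * max(s[0], 1.0):
        warnings.warn(
            "rank-deficient Q^T Q Theta in the orthonormal update; the "
            "deficient directions are completed deterministically by the SVD",
            RuntimeWarning,
            stacklevel=2,
        )
    return U @ Vt


@dataclass
class CommonComponentModel:
    """Fitted NetSCCA model.

    ``loadings`` are the unit-normalized sparse loading vectors (p x K);
    columns whose raw theta was identically zero are listed in
    ``zero_components`` and left as zero vectors.
    """

    loadings: NDArray[np.float64]  # (p, K), unit columns (or zero)
    Theta: NDArray[np.float64]  # raw surrogate loadings
    A: NDArray[np.float64]  # orthonormal (p, K)
    K: int
    lambda1: float
    lambda2: float
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    zero_components: list[int] = field(default_factory=list)


def _auto_K(G: NDArray, explained: float = 0.8) -> int:
    evals = np.sort(np.linalg.eigvalsh(G))[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(evals) / total
    return int(np.searchsorted(cum, explained) + 1)


def netscca_fit(
    effects: RegulatoryEffectSet | Sequence[ArrayLike] | GramFactor,
    W: ArrayLike | GeneSimilarity | None = None,
    K: int | str = "auto",
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> CommonComponentModel:
    """Alternating estimation of sparse common loadings of the effect stack.

    A is initialized from the unpenalized principal components; the theta
    and A steps alternate until the relative change of the normalized Theta
    falls below ``tol`` or ``max_iter`` is reached (then the model is
    returned with ``converged=False`` and a warning).  ``K="auto"`` picks
    the smallest K whose unpenalized components explain 80% of tr(G).
    """
    gf = effects if isinstance(effects, GramFactor) else gram_matrix(effects)
    G, Q = gf.G, gf.Q
    p = G.shape[0]
    if K == "auto":
        K = _auto_K(G)
    K = int(K)
    if not 1 <= K <= p:
        raise InvalidParameterError(f"K must satisfy 1 <= K <= p={p}")
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")

    A = common_components_unpenalized(G, K)
    trace_G = float(np.trace(G))
    objective: list[float] = []
    prev = None
    converged = False
    it = 0
    Theta = A.copy()
    for it in range(1, max_iter + 1):
        Theta = np.column_stack(
            [
                theta_step(Q, Q @ A[:, k], W, lambda1, lambda2,
                           theta_init=Theta[:, k])
                for k in range(K)
            ]
        )
        A = a_step(Q, Theta)
        objective.append(trace_G - float(np.trace(A.T @ G @ A)))
        # convergence measured on sign-aligned, per-column-normalized Theta
        norms = np.linalg.norm(Theta, axis=0)
        Tn = Theta / np.where(norms > 0, norms, 1.0)
        if prev is not None:
            signs = np.sign(np.einsum("jk,jk->k", Tn, prev))
            signs[signs == 0] = 1.0
            if float(np.max(np.abs(Tn * signs - prev))) < tol:
                converged = True
                prev = Tn
                break
        prev = Tn
    if not converged:
        warnings.warn(
            f"NetSCCA did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    norms = np.linalg.norm(Theta, axis=0)
    zero = [k for k in range(K) if norms[k] == 0]
    loadings = _fix_signs(Theta / np.where(norms > 0, norms, 1.0))
    loadings[:, zero] = 0.0
    return CommonComponentModel(
        loadings, Theta, A, K, float(lambda1), float(lambda2), it, converged,
        objective, zero,
    )


class NetSCCA(BaseEstimator):
    """Sparse common component analysis estimator (scikit-learn style).

    Parameters mirror :func:`netscca_fit`; after ``fit`` the attribute
    ``components_`` holds the unit-norm sparse loadings with shape
    (n_components, p), following the scikit-learn decomposition convention,
    and ``model_`` the full :class:`CommonComponentModel`.
    """

    def __init__(self, n_components: int | str = "auto", lambda1: float = 0.0,
                 lambda2: float = 0.0, tol: float = 1e-4, max_iter: int = 200):
        self.n_components = n_components
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, similarity: ArrayLike | GeneSimilarity | None = None):
        """X: RegulatoryEffectSet, list of R_l matrices, or GramFactor."""
        model = netscca_fit(
            X, W=similarity, K=self.n_components, lambda1=self.lambda1,
            lambda2=self.lambda2, tol=self.tol, max_iter=self.max_iter,
        )
        self.model_ = model
        self.components_ = model.loadings.T
        self.n_iter_ = model.n_iter
        self.converged_ = model.converged
        return self

    def transform(self, R: ArrayLike) -> NDArray[np.float64]:
        """Project an (n, p) effect matrix onto the common loadings."""
        return np.asarray(R, dtype=float) @ self.components_.T
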