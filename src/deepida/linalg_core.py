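"""Covariance construction, whitening, and the alternating eigensystem solver.

All quantities here operate on top-layer network representations
``H_d`` (one ``n x o_d`` matrix per view).  The discriminant/association
objective couples, per view, a between-class scatter term with pairwise
cross-covariance terms between views; after whitening by ``S_td^{-1/2}``
both terms become trace quantities over orthonormal projection matrices
``Gamma_d`` and the stationary points are solutions of a coupled system
of symmetric eigenproblems which we solve by cyclic updates.

Conventions
-----------
* ``mu_k`` is the mean of class ``k`` rows of ``H``; ``mu`` is the
  *unweighted* mean of the class means (not the grand sample mean —
  the two coincide only for balanced classes).
* ``S_b = (1/(n-1)) sum_k n_k (mu_k - mu)(mu_k - mu)^T``.
* ``S_t = (1/(n-1)) (H - 1 mu^T)^T (H - 1 mu^T)`` — total scatter about
  the mean-of-class-means.
* ``S_dj = (1/(n-1)) (H_d - 1 mu_d^T)^T (H_j - 1 mu_j^T)``.
* The mixing weights are ``c1 = rho/D`` (separation) and
  ``c2 = 2(1-rho)/(D(D-1))`` (association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "CovarianceSet",
    "WhitenedSystem",
    "GammaSolution",
    "class_statistics",
    "covariances_from_representations",
    "cross_covariance",
    "inv_sqrt_psd",
    "build_system",
    "solve_gamma",
    "system_objective",
]

DEFAULT_RIDGE_SCALE = 1e-4
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100


@dataclass
class CovarianceSet:
    """Per-view class statistics plus pairwise cross-covariances.

    ``class_means[d]`` is a ``K x o_d`` array (rows ordered by sorted
    class label), ``view_means[d]`` the unweighted mean of class means,
    ``between[d]``/``total[d]`` the ``o_d x o_d`` scatter matrices and
    ``cross[(d, j)]`` the ``o_d x o_j`` cross-covariance.
    """

    class_means: list[np.ndarray]
    view_means: list[np.ndarray]
    between: list[np.ndarray]
    total: list[np.ndarray]
    cross: dict[tuple[int, int], np.ndarray]
    classes: np.ndarray
    class_counts: np.ndarray
    n: int

    @property
    def n_views(self) -> int:
        return len(self.between)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class WhitenedSystem:
    """Whitened separation (``M_d``) and association (``N_dj``) matrices."""

    M: list[np.ndarray]
    N: dict[tuple[int, int], np.ndarray]
    c1: float
    c2: float
    l: int
    rho: float

    @property
    def n_views(self) -> int:
        return len(self.M)


@dataclass
class GammaSolution:
    """Solution of the coupled eigensystem: per-view orthonormal ``Gamma_d``."""

    gammas: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    objective_value: float
    iterations_used: int
    converged: bool
    all_positive: bool = True
    objective_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _class_info(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return classes, inverse, counts


def class_statistics(H: np.ndarray, labels: np.ndarray) -> CovarianceSet:
    """Compute one view's class means and between/total covariances.

    Returns a :class:`CovarianceSet` with single-view entries; use
    :func:`cross_covariance` / :func:`merge_covariances` (or the
    convenience :func:`covariances_from_representations`) for the
    multi-view structure.
    """
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels)
    n = H.shape[0]
    if n <= 1:
        raise ValueError("degenerate sample size: need n > 1")
    if labels.shape[0] != n:
        raise ValueError("labels length does not match number of rows")
    if np.isnan(H).any():
        raise ValueError("H has missing values")
    classes, inverse, counts = _class_info(labels)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least two classes")
    if (counts == 0).any():
        raise ValueError("empty class")

    mu_k = np.stack([H[inverse == k].mean(axis=0) for k in range(K)])
    mu = mu_k.mean(axis=0)

    diff = mu_k - mu  # K x o
    S_b = (diff.T * counts) @ diff / (n - 1)
    C = H - mu
    S_t = C.T @ C / (n - 1)
    S_b = 0.5 * (S_b + S_b.T)
    S_t = 0.5 * (S_t + S_t.T)
    return CovarianceSet(
        class_means=[mu_k],
        view_means=[mu],
        between=[S_b],
        total=[S_t],
        cross={},
        classes=classes,
        class_counts=counts,
        n=n,
    )


def cross_covariance(Hd: np.ndarray, Hj: np.ndarray,
                     mu_d: np.ndarray, mu_j: np.ndarray) -> np.ndarray:
    """``(1/(n-1)) (H_d - 1 mu_d^T)^T (H_j - 1 mu_j^T)``."""
    Hd = np.asarray(Hd, dtype=float)
    Hj = np.asarray(Hj, dtype=float)
    if Hd.shape[0] != Hj.shape[0]:
        raise ValueError("views are not row-aligned")
    n = Hd.shape[0]
    return (Hd - mu_d).T @ (Hj - mu_j) / (n - 1)


def covariances_from_representations(Hs: list[np.ndarray],
                                     labels: np.ndarray) -> CovarianceSet:
    """Full multi-view :class:`CovarianceSet` from top-layer representations."""
    per_view = [class_statistics(H, labels) for H in Hs]
    covs = CovarianceSet(
        class_means=[c.class_means[0] for c in per_view],
        view_means=[c.view_means[0] for c in per_view],
        between=[c.between[0] for c in per_view],
        total=[c.total[0] for c in per_view],
        cross={},
        classes=per_view[0].classes,
        class_counts=per_view[0].class_counts,
        n=per_view[0].n,
    )
    D = len(Hs)
    for d in range(D):
        for j in range(D):
            if d == j:
                continue
            if (j, d) in covs.cross:
                covs.cross[(d, j)] = covs.cross[(j, d)].T
            else:
                covs.cross[(d, j)] = cross_covariance(
                    Hs[d], Hs[j], covs.view_means[d], covs.view_means[j]
                )
    return covs


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def inv_sqrt_psd(S: np.ndarray, ridge: float = 0.0,
                 sym_tol: float = 1e-8) -> np.ndarray:
    """Symmetric ``R`` with ``R (S + ridge*I) R = I``.

    Computed through an eigendecomposition of the symmetrized input;
    fails if ``S + ridge*I`` is not positive definite.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("matrix must be square")
    asym = np.abs(S - S.T).max() if S.size else 0.0
    scale = max(1.0, np.abs(S).max()) if S.size else 1.0
    if asym > sym_tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    w, U = scipy.linalg.eigh(0.5 * (S + S.T))
    w = w + ridge
    if (w <= 0).any():
        raise ValueError("not positive definite")
    return (U * (1.0 / np.sqrt(w))) @ U.T


def build_system(covs: CovarianceSet, rho: float, l: int,
                 ridge_scale: float = DEFAULT_RIDGE_SCALE) -> WhitenedSystem:
    """Whiten a :class:`CovarianceSet` into ``M_d`` and ``N_dj`` matrices.

    A relative ridge ``ridge_scale * mean(diag(S_td))`` is added before
    inverting each total covariance, guarding against near-singular
    finite-sample top-layer scatter.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    D = covs.n_views
    if D < 2:
        raise ValueError("need at least two views")
    dims = [S.shape[0] for S in covs.total]
    l_max = min([covs.n_classes - 1] + dims)
    if l > l_max:
        raise ValueError(f"l={l} exceeds bound min(K-1, o_1..o_D)={l_max}")
    R = []
    for S_t in covs.total:
        ridge = ridge_scale * float(np.mean(np.diag(S_t))) if ridge_scale else 0.0
        R.append(inv_sqrt_psd(S_t, ridge=ridge))
    M = []
    for d in range(D):
        Md = R[d] @ covs.between[d] @ R[d]
        M.append(0.5 * (Md + Md.T))
    N = {}
    for (d, j), S_dj in covs.cross.items():
        N[(d, j)] = R[d] @ S_dj @ R[j]
    c1 = rho / D
    c2 = 2.0 * (1.0 - rho) / (D * (D - 1))
    return WhitenedSystem(M=M, N=N, c1=c1, c2=c2, l=l, rho=rho)


# ---------------------------------------------------------------------------
# the coupled eigensystem
# ---------------------------------------------------------------------------

def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _coupling_matrix(system: WhitenedSystem, gammas: list[np.ndarray],
                     d: int) -> np.ndarray:
    G = system.c1 * system.M[d]
    if system.c2 != 0.0:
        for j in range(system.n_views):
            if j == d:
                continue
            NG = system.N[(d, j)] @ gammas[j]
            G = G + system.c2 * (NG @ NG.T)
    return 0.5 * (G + G.T)


def system_objective(system: WhitenedSystem, gammas: list[np.ndarray]) -> float:
    """Separation-plus-association objective at a feasible ``Gamma`` set."""
    D = system.n_views
    val = 0.0
    for d in range(D):
        val += system.c1 * float(np.trace(gammas[d].T @ system.M[d] @ gammas[d]))
        if system.c2 != 0.0:
            for j in range(D):
                if j == d:
                    continue
                B = gammas[d].T @ system.N[(d, j)] @ gammas[j]
                val += system.c2 * float(np.sum(B * B))
    return val


def _random_orthonormal(rng: np.random.Generator, o: int, l: int) -> np.ndarray:
    A = rng.standard_normal((o, l))
    Q, _ = np.linalg.qr(A)
    return Q[:, :l]


def solve_gamma(system: WhitenedSystem, init_seed: int = 0,
                tol: float = DEFAULT_TOL,
                max_iter: int = DEFAULT_MAX_ITER) -> GammaSolution:
    """Cyclically solve the coupled symmetric eigenproblems for ``Gamma_d``.

    Each sweep updates every view's ``Gamma_d`` to the top-``l``
    eigenvectors of ``c1 M_d + c2 sum_{j != d} N_dj G_j G_j^T N_dj^T``
    evaluated at the other views' current values; sweeps stop when the
    relative objective change drops below ``tol``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    D = system.n_views
    l = system.l
    rng = np.random.default_rng(init_seed)
    gammas = [_random_orthonormal(rng, system.M[d].shape[0], l) for d in range(D)]
    eigvals = [np.zeros(l) for _ in range(D)]
    prev_obj = -np.inf
    obj = system_objective(system, gammas)
    trace = [obj]
    converged = False
    all_positive = True
    it = 0
    for it in range(1, max_iter + 1):
        for d in range(D):
            G = _coupling_matrix(system, gammas, d)
            w, V = scipy.linalg.eigh(G)
            order = np.argsort(w)[::-1][:l]
            eigvals[d] = w[order]
            gammas[d] = _fix_signs(V[:, order])
        prev_obj, obj = obj, system_objective(system, gammas)
        trace.append(obj)
        denom = max(abs(prev_obj), 1e-12)
        if abs(obj - prev_obj) / denom < tol:
            converged = True
            break
    for vals in eigvals:
        if (vals <= 0).any():
            all_positive = False
    if not all_positive:
        warnings.warn(
            "fewer than l strictly positive eigenvalues; padded with the "
            "next eigenvectors",
            RuntimeWarning,
            stacklevel=2,
        )
    return GammaSolution(
        gammas=gammas,
        eigenvalues=eigvals,
        objective_value=obj,
        iterations_used=it,
        converged=converged,
        all_positive=all_positive,
        objective_trace=trace,
    )
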