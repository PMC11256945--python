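"""End-to-end fitting of the joint association-and-discrimination model.

The networks are trained to maximize, per view, the sum of the top-``l``
eigenvalues of ``G_d = c1 M_d + c2 sum_{j != d} N_dj G~_j G~_j^T N_dj^T``,
where ``M_d`` and ``N_dj`` are whitened covariances of the top-layer
representations and the projection matrices ``G~_j`` come from the
coupled eigensystem solver.  The loss is the negative eigenvalue sum.

Gradients are computed in closed form by reverse-mode matrix calculus:

* ``d(sum of top-l eigenvalues)/dG = V V^T`` (``V`` the top eigenvectors);
* the whitening map ``S_t -> (S_t + ridge I)^{-1/2}`` is differentiated
  with the Daleckii-Krein formula in the eigenbasis of ``S_t``;
* the covariance construction and the class/view means are linear maps
  of the representations with simple adjoints;
* ``G~`` is held constant during backpropagation (the eigensystem is
  re-solved each epoch on the fresh representations).

Optimization is full-batch Adam by default; views are column z-scored
with training-set statistics before entering the networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .linalg_core import (
    DEFAULT_MAX_ITER,
    DEFAULT_RIDGE_SCALE,
    DEFAULT_TOL,
    GammaSolution,
    WhitenedSystem,
    solve_gamma,
)
from .networks import ModelParams, NetworkSpec, backward, forward, forward_cached, init_params

__all__ = [
    "TrainConfig",
    "DeepIDAModel",
    "deep_ida_loss",
    "deep_ida_loss_and_grad",
    "train",
    "project",
]


@dataclass
class TrainConfig:
    """Hyperparameters of a fit.

    ``rho`` balances class separation against view association; 0.5 is
    the default as it gives good classification performance across a
    wide range of problems.  ``l`` defaults to
    ``min(K-1, min_d o_d)``.
    """

    rho: float = 0.5
    l: int | None = None
    epochs: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    batch_mode: str = "full"
    weight_decay: float = 0.0
    lr_decay: bool = False
    ridge_scale: float = DEFAULT_RIDGE_SCALE
    gamma_tol: float = DEFAULT_TOL
    gamma_max_iter: int = DEFAULT_MAX_ITER
    standardize: bool = True
    seed: int = 0
    verbose: bool = False
    log_file: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l is not None and self.l < 1:
            raise ValueError("l must be >= 1")
        if self.batch_mode != "full":
            raise ValueError("only full-batch training is supported")


@dataclass
class DeepIDAModel:
    """A fitted model: per-view networks, scalers, projections, trace."""

    specs: list[NetworkSpec]
    params: list[ModelParams]
    scalers: list[tuple[np.ndarray, np.ndarray]]
    gamma: GammaSolution
    loss_trace: list[float]
    config: TrainConfig
    classes: np.ndarray

    @property
    def n_views(self) -> int:
        return len(self.specs)


# ---------------------------------------------------------------------------
# loss forward + reverse
# ---------------------------------------------------------------------------

def _class_partition(labels: np.ndarray):
    classes, inverse, counts = np.unique(
        np.asarray(labels), return_inverse=True, return_counts=True
    )
    return classes, inverse, counts


def deep_ida_loss_and_grad(
    Hs: list[np.ndarray],
    labels: np.ndarray,
    rho: float = 0.5,
    l: int | None = None,
    ridge_scale: float = DEFAULT_RIDGE_SCALE,
    gammas: list[np.ndarray] | None = None,
    gamma_seed: int = 0,
    gamma_tol: float = DEFAULT_TOL,
    gamma_max_iter: int = DEFAULT_MAX_ITER,
):
    """Negative eigenvalue-sum loss and its gradient w.r.t. each ``H_d``.

    Returns ``(loss, grads, aux)`` where ``grads[d]`` has the shape of
    ``Hs[d]`` and ``aux`` carries the whitened system and the (fixed)
    projection matrices used.  If ``gammas`` is None the coupled
    eigensystem is solved first and the result treated as constant.
    """
    D = len(Hs)
    if D < 2:
        raise ValueError("need at least two views")
    Hs = [np.asarray(H, dtype=float) for H in Hs]
    n = Hs[0].shape[0]
    classes, inverse, counts = _class_partition(labels)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least two classes in the batch")
    for H in Hs:
        if H.shape[0] != n:
            raise ValueError("views are not row-aligned")
        if H.shape[1] >= n:
            raise ValueError("output dimension must be below the sample size")

    # ---- forward: covariances ------------------------------------------
    mu_k = []          # per view: K x o
    mu = []            # per view: o
    C = []             # per view: n x o, H - mu
    m_k = []           # per view: K x o, mu_k - mu
    S_b = []
    eig_w = []         # eigenvalues of S_t
    eig_U = []
    ridge = []
    R = []             # (S_t + ridge I)^{-1/2}
    for d in range(D):
        mk = np.stack([Hs[d][inverse == k].mean(axis=0) for k in range(K)])
        m = mk.mean(axis=0)
        Cd = Hs[d] - m
        St = Cd.T @ Cd / (n - 1)
        St = 0.5 * (St + St.T)
        diffs = mk - m
        Sb = (diffs.T * counts) @ diffs / (n - 1)
        Sb = 0.5 * (Sb + Sb.T)
        w, U = scipy.linalg.eigh(St)
        r = ridge_scale * float(np.mean(np.diag(St)))
        if ((w + r) <= 0).any():
            raise ValueError("total covariance not positive definite after ridge")
        Rd = (U * (w + r) ** -0.5) @ U.T
        mu_k.append(mk)
        mu.append(m)
        C.append(Cd)
        m_k.append(diffs)
        S_b.append(Sb)
        eig_w.append(w)
        eig_U.append(U)
        ridge.append(r)
        R.append(Rd)

    S_cross = {}
    for d in range(D):
        for j in range(D):
            if d != j:
                S_cross[(d, j)] = C[d].T @ C[j] / (n - 1)

    c1 = rho / D
    c2 = 2.0 * (1.0 - rho) / (D * (D - 1))
    M = []
    for d in range(D):
        Md = R[d] @ S_b[d] @ R[d]
        M.append(0.5 * (Md + Md.T))
    N = {k: R[d] @ S @ R[j] for (d, j), S in S_cross.items() for k in [(d, j)]}

    if l is None:
        l = min([K - 1] + [H.shape[1] for H in Hs])
    system = WhitenedSystem(M=M, N=N, c1=c1, c2=c2, l=l, rho=rho)

    if gammas is None:
        sol = solve_gamma(system, init_seed=gamma_seed, tol=gamma_tol,
                          max_iter=gamma_max_iter)
        gammas = sol.gammas
    else:
        sol = None
    P = [G @ G.T for G in gammas]

    # ---- forward: eigenvalue sums --------------------------------------
    loss = 0.0
    bar_G = []
    eig_sums = []
    for d in range(D):
        Gd = c1 * M[d]
        if c2 != 0.0:
            for j in range(D):
                if j != d:
                    NP = N[(d, j)] @ gammas[j]
                    Gd = Gd + c2 * (NP @ NP.T)
        Gd = 0.5 * (Gd + Gd.T)
        w, V = scipy.linalg.eigh(Gd)
        order = np.argsort(w)[::-1][:l]
        eig_sums.append(float(np.sum(w[order])))
        loss -= eig_sums[-1]
        Vl = V[:, order]
        bar_G.append(-(Vl @ Vl.T))  # d loss / d G_d

    # ---- reverse -------------------------------------------------------
    bar_Sb = [c1 * (R[d] @ bar_G[d] @ R[d]) for d in range(D)]
    bar_R = [c1 * (bar_G[d] @ R[d] @ S_b[d] + S_b[d] @ R[d] @ bar_G[d])
             for d in range(D)]
    bar_Scross = {k: np.zeros_like(v) for k, v in S_cross.items()}
    if c2 != 0.0:
        for d in range(D):
            for j in range(D):
                if j == d:
                    continue
                bar_N = 2.0 * c2 * (bar_G[d] @ N[(d, j)] @ P[j])
                bar_Scross[(d, j)] += R[d] @ bar_N @ R[j]
                bar_R[d] += bar_N @ R[j] @ S_cross[(d, j)].T
                bar_R[j] += S_cross[(d, j)].T @ R[d] @ bar_N

    bar_St = []
    for d in range(D):
        # Daleckii-Krein for S_t -> (S_t + r I)^{-1/2}, including the
        # dependence of the relative ridge r on diag(S_t).
        w, U = eig_w[d], eig_U[d]
        r = ridge[d]
        o = len(w)
        f = (w + r) ** -0.5
        fprime = -0.5 * (w + r) ** -1.5
        sym = 0.5 * (bar_R[d] + bar_R[d].T)
        B = U.T @ sym @ U
        dw = w[:, None] - w[None, :]
        close = np.abs(dw) < 1e-10 * max(1.0, np.abs(w).max())
        Kmat = np.where(close, 0.0, (f[:, None] - f[None, :]) / np.where(close, 1.0, dw))
        mid = 0.5 * (w[:, None] + w[None, :])
        Kmat = np.where(close, -0.5 * (mid + r) ** -1.5, Kmat)
        bS = U @ (B * Kmat) @ U.T
        bar_r = float(np.sum(np.diag(B) * fprime))
        bS = bS + (ridge_scale * bar_r / o) * np.eye(o)
        bar_St.append(0.5 * (bS + bS.T))

    grads = []
    for d in range(D):
        bar_C = C[d] @ (bar_St[d] + bar_St[d].T) / (n - 1)
        for j in range(D):
            if j == d:
                continue
            bar_C += C[j] @ bar_Scross[(d, j)].T / (n - 1)
            bar_C += C[j] @ bar_Scross[(j, d)] / (n - 1)
        bar_H = bar_C.copy()
        bar_mu = -bar_C.sum(axis=0)
        # between-class scatter
        bar_mk = ((counts / (n - 1))[:, None]) * (m_k[d] @ (bar_Sb[d] + bar_Sb[d].T))
        bar_mu -= bar_mk.sum(axis=0)
        bar_muk = bar_mk + bar_mu / K
        bar_H += (bar_muk / counts[:, None])[inverse]
        grads.append(bar_H)

    aux = {"system": system, "gammas": gammas, "solution": sol,
           "eig_sums": eig_sums, "l": l}
    return loss, grads, aux


def deep_ida_loss(Hs, labels, rho=0.5, l=None, ridge_scale=DEFAULT_RIDGE_SCALE,
                  gammas=None, gamma_seed=0) -> float:
    """Scalar loss: negative sum over views of the top-``l`` eigenvalues."""
    loss, _, _ = deep_ida_loss_and_grad(
        Hs, labels, rho=rho, l=l, ridge_scale=ridge_scale, gammas=gammas,
        gamma_seed=gamma_seed,
    )
    return loss


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class _Adam:
    """Adam with decoupled weight decay and an optional cosine decay of
    the step size to one tenth of its initial value."""

    def __init__(self, params_list, lr, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0, total_steps=None):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.total_steps = total_steps
        self.t = 0
        self.m = [[np.zeros_like(a) for a in view] for view in params_list]
        self.v = [[np.zeros_like(a) for a in view] for view in params_list]

    def step(self, params_list, grads_list):
        self.t += 1
        lr = self.lr
        if self.total_steps:
            frac = min(self.t / self.total_steps, 1.0)
            lr = self.lr * (0.55 + 0.45 * np.cos(np.pi * frac))
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for view, (params, grads) in enumerate(zip(params_list, grads_list)):
            for i, (p, g) in enumerate(zip(params, grads)):
                m = self.m[view][i] = self.b1 * self.m[view][i] + (1 - self.b1) * g
                v = self.v[view][i] = self.b2 * self.v[view][i] + (1 - self.b2) * g * g
                if self.wd:
                    p -= lr * self.wd * p
                p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class _SGD:
    def __init__(self, params_list, lr):
        self.lr = lr

    def step(self, params_list, grads_list):
        for params, grads in zip(params_list, grads_list):
            for p, g in zip(params, grads):
                p -= self.lr * g


def _fit_scaler(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    std = np.where(std < 1e-8, 1.0, std)
    return mean, std


def train(dataset, specs: list[NetworkSpec] | None = None,
          config: TrainConfig | None = None) -> DeepIDAModel:
    """Fit the model on a multi-view dataset.

    ``dataset`` is anything with ``views`` (list of n x p_d arrays) and
    ``labels``; ``specs`` defaults to the standard architecture per view.
    Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    views = [np.asarray(X, dtype=float) for X in dataset.views]
    labels = np.asarray(dataset.labels)
    D = len(views)
    if D < 2:
        raise ValueError("need at least two views")
    n = views[0].shape[0]
    classes, _, counts = _class_partition(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    if specs is None:
        specs = [NetworkSpec(input_dim=X.shape[1]) for X in views]
    for spec in specs:
        if spec.output_dim >= n:
            raise ValueError(
                f"output_dim={spec.output_dim} must be below n={n} "
                "for an invertible total covariance"
            )
    l = config.l
    if l is None:
        l = min([len(classes) - 1] + [s.output_dim for s in specs])

    if config.standardize:
        scalers = [_fit_scaler(X) for X in views]
        Xs = [(X - m) / s for X, (m, s) in zip(views, scalers)]
    else:
        scalers = [(np.zeros(X.shape[1]), np.ones(X.shape[1])) for X in views]
        Xs = views

    ss = np.random.SeedSequence(config.seed)
    view_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(D + 1)]
    gamma_seed = view_seeds[-1]
    params = [init_params(spec, seed=view_seeds[d]) for d, spec in enumerate(specs)]

    flat = [p.weights + p.biases for p in params]
    if config.optimizer == "adam":
        opt = _Adam(flat, config.learning_rate,
                    weight_decay=config.weight_decay,
                    total_steps=config.epochs if config.lr_decay else None)
    elif config.optimizer == "sgd":
        opt = _SGD(flat, config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    log_fh = open(config.log_file, "w") if config.log_file else None
    loss_trace = []
    for epoch in range(config.epochs):
        Hs, caches = [], []
        for d in range(D):
            H, cache = forward_cached(params[d], Xs[d])
            Hs.append(H)
            caches.append(cache)
        loss, grad_Hs, _aux = deep_ida_loss_and_grad(
            Hs, labels, rho=config.rho, l=l, ridge_scale=config.ridge_scale,
            gamma_seed=gamma_seed, gamma_tol=config.gamma_tol,
            gamma_max_iter=config.gamma_max_iter,
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {loss!r}; consider a "
                "larger ridge or a smaller learning rate"
            )
        loss_trace.append(float(loss))
        if config.verbose or log_fh:
            sums = " ".join(f"{s:.4f}" for s in _aux["eig_sums"])
            line = f"epoch {epoch:4d}  loss {loss:.6f}  eig_sums {sums}"
            if config.verbose:
                print(line)
            if log_fh:
                log_fh.write(line + "\n")
        grads_flat = []
        for d in range(D):
            gW, gb = backward(params[d], caches[d], grad_Hs[d])
            grads_flat.append(gW + gb)
        opt.step(flat, grads_flat)

    if log_fh:
        log_fh.close()
    # final projections on the trained representations
    Hs = [forward(params[d], Xs[d]) for d in range(D)]
    _, _, aux = deep_ida_loss_and_grad(
        Hs, labels, rho=config.rho, l=l, ridge_scale=config.ridge_scale,
        gamma_seed=gamma_seed, gamma_tol=config.gamma_tol,
        gamma_max_iter=config.gamma_max_iter,
    )
    return DeepIDAModel(
        specs=specs,
        params=params,
        scalers=scalers,
        gamma=aux["solution"],
        loss_trace=loss_trace,
        config=config,
        classes=classes,
    )


def project(model: DeepIDAModel, views: list[np.ndarray]):
    """Top-layer representations and discriminant scores for new data.

    Returns ``(Hs, scores)`` where ``scores[d] = H_d Gamma_d`` has ``l``
    columns; concatenate entries of either list for pooled variants.
    """
    views = [np.asarray(X, dtype=float) for X in views]
    if len(views) != model.n_views:
        raise ValueError("wrong number of views")
    Hs = []
    for d, X in enumerate(views):
        mean, std = model.scalers[d]
        if X.shape[1] != mean.shape[0]:
            raise ValueError(
                f"view {d} has {X.shape[1]} columns, model expects {mean.shape[0]}"
            )
        Hs.append(forward(model.params[d], (X - mean) / std))
    scores = [H @ G for H, G in zip(Hs, model.gamma.gammas)]
    return Hs, scores
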