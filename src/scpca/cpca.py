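"""Multinomial exponential-family PCA (categorical PCA) for SNP genotypes.

Genotypes 0/1/2 are treated as three unordered categories of a multinomial
distribution.  Each cell's natural parameter vector is modelled as a low-rank
bilinear form

    theta^k_{ij} = V^k_j . u_i + mu^k_j          for k in {1, .., c-1},

with category 0 taken as the reference (theta^0 = 0), which removes the
softmax gauge freedom and reduces exactly to Bernoulli (logistic) PCA when
c = 2.  The log-likelihood

    l = sum_{ij} [ theta^{k(i,j)}_{ij} - log(1 + sum_k exp theta^k_{ij}) ]

is maximized by alternating damped Newton updates of the score matrix U, the
per-category loading matrices V^k and the offsets mu^k, with a QR step that
re-orthonormalizes the stacked loading matrix after every score update while
leaving every natural parameter unchanged.

The solver is block-coordinate ascent: each block update is a Newton step with
step-halving, so the likelihood trace is non-decreasing within a restart.
Multiple random restarts guard against local maxima of this non-concave
objective.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .setio import GenotypeMatrix

__all__ = [
    "OneHotGenotypes",
    "FitConfig",
    "CPCAModel",
    "encode_one_hot",
    "log_likelihood",
    "newton_step_scores",
    "newton_step_loadings",
    "newton_step_offsets",
    "orthonormalize",
    "fit_cpca",
    "first_pc_scores",
]

#: probabilities and likelihoods use max-subtracted (log-sum-exp) softmax, so
#: arbitrarily large natural parameters stay finite without clipping; under
#: separation (e.g. a zero-count category) parameters drift but damping and
#: the iteration cap bound the drift.


@dataclass
class OneHotGenotypes:
    """Indicator representation of a categorical matrix.

    ``indicators[k]`` is the n x d 0/1 matrix marking cells observed in
    category k; the categories partition every cell, so the indicators sum to
    one over k.  ``codes`` keeps the compact integer coding used internally.
    """

    codes: np.ndarray  # (n, d) int8, values in 0..c-1
    n_categories: int = 3

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-d matrix")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) >= self.n_categories:
            raise ValueError(f"category codes must lie in [0, {self.n_categories})")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def indicators(self) -> np.ndarray:
        """(c, n, d) stack of 0/1 indicator matrices."""
        c = self.n_categories
        return np.stack([(self.codes == k).astype(np.uint8) for k in range(c)])


def encode_one_hot(G: GenotypeMatrix | np.ndarray, n_categories: int = 3) -> OneHotGenotypes:
    """One-hot encode a genotype matrix: x^k_{ij} = 1 iff G_{ij} = k."""
    values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    return OneHotGenotypes(codes=values.astype(np.int8), n_categories=n_categories)


@dataclass
class FitConfig:
    """Solver settings for :func:`fit_cpca`.

    latent_dim
        Number of principal components l (>= 1, < min(n, (c-1) d)).
    tolerance
        Relative log-likelihood change declaring convergence.
    n_restarts
        Random restarts; the best restart by final likelihood is kept.
    damping
        Maximum number of Newton step-halvings per block update.
    ridge
        Weight of an optional Gaussian (ridge) penalty lambda/2 sum theta^2
        on the natural parameters.  0 (default) maximizes the plain
        likelihood; a small positive value (~1e-3) keeps the optimum finite
        under partial separation, where the unpenalized MLE does not exist.
    """

    latent_dim: int = 1
    max_iterations: int = 200
    tolerance: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    damping: int = 20
    ridge: float = 0.0

    def validate(self, n: int, d: int, c: int = 3) -> None:
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.latent_dim >= min(n, (c - 1) * d):
            raise ValueError(
                f"latent_dim={self.latent_dim} must be < min(n_samples, (c-1)*d_snps)"
                f" = {min(n, (c - 1) * d)}"
            )
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class CPCAModel:
    """Fitted categorical PCA model.

    scores U (n x l), loadings V (c-1, d, l) and offsets mu (c-1, d) define
    the natural parameters; the stacked ((c-1)d x l) loading matrix has
    orthonormal columns.
    """

    scores: np.ndarray  # (n, l)
    loadings: np.ndarray  # (K, d, l), K = c - 1
    offsets: np.ndarray  # (K, d)
    log_likelihood: float
    converged: bool
    n_iterations: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    config: Optional[FitConfig] = None

    @property
    def latent_dim(self) -> int:
        return self.scores.shape[1]

    @property
    def n_categories(self) -> int:
        return self.loadings.shape[0] + 1

    def natural_parameters(self) -> np.ndarray:
        """(K, n, d) array of theta^k for the non-reference categories."""
        return _theta(self.scores, self.loadings, self.offsets)

    def cell_probabilities(self) -> np.ndarray:
        """(c, n, d) fitted multinomial cell probabilities (reference first)."""
        p = _probs(self.natural_parameters())
        p0 = 1.0 - p.sum(axis=0)
        return np.concatenate([p0[None], p], axis=0)

    def to_json(self) -> str:
        doc = {
            "latent_dim": self.latent_dim,
            "n_categories": self.n_categories,
            "scores": self.scores.tolist(),
            "loadings": self.loadings.tolist(),
            "offsets": self.offsets.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "seed": None if self.config is None else self.config.seed,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CPCAModel":
        doc = json.loads(text)
        return cls(
            scores=np.asarray(doc["scores"], dtype=float),
            loadings=np.asarray(doc["loadings"], dtype=float),
            offsets=np.asarray(doc["offsets"], dtype=float),
            log_likelihood=float(doc["log_likelihood"]),
            converged=bool(doc["converged"]),
            n_iterations=int(doc["n_iterations"]),
        )


# ---------------------------------------------------------------------------
# likelihood machinery (reference NumPy path, any latent dimension)
# ---------------------------------------------------------------------------


def _theta(U: np.ndarray, V: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Natural parameters theta^k_{ij} = V^k_j . u_i + mu^k_j."""
    return np.einsum("nl,kjl->knj", U, V) + mu[:, None, :]


def _probs(theta: np.ndarray) -> np.ndarray:
    """Multinomial probabilities p^k (non-reference categories) from theta,
    computed with max-subtracted softmax for stability."""
    a = np.maximum(theta.max(axis=0), 0.0)
    E = np.exp(theta - a)
    Z = np.exp(-a) + E.sum(axis=0)
    return E / Z


def _ll_cells(codes: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-cell log-likelihood contributions, shape (n, d)."""
    K = theta.shape[0]
    a = np.maximum(theta.max(axis=0), 0.0)
    logZ = a + np.log(np.exp(-a) + np.exp(theta - a).sum(axis=0))
    out = -logZ
    for k in range(K):
        out = out + np.where(codes == k + 1, theta[k], 0.0)
    return out


def log_likelihood(
    X: OneHotGenotypes,
    model: CPCAModel | None = None,
    *,
    U: np.ndarray | None = None,
    V: np.ndarray | None = None,
    mu: np.ndarray | None = None,
) -> float:
    """Multinomial log-likelihood of the one-hot data under the model.

    Accepts either a fitted :class:`CPCAModel` or raw (U, V, mu) arrays.
    Always <= 0; the constant base-measure term is omitted.
    """
    if model is not None:
        U, V, mu = model.scores, model.loadings, model.offsets
    assert U is not None and V is not None and mu is not None
    th = _theta(U, V, mu)
    if not np.all(np.isfinite(th)):
        bad = np.argwhere(~np.isfinite(th))[0]
        raise FloatingPointError(f"non-finite natural parameter at (k,i,j)={tuple(bad)}")
    return float(_ll_cells(X.codes, th).sum())


def _row_obj(codes, U, V, mu, ridge=0.0) -> np.ndarray:
    th = _theta(U, V, mu)
    out = _ll_cells(codes, th).sum(axis=1)
    if ridge:
        out = out - 0.5 * ridge * (th ** 2).sum(axis=(0, 2))
    return out


def _col_obj(codes, U, V, mu, ridge=0.0) -> np.ndarray:
    th = _theta(U, V, mu)
    out = _ll_cells(codes, th).sum(axis=0)
    if ridge:
        out = out - 0.5 * ridge * (th ** 2).sum(axis=(0, 1))
    return out


def _multinomial_weights(p: np.ndarray) -> np.ndarray:
    """(K, K, n, d) multinomial covariance per cell: diag(p) - p p^T."""
    K = p.shape[0]
    W = -p[:, None] * p[None, :]
    for k in range(K):
        W[k, k] += p[k]
    return W


def newton_step_scores(
    X: OneHotGenotypes,
    U: np.ndarray,
    V: np.ndarray,
    mu: np.ndarray,
    damping: int = 20,
    ridge: float = 0.0,
) -> np.ndarray:
    """One damped Newton update of every score row u_i (loadings fixed).

    The gradient for row i is sum_{j,k} (x^k_{ij} - p^k_{ij}) V^k_j and the
    Hessian is minus the multinomial covariance projected through the
    loadings; each row's step is halved until its objective contribution
    improves.  ``ridge`` adds the natural-parameter penalty terms.
    """
    codes = X.codes
    n, l = U.shape
    th = _theta(U, V, mu)
    p = _probs(th)
    K = p.shape[0]

    resid = np.stack([(codes == k + 1) - p[k] for k in range(K)])  # (K, n, d)
    g = np.einsum("knj,kjl->nl", resid, V)
    W = _multinomial_weights(p)
    H = -np.einsum("kqnj,kjl,qjm->nlm", W, V, V)
    if ridge:
        g = g - ridge * np.einsum("knj,kjl->nl", th, V)
        H = H - ridge * np.einsum("kjl,kjm->lm", V, V)

    delta = np.empty_like(U)
    ok = True
    try:
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        ok = np.all(np.isfinite(delta))
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        warnings.warn("singular score Hessian; falling back to a fixed gradient step")
        delta = -0.1 * g  # ascent direction once negated below

    # Newton ascent: u <- u - H^{-1} g (H is negative definite at a maximum);
    # quasi-separated rows give huge deltas, capped so step-halving can land
    norms = np.linalg.norm(delta, axis=1, keepdims=True)
    delta = delta * np.minimum(1.0, 100.0 / np.maximum(norms, 1e-300))
    u_new = U - delta

    before = _row_obj(codes, U, V, mu, ridge)
    accepted = U.copy()
    pending = np.ones(n, dtype=bool)
    step = 1.0
    for _ in range(damping + 1):
        trial = accepted.copy()
        trial[pending] = U[pending] + step * (u_new[pending] - U[pending])
        after = _row_obj(codes, trial, V, mu, ridge)
        good = pending & (after > before + 1e-12)
        accepted[good] = trial[good]
        pending = pending & ~good
        if not pending.any():
            break
        step *= 0.5
    return accepted


def newton_step_loadings(
    X: OneHotGenotypes,
    U: np.ndarray,
    V: np.ndarray,
    mu: np.ndarray,
    damping: int = 20,
    ridge: float = 0.0,
) -> np.ndarray:
    """One damped Newton update of every loading row V^k_j (scores fixed).

    Category blocks are updated sequentially (probabilities refreshed in
    between) so the objective is non-decreasing after damping.
    """
    codes = X.codes
    K, d, l = V.shape
    V = V.copy()
    for k in range(K):
        th = _theta(U, V, mu)
        p = _probs(th)
        resid_k = (codes == k + 1) - p[k]  # (n, d)
        g = resid_k.T @ U  # (d, l)
        w = p[k] * (1.0 - p[k])  # (n, d)
        H = -np.einsum("nj,nl,nm->jlm", w, U, U)
        if ridge:
            g = g - ridge * (th[k].T @ U)
            H = H - ridge * (U.T @ U)
        try:
            delta = np.linalg.solve(H, g[..., None])[..., 0]
            if not np.all(np.isfinite(delta)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular loading Hessian; falling back to a fixed gradient step")
            delta = -0.1 * g
        norms = np.linalg.norm(delta, axis=1, keepdims=True)
        delta = delta * np.minimum(1.0, 100.0 / np.maximum(norms, 1e-300))
        v_new = V[k] - delta

        before = _col_obj(codes, U, V, mu, ridge)
        pending = np.ones(d, dtype=bool)
        step = 1.0
        for _ in range(damping + 1):
            trial = V.copy()
            trial[k][pending] = V[k][pending] + step * (v_new[pending] - V[k][pending])
            after = _col_obj(codes, U, trial, mu, ridge)
            good = pending & (after > before + 1e-12)
            V[k][good] = trial[k][good]
            pending = pending & ~good
            if not pending.any():
                break
            step *= 0.5
    return V


def newton_step_offsets(
    X: OneHotGenotypes,
    U: np.ndarray,
    V: np.ndarray,
    mu: np.ndarray,
    damping: int = 20,
    ridge: float = 0.0,
) -> np.ndarray:
    """One damped Newton update of the offset vector (mu^1_j, .., mu^{c-1}_j)
    jointly per SNP j (scores and loadings fixed)."""
    codes = X.codes
    K, d = mu.shape
    th = _theta(U, V, mu)
    p = _probs(th)
    resid = np.stack([(codes == k + 1) - p[k] for k in range(K)])
    g = resid.sum(axis=1).T  # (d, K)
    W = _multinomial_weights(p)  # (K, K, n, d)
    H = -W.sum(axis=2).transpose(2, 0, 1)  # (d, K, K)
    if ridge:
        g = g - ridge * th.sum(axis=1).T
        for k in range(K):
            H[:, k, k] -= ridge * codes.shape[0]
    # freeze flat-curvature coordinates (empty categories) before solving
    n = codes.shape[0]
    flat = np.einsum("dkk->dk", H) > -1e-9 * n  # (d, K) diagonal check
    if flat.any():
        for j, k in np.argwhere(flat):
            H[j, k, :] = 0.0
            H[j, :, k] = 0.0
            H[j, k, k] = -1.0
            g[j, k] = 0.0
    try:
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        if not np.all(np.isfinite(delta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular offset Hessian; falling back to a fixed gradient step")
        delta = -0.1 * g
    norms = np.linalg.norm(delta, axis=1, keepdims=True)
    delta = delta * np.minimum(1.0, 100.0 / np.maximum(norms, 1e-300))
    mu_new = mu - delta.T

    before = _col_obj(codes, U, V, mu, ridge)
    accepted = mu.copy()
    pending = np.ones(d, dtype=bool)
    step = 1.0
    for _ in range(damping + 1):
        trial = accepted.copy()
        trial[:, pending] = mu[:, pending] + step * (mu_new[:, pending] - mu[:, pending])
        after = _col_obj(codes, U, V, trial, ridge)
        good = pending & (after > before + 1e-12)
        accepted[:, good] = trial[:, good]
        pending = pending & ~good
        if not pending.any():
            break
        step *= 0.5
    return accepted


def orthonormalize(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """QR re-orthonormalization of the stacked loading matrix.

    The (c-1)d x l stacked loadings are replaced by the Q factor and the
    scores back-rotated by R^T, so every natural parameter theta^k_{ij} is
    unchanged to machine precision.
    """
    K, d, l = V.shape
    stacked = V.reshape(K * d, l)
    Q, R = np.linalg.qr(stacked)
    diag = np.diag(R)
    if np.any(np.abs(diag) < 1e-12):
        raise np.linalg.LinAlgError(
            "rank-deficient loadings; try a smaller latent_dim"
        )
    s = np.sign(diag)
    Q = Q * s
    R = R * s[:, None]
    return U @ R.T, Q.reshape(K, d, l)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _init_params(
    X: OneHotGenotypes, l: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.codes.shape
    K = X.n_categories - 1
    U = 0.1 * rng.standard_normal((n, l))
    V = 0.1 * rng.standard_normal((K, d, l))
    # offsets start at smoothed per-SNP empirical log-odds vs the reference
    counts = np.stack([(X.codes == k).sum(axis=0) for k in range(X.n_categories)])
    mu = np.log((counts[1:] + 0.5) / (counts[0] + 0.5))
    return U, V, mu


def _fit_single_numpy(
    X: OneHotGenotypes,
    U: np.ndarray,
    V: np.ndarray,
    mu: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    ridge = config.ridge

    def _obj(U_, V_, mu_):
        val = log_likelihood(X, U=U_, V=V_, mu=mu_)
        if ridge:
            val -= 0.5 * ridge * float((_theta(U_, V_, mu_) ** 2).sum())
        return val

    trace = [_obj(U, V, mu)]
    converged = False
    for _ in range(config.max_iterations):
        U = newton_step_scores(X, U, V, mu, config.damping, ridge)
        # exact reparameterization: move the score mean into the offsets
        # ((u - c) V + (mu + V c) leaves theta unchanged) so the flat
        # translation direction does not slow the block updates down
        c = U.mean(axis=0)
        U = U - c
        mu = mu + np.einsum("kjl,l->kj", V, c)
        U, V = orthonormalize(U, V)
        V = newton_step_loadings(X, U, V, mu, config.damping, ridge)
        mu = newton_step_offsets(X, U, V, mu, config.damping, ridge)
        ll = _obj(U, V, mu)
        trace.append(ll)
        if abs(ll - trace[-2]) < config.tolerance * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    return U, V, mu, np.asarray(trace), converged


def _fit_single_kernel(
    X: OneHotGenotypes,
    U: np.ndarray,
    V: np.ndarray,
    mu: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    kernel = _kernels.fit_l1_k2 if V.shape[0] == 2 else _kernels.fit_l1
    u, v, m, trace, n_tr, conv = kernel(
        X.codes,
        np.ascontiguousarray(U[:, 0]),
        np.ascontiguousarray(V[:, :, 0]),
        np.ascontiguousarray(mu),
        config.max_iterations,
        config.tolerance,
        config.damping,
        config.ridge,
    )
    return u[:, None], v[:, :, None], m, trace[:n_tr], bool(conv)


def _fit_l1_fast(
    codes: np.ndarray,
    n_categories: int,
    config: FitConfig,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slim latent_dim=1 fit for the supervised pipeline's score cache.

    Same kernel and update cycle as :func:`fit_cpca`, without the model
    object, validation, final QR or data-likelihood bookkeeping (the cache
    only needs scores and parameters for warm starts).  Scores are
    sign-stabilized against per-sample minor-allele counts.
    """
    X = OneHotGenotypes.__new__(OneHotGenotypes)
    X.codes = codes
    X.n_categories = n_categories
    if init is not None:
        U0, V0, mu0 = (np.array(a, dtype=float) for a in init)
    else:
        U0, V0, mu0 = _init_params(X, 1, np.random.default_rng(config.seed))
    kernel = _kernels.fit_l1_k2 if n_categories == 3 else _kernels.fit_l1
    u, V, mu, trace, n_tr, conv = kernel(
        codes,
        np.ascontiguousarray(U0[:, 0]),
        np.ascontiguousarray(V0[:, :, 0]),
        np.ascontiguousarray(mu0),
        config.max_iterations,
        config.tolerance,
        config.damping,
        config.ridge,
    )
    counts = codes.sum(axis=1).astype(float)
    cov = float((u - u.mean()) @ (counts - counts.mean()))
    if cov < 0:
        u = -u
        V = -V
    return u[:, None], V[:, :, None], mu


def fit_cpca(
    G: GenotypeMatrix | np.ndarray,
    config: FitConfig | None = None,
    *,
    n_categories: int = 3,
    use_kernel: bool = True,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> CPCAModel:
    """Fit categorical PCA by alternating damped Newton updates.

    Runs ``config.n_restarts`` seed-controlled restarts and keeps the best
    final likelihood.  For ``latent_dim == 1`` a compiled kernel carries out
    the same update cycle; set ``use_kernel=False`` to force the reference
    NumPy path.  ``init`` supplies explicit starting (U, V, mu) arrays and
    replaces the random restarts with a single warm-started run.
    """
    config = config or FitConfig()
    X = encode_one_hot(G, n_categories=n_categories)
    n, d = X.codes.shape
    config.validate(n, d, c=n_categories)

    if init is not None:
        starts = [tuple(np.array(a, dtype=float) for a in init)]
    else:
        ss = np.random.SeedSequence(config.seed)
        starts = [
            _init_params(X, config.latent_dim, np.random.default_rng(child))
            for child in ss.spawn(config.n_restarts)
        ]

    best: tuple[float, tuple] | None = None
    initial_ll = None
    for U0, V0, mu0 in starts:
        if config.latent_dim == 1 and use_kernel:
            fit = _fit_single_kernel(X, U0, V0, mu0, config)
        else:
            fit = _fit_single_numpy(X, U0, V0, mu0, config)
        if initial_ll is None:
            initial_ll = float(fit[3][0])  # trace starts at the init ll
        ll = float(fit[3][-1])
        if best is None or ll > best[0]:
            best = (ll, fit)

    assert best is not None and initial_ll is not None
    ll, (U, V, mu, trace, converged) = best
    if ll < initial_ll - 1e-9:
        warnings.warn("no restart improved on its initialization; model may be degenerate")
        converged = False

    # the cycle ends on a loading/offset update; re-impose orthonormality
    # (theta-preserving) so the returned model satisfies its invariant
    try:
        U, V = orthonormalize(U, V)
    except np.linalg.LinAlgError:
        warnings.warn("final loadings are rank deficient; returned unnormalized")
    U, V = _fix_first_pc_sign(X, U, V)
    if config.ridge:
        ll = log_likelihood(X, U=U, V=V, mu=mu)  # report the data term
    return CPCAModel(
        scores=U,
        loadings=V,
        offsets=mu,
        log_likelihood=ll,
        converged=converged,
        n_iterations=len(trace) - 1,
        ll_trace=np.asarray(trace),
        config=config,
    )


def _fix_first_pc_sign(
    X: OneHotGenotypes, U: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flip the first PC so it correlates non-negatively with per-sample
    minor-allele counts; theta is preserved by flipping U and V together."""
    counts = X.codes.sum(axis=1).astype(float)
    u1 = U[:, 0]
    cov = float((u1 - u1.mean()) @ (counts - counts.mean()))
    if cov < 0:
        U = U.copy()
        V = V.copy()
        U[:, 0] *= -1
        V[:, :, 0] *= -1
    return U, V


def first_pc_scores(model: CPCAModel) -> np.ndarray:
    """First principal component scores (column 1 of U, sign-stabilized)."""
    if model.scores.size == 0:
        raise ValueError("model has no fitted scores")
    return model.scores[:, 0].copy()
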