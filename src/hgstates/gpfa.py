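"""Gaussian process factor analysis (GPFA), from scratch.

Model: per 250 ms bin, observed q-channel activity y_t is a linear-Gaussian
readout of a p-dimensional latent state x_t,

    y_t | x_t ~ N(C x_t + d, R),          R diagonal,

and each latent dimension i is, across the T bins of an epoch, a draw from a
zero-mean Gaussian process with a squared-exponential kernel of timescale
tau_i,

    K_i(t1, t2) = (1 - sigma_n^2) exp(-(t1 - t2)^2 / (2 tau_i^2))
                  + sigma_n^2 [t1 = t2],

unit marginal variance, and a small noise floor sigma_n^2 = 1e-3.  Setting
K_i = I recovers plain factor analysis (FA); the FA baseline here is backed by
scikit-learn and also initializes the EM.

Fitting is exact EM: the E-step computes the joint Gaussian posterior over all
pT latents of an epoch (shared across epochs of equal length), the M-step
updates C, d, R in closed form and each tau_i by numerically maximizing its
expected log-likelihood term.  The data log-likelihood is evaluated with the
matrix-inversion lemma so nothing larger than pT x pT is ever factorized, and
it is monotone non-decreasing over iterations.

Also here: posterior latent inference (including with held-out channels, for
leave-one-channel-out prediction error), orthonormalization of the loading
matrix by SVD ("reduced GPFA", factors ordered by covariance explained), the
class-balanced leave-one-channel-out RMSE model comparison, and the decoding
curves over latent factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.decomposition import FactorAnalysis

from .classifiers import ConstrainedGaussianModel, DecodingResult
from .preprocess import BIN_MS
from .synthetic import SIGMA_N_SQ, gp_kernel
from .validation import CVPlan, balance_classes

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class GPFAParams:
    """Fitted model parameters theta = (C, d, R, tau_1..tau_p).

    ``taus_ms is None`` marks a plain FA model (time-independent latents).
    ``fit_log`` records the per-iteration training objective (data
    log-likelihood for GPFA; scikit-learn's per-sample average log-likelihood
    for FA) and is non-decreasing.
    """

    C: np.ndarray  # (q, p)
    d: np.ndarray  # (q,)
    R: np.ndarray  # (q,) diagonal observation noise
    taus_ms: np.ndarray | None
    sigma_n_sq: float = SIGMA_N_SQ
    bin_ms: float = BIN_MS
    fit_log: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.taus_ms is not None:
            self.taus_ms = np.asarray(self.taus_ms, dtype=float)
            if np.any(self.taus_ms <= 0):
                raise ValueError("taus_ms must be positive")
            if self.taus_ms.shape != (self.C.shape[1],):
                raise ValueError("one tau per latent factor required")
        if np.any(self.R <= 0):
            raise ValueError("R entries must be positive")

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]

    @property
    def n_factors(self) -> int:
        return self.C.shape[1]


@dataclass
class LatentTrajectories:
    """Posterior-mean latent paths, (E, p, T).

    When ``ortho`` the paths are orthonormalized: ``U`` carries the orthonormal
    loading columns (ordered by covariance explained, descending singular
    value ``D_diag``) and ``U @ paths[e] == C @ raw_paths[e]`` exactly.
    """

    paths: np.ndarray
    ortho: bool = False
    U: np.ndarray | None = None
    D_diag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.paths = np.asarray(self.paths, dtype=float)
        if self.paths.ndim != 3:
            raise ValueError("paths must be (E, p, T)")
        if self.ortho:
            if self.U is None or self.D_diag is None:
                raise ValueError("orthonormalized trajectories need U and D_diag")
            if not np.allclose(self.U.T @ self.U, np.eye(self.U.shape[1]), atol=1e-8):
                raise ValueError("U columns must be orthonormal")
            if np.any(np.diff(self.D_diag) > 1e-12):
                raise ValueError("factors must be ordered by descending singular value")


@dataclass
class RMSECurve:
    """Leave-one-channel-out class-balanced RMSE vs latent dimensionality."""

    dimensions: np.ndarray
    rmse_fa: np.ndarray  # (n_dims,) fold means
    rmse_gpfa: np.ndarray
    rmse_reduced: np.ndarray
    fold_se: dict[str, np.ndarray] = field(default_factory=dict)
    per_fold: dict[str, np.ndarray] = field(default_factory=dict)  # (n_folds, n_dims)

    def __post_init__(self) -> None:
        self.dimensions = np.asarray(self.dimensions, dtype=int)
        if np.any(np.diff(self.dimensions) <= 0):
            raise ValueError("dimensions must be strictly increasing")


# --------------------------------------------------------------------------- #
# FA baseline
# --------------------------------------------------------------------------- #

def fa_fit(
    epochs: np.ndarray,
    p: int,
    pre_smooth_ms: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> GPFAParams:
    """Plain factor analysis on bins pooled across time (``taus_ms=None``).

    ``pre_smooth_ms`` optionally smooths each epoch along time with a Gaussian
    kernel of that standard deviation before fitting (the "smoothed-FA"
    control); 0 or None means no smoothing.  ``p=0`` returns the pure
    diagonal-noise model.
    """
    epochs = np.asarray(epochs, dtype=float)
    E, q, T = epochs.shape
    if p >= q:
        raise ValueError("latent dimensionality p must be < q")
    if pre_smooth_ms:
        from scipy.ndimage import gaussian_filter1d

        epochs = gaussian_filter1d(epochs, sigma=pre_smooth_ms / BIN_MS, axis=2, mode="nearest")
    X = epochs.transpose(0, 2, 1).reshape(-1, q)  # samples x channels
    if p == 0:
        return GPFAParams(
            C=np.zeros((q, 0)),
            d=X.mean(axis=0),
            R=np.maximum(X.var(axis=0), 1e-12),
            taus_ms=None,
        )
    fa = FactorAnalysis(
        n_components=p, tol=tol, max_iter=max_iter, svd_method="lapack", random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence warning handled below
        fa.fit(X)
    converged = fa.n_iter_ < max_iter
    if not converged:
        logger.info("FA stopped at the %d-iteration cap", max_iter)
    return GPFAParams(
        C=fa.components_.T,
        d=fa.mean_,
        R=np.maximum(fa.noise_variance_, 1e-12),
        taus_ms=None,
        fit_log=np.asarray(fa.loglike_),
        converged=converged,
    )


# --------------------------------------------------------------------------- #
# posterior machinery
# --------------------------------------------------------------------------- #

class _PosteriorEngine:
    """Precomputed posterior solver for one parameter set and epoch length.

    Latents are vectorized factor-major (factor i occupies rows iT..(i+1)T);
    the posterior precision is Lambda = blockdiag(K_i^{-1}) + (C' R^{-1} C)
    placed as T x T identity-scaled blocks.  The posterior covariance is
    shared by all epochs of length T; only the mean depends on the data.
    ``channel_idx`` restricts the observation model to a channel subset
    (used for leave-one-channel-out prediction).
    """

    def __init__(self, params: GPFAParams, T: int, channel_idx: np.ndarray | None = None):
        C, d, R = params.C, params.d, params.R
        if channel_idx is not None:
            C, d, R = C[channel_idx], d[channel_idx], R[channel_idx]
        self.params = params
        self.T = T
        self.C, self.d, self.R = C, d, R
        self.p = C.shape[1]
        self.CRinv = C.T / R  # (p, q_sub)
        A = self.CRinv @ C  # (p, p)
        self.fa = params.taus_ms is None

        if self.fa:
            M = np.eye(self.p) + A
            self._cho = cho_factor(M, lower=True)
            self._logdet_lam = 2.0 * np.log(np.diag(self._cho[0])).sum()
            self._logdet_K = 0.0
        else:
            p, t = self.p, T
            self._logdet_K = 0.0
            lam = np.zeros((p * t, p * t))
            for i, tau in enumerate(params.taus_ms):
                K = gp_kernel(tau, t, params.bin_ms, params.sigma_n_sq)
                cK = cho_factor(K, lower=True)
                self._logdet_K += 2.0 * np.log(np.diag(cK[0])).sum()
                lam[i * t : (i + 1) * t, i * t : (i + 1) * t] = cho_solve(cK, np.eye(t))
            idx = np.arange(t)
            for i in range(p):
                for j in range(p):
                    lam[i * t + idx, j * t + idx] += A[i, j]
            self._cho = cho_factor(lam, lower=True)
            self._logdet_lam = 2.0 * np.log(np.diag(self._cho[0])).sum()

    # -- posterior moments ------------------------------------------------- #

    def mean(self, Y: np.ndarray) -> np.ndarray:
        """Posterior mean E[x|y] for one epoch (q_sub, T) -> (p, T)."""
        B = self.CRinv @ (Y - self.d[:, None])  # (p, T)
        if self.fa:
            return cho_solve(self._cho, B)
        mu = cho_solve(self._cho, B.reshape(-1))
        return mu.reshape(self.p, self.T)

    def covariance(self) -> np.ndarray:
        """Posterior covariance, (pT, pT) factor-major (or (p, p) for FA)."""
        n = self.p if self.fa else self.p * self.T
        return cho_solve(self._cho, np.eye(n))

    # -- log-likelihood ---------------------------------------------------- #

    def loglik(self, epochs: np.ndarray) -> float:
        """Exact data log-likelihood of (E, q_sub, T) epochs under the model."""
        E, q, T = epochs.shape
        logdet_R = np.log(self.R).sum()
        total = 0.0
        if self.fa:
            const = q * np.log(2 * np.pi) + logdet_R + self._logdet_lam
            for Y in epochs:
                Z = Y - self.d[:, None]
                B = self.CRinv @ Z
                quad = np.sum(Z**2 / self.R[:, None]) - np.sum(B * cho_solve(self._cho, B))
                total += -0.5 * (T * const + quad)
            return total
        const = T * (q * np.log(2 * np.pi) + logdet_R) + self._logdet_K + self._logdet_lam
        for Y in epochs:
            Z = Y - self.d[:, None]
            b = (self.CRinv @ Z).reshape(-1)
            quad = np.sum(Z**2 / self.R[:, None]) - b @ cho_solve(self._cho, b)
            total += -0.5 * (const + quad)
        return total


def gpfa_posterior(params: GPFAParams, epoch: np.ndarray) -> np.ndarray:
    """Posterior expectation E[x|y] of the latent path for one (q, T) epoch."""
    epoch = np.asarray(epoch, dtype=float)
    return _PosteriorEngine(params, epoch.shape[1]).mean(epoch)


def infer_latents(params: GPFAParams, epochs: np.ndarray) -> LatentTrajectories:
    """Posterior-mean latent trajectories for a stack of (E, q, T) epochs."""
    epochs = np.asarray(epochs, dtype=float)
    eng = _PosteriorEngine(params, epochs.shape[2])
    return LatentTrajectories(np.stack([eng.mean(Y) for Y in epochs]))


def loglik(params: GPFAParams, epochs: np.ndarray) -> float:
    """Data log-likelihood of (E, q, T) epochs under a fitted model."""
    epochs = np.asarray(epochs, dtype=float)
    return _PosteriorEngine(params, epochs.shape[2]).loglik(epochs)


# --------------------------------------------------------------------------- #
# EM fitting
# --------------------------------------------------------------------------- #

TAU_INIT_BASE_MS = 500.0


def _default_tau_init(p: int) -> np.ndarray:
    """500, 1000, 2000, ... ms, cycling over octaves for large p."""
    return TAU_INIT_BASE_MS * 2.0 ** (np.arange(p) % 6)


def _optimize_tau(W: np.ndarray, n_draws: int, bin_ms: float, sigma_n_sq: float, lo: float, hi: float) -> float:
    """Maximize -1/2 (n log|K(tau)| + tr(K^{-1} W)) over tau in [lo, hi] (log-space)."""
    T = W.shape[0]

    def neg(log_tau: float) -> float:
        K = gp_kernel(np.exp(log_tau), T, bin_ms, sigma_n_sq)
        cK = cho_factor(K, lower=True)
        logdet = 2.0 * np.log(np.diag(cK[0])).sum()
        return 0.5 * (n_draws * logdet + np.trace(cho_solve(cK, W)))

    res = minimize_scalar(
        neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-3, "maxiter": 60},
    )
    return float(np.exp(res.x))


def gpfa_fit_em(
    epochs: np.ndarray,
    p: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    sigma_n_sq: float = SIGMA_N_SQ,
    bin_ms: float = BIN_MS,
    taus_init: np.ndarray | None = None,
    fit_taus: bool = True,
    fa_init_iter: int = 200,
) -> GPFAParams:
    """Fit GPFA by EM on (E, q, T) epochs.

    C, d, R are initialized from an FA fit and taus from an octave ladder
    (500, 1000, 2000, ... ms).  Each iteration runs the exact E-step, the
    closed-form M-step for (C, d, R), and per-factor numerical maximization of
    the expected log-likelihood over tau (a generalized EM step, so the data
    log-likelihood recorded in ``fit_log`` is monotone).  Convergence: relative
    log-likelihood gain below ``tol``.
    """
    epochs = np.asarray(epochs, dtype=float)
    E, q, T = epochs.shape
    if p >= q:
        raise ValueError("latent dimensionality p must be < q")
    if E * T <= q:
        raise ValueError("need more bins than channels to fit")

    init = fa_fit(epochs, p, max_iter=fa_init_iter, seed=seed)
    C, d, R = init.C.copy(), init.d.copy(), init.R.copy()
    taus = np.asarray(taus_init, float).copy() if taus_init is not None else _default_tau_init(p)
    if taus.shape != (p,):
        raise ValueError("taus_init must have length p")

    channel_var = np.maximum(epochs.var(axis=(0, 2)), 1e-12)
    r_floor = 1e-8 * channel_var
    tau_lo, tau_hi = bin_ms / 2.0, 100.0 * T * bin_ms

    Ymat = epochs  # (E, q, T)
    s_y = Ymat.sum(axis=(0, 2))  # (q,)
    S_yy_diag = np.sum(Ymat**2, axis=(0, 2))  # (q,)
    N = E * T
    idxT = np.arange(T)

    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        params = GPFAParams(C, d, R, taus, sigma_n_sq, bin_ms)
        eng = _PosteriorEngine(params, T)

        # ---- E-step ------------------------------------------------------ #
        Sigma = eng.covariance()  # (pT, pT)
        mus = np.stack([eng.mean(Y).reshape(-1) for Y in Ymat])  # (E, pT)
        big = E * Sigma + mus.T @ mus  # sum of E[x x'] over epochs
        big4 = big.reshape(p, T, p, T)

        lls.append(eng.loglik(Ymat))
        if len(lls) > 1:
            gain = lls[-1] - lls[-2]
            if gain < -1e-6 * abs(lls[-2]):
                logger.warning("log-likelihood decreased by %.3g", -gain)
            if gain < tol * abs(lls[-2]):
                converged = True
                break

        # ---- M-step: C, d, R --------------------------------------------- #
        S_xx = np.einsum("itjt->ij", big4)  # (p, p) summed over epochs & time
        s_x = mus.reshape(E, p, T).sum(axis=(0, 2))  # (p,)
        Mu = mus.reshape(E, p, T)
        S_yx = np.einsum("eqt,ept->qp", Ymat, Mu)  # (q, p)

        G = np.empty((p + 1, p + 1))
        G[:p, :p], G[:p, p], G[p, :p], G[p, p] = S_xx, s_x, s_x, N
        H = np.concatenate([S_yx, s_y[:, None]], axis=1)  # (q, p+1)
        Cd = np.linalg.solve(G.T, H.T).T  # (q, p+1)
        C, d = Cd[:, :p], Cd[:, p]
        R = np.maximum((S_yy_diag - np.einsum("qk,qk->q", Cd, H)) / N, r_floor)

        # ---- M-step: taus ------------------------------------------------- #
        if fit_taus:
            for i in range(p):
                W = big4[i, :, i, :]
                taus[i] = _optimize_tau(W, E, bin_ms, sigma_n_sq, tau_lo, tau_hi)

    if not converged:
        logger.info("GPFA EM stopped at the %d-iteration cap", max_iter)
    return GPFAParams(
        C, d, R, taus, sigma_n_sq, bin_ms, fit_log=np.asarray(lls), converged=converged
    )


# --------------------------------------------------------------------------- #
# orthonormalization ("reduced GPFA")
# --------------------------------------------------------------------------- #

def orthonormalize(params: GPFAParams, trajs: LatentTrajectories) -> LatentTrajectories:
    """Orthonormalize latent trajectories through the SVD of the loading.

    C = U D V'; the transformed paths x~ = D V' x satisfy U x~ = C x exactly,
    and the columns of U (orthonormal spatial factors) are ordered by the
    covariance they explain (descending singular values).  The sign of each
    column is fixed so its largest-magnitude entry is positive.  Zero singular
    directions of a rank-deficient loading are dropped with a warning.
    """
    U, s, Vt = np.linalg.svd(params.C, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size else np.zeros(0, bool)
    if not keep.all():
        warnings.warn(f"loading matrix rank-deficient; dropping {int((~keep).sum())} factor(s)")
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    U = U * flip
    DVt = (s[:, None] * Vt) * flip[:, None]
    paths = np.einsum("ij,ejt->eit", DVt, trajs.paths)
    return LatentTrajectories(paths, ortho=True, U=U, D_diag=s)


# --------------------------------------------------------------------------- #
# leave-one-channel-out prediction error
# --------------------------------------------------------------------------- #

def loo_rmse(
    params: GPFAParams,
    epochs: np.ndarray,
    labels: np.ndarray,
    reduced_m: int | None = None,
) -> float:
    """Class-balanced leave-one-channel-out RMSE.

    For each channel j, latents are inferred from the other q-1 channels and
    channel j is predicted as C_j E[x|y_-j] + d_j.  The RMSE (over all bins and
    held-out channels) is computed for each behavioral class separately and the
    class RMSEs are summed.  With ``reduced_m`` the prediction uses only the
    top-m orthonormalized factors of the fitted loading (reduced GPFA).
    """
    epochs = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    E, q, T = epochs.shape
    if reduced_m is not None:
        U, s, Vt = np.linalg.svd(params.C, full_matrices=False)
        U_m, DVt_m = U[:, :reduced_m], (s[:, None] * Vt)[:reduced_m]

    sq_err = {c: 0.0 for c in np.unique(labels)}
    n_obs = {c: 0 for c in np.unique(labels)}
    for j in range(q):
        rest = np.array([i for i in range(q) if i != j])
        eng = _PosteriorEngine(params, T, channel_idx=rest)
        for Y, lab in zip(epochs, labels):
            x = eng.mean(Y[rest])
            if reduced_m is not None:
                pred = U_m[j] @ (DVt_m @ x) + params.d[j]
            else:
                pred = params.C[j] @ x + params.d[j]
            sq_err[lab] += float(np.sum((Y[j] - pred) ** 2))
            n_obs[lab] += T
    return float(sum(np.sqrt(sq_err[c] / n_obs[c]) for c in sq_err))


def rmse_curve(
    epochs: np.ndarray,
    labels: np.ndarray,
    plan: CVPlan,
    dims: list[int],
    seed: int = 0,
    p_full: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> RMSECurve:
    """FA vs GPFA vs reduced-GPFA prediction error across dimensionalities.

    Per fold: models are fit on the class-balanced training set; the
    class-balanced leave-one-channel-out RMSE is evaluated on the full
    (unbalanced) test fold.  Reduced GPFA truncates the orthonormalized
    loading of a single larger fit (``p_full``, default max(dims)).
    """
    dims = sorted(dims)
    labels = np.asarray(labels)
    p_full = p_full if p_full is not None else max(dims)
    per_fold = {k: np.zeros((plan.n_folds, len(dims))) for k in ("fa", "gpfa", "reduced")}

    for fold in range(plan.n_folds):
        rng = np.random.default_rng([seed, fold])
        train = balance_classes(plan.train_indices(fold), labels, rng)
        test = plan.test_indices(fold)
        Y_tr, Y_te, lab_te = epochs[train], epochs[test], labels[test]

        full = gpfa_fit_em(Y_tr, p_full, max_iter=max_iter, tol=tol, seed=seed)
        for di, pdim in enumerate(dims):
            fa = fa_fit(Y_tr, pdim, seed=seed)
            per_fold["fa"][fold, di] = loo_rmse(fa, Y_te, lab_te)
            if pdim == p_full:
                gp = full
            else:
                gp = gpfa_fit_em(Y_tr, pdim, max_iter=max_iter, tol=tol, seed=seed)
            per_fold["gpfa"][fold, di] = loo_rmse(gp, Y_te, lab_te)
            per_fold["reduced"][fold, di] = loo_rmse(full, Y_te, lab_te, reduced_m=pdim)

    se = {k: v.std(axis=0, ddof=1) / np.sqrt(plan.n_folds) for k, v in per_fold.items()}
    return RMSECurve(
        dimensions=np.asarray(dims),
        rmse_fa=per_fold["fa"].mean(axis=0),
        rmse_gpfa=per_fold["gpfa"].mean(axis=0),
        rmse_reduced=per_fold["reduced"].mean(axis=0),
        fold_se=se,
        per_fold=per_fold,
    )


# --------------------------------------------------------------------------- #
# decoding from latent trajectories
# --------------------------------------------------------------------------- #

@dataclass
class FoldLatents:
    """Per-fold refit GPFA latents, sorted slowest -> fastest."""

    taus_ms: np.ndarray  # (p,) descending
    train_trajs: np.ndarray  # (n_train, p, T)
    test_trajs: np.ndarray  # (n_test, p, T)
    train_idx: np.ndarray
    test_idx: np.ndarray
    params: GPFAParams


def fit_fold_latents(
    epochs: np.ndarray,
    labels: np.ndarray,
    plan: CVPlan,
    p: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> list[FoldLatents]:
    """Refit GPFA per fold (balanced training set) and infer latents.

    Factors are sorted by fitted timescale, slowest first, so factor rank is
    comparable across folds.  Test latents are inferred for the class-balanced
    test set used by the decoding curves.
    """
    labels = np.asarray(labels)
    out = []
    for fold in range(plan.n_folds):
        rng = np.random.default_rng([seed, fold])
        train = balance_classes(plan.train_indices(fold), labels, rng)
        test = balance_classes(plan.test_indices(fold), labels, rng)
        params = gpfa_fit_em(epochs[train], p, max_iter=max_iter, tol=tol, seed=seed)
        order = np.argsort(-params.taus_ms, kind="stable")
        params = replace(
            params, C=params.C[:, order], taus_ms=params.taus_ms[order], fit_log=params.fit_log
        )
        eng = _PosteriorEngine(params, epochs.shape[2])
        out.append(
            FoldLatents(
                taus_ms=params.taus_ms,
                train_trajs=np.stack([eng.mean(Y) for Y in epochs[train]]),
                test_trajs=np.stack([eng.mean(Y) for Y in epochs[test]]),
                train_idx=train,
                test_idx=test,
                params=params,
            )
        )
    return out


def factor_decoding_curve(
    folds: list[FoldLatents],
    labels: np.ndarray,
    order: str = "slow_first",
    shared_covariance: bool = False,
) -> DecodingResult:
    """Accuracy vs number of latent factors, added slowest- or fastest-first.

    For m = 1..p the constrained Gaussian classifier is trained and tested on
    the first m factors in the requested order; fold accuracies are stacked as
    ``per_fold`` of shape (n_folds, p).
    """
    if order not in ("slow_first", "fast_first"):
        raise ValueError("order must be 'slow_first' or 'fast_first'")
    labels = np.asarray(labels)
    p = folds[0].taus_ms.size
    accs = np.zeros((len(folds), p))
    ns = []
    for fi, fl in enumerate(folds):
        ranks = np.arange(p) if order == "slow_first" else np.arange(p)[::-1]
        for m in range(1, p + 1):
            sel = np.sort(ranks[:m])
            model = ConstrainedGaussianModel.fit(
                fl.train_trajs[:, sel], labels[fl.train_idx], shared_covariance
            )
            pred = model.predict(fl.test_trajs[:, sel])
            accs[fi, m - 1] = np.mean(pred == labels[fl.test_idx])
        ns.append(fl.test_idx.size)
    return DecodingResult(accs, np.asarray(ns), np.unique(labels).size)


def single_factor_decoding(
    folds: list[FoldLatents], labels: np.ndarray, shared_covariance: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Accuracy of each latent factor alone, rank-aligned across folds.

    Factors are sorted slowest to fastest within each fold; the k-th slowest
    factor's accuracy is averaged across folds.  Returns ``(mean_taus_ms,
    mean_accuracy)`` both ordered slowest -> fastest.
    """
    labels = np.asarray(labels)
    p = folds[0].taus_ms.size
    accs = np.zeros((len(folds), p))
    taus = np.zeros((len(folds), p))
    for fi, fl in enumerate(folds):
        taus[fi] = fl.taus_ms
        for i in range(p):
            model = ConstrainedGaussianModel.fit(
                fl.train_trajs[:, [i]], labels[fl.train_idx], shared_covariance
            )
            pred = model.predict(fl.test_trajs[:, [i]])
            accs[fi, i] = np.mean(pred == labels[fl.test_idx])
    return taus.mean(axis=0), accs.mean(axis=0)
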