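"""Decoders for behavioral-state classification.

Three families, matching the feature families they consume:

* a linear multi-class SVM (one-versus-one voting) on epoch feature vectors,
* a minimum-distance-to-mean (MDM) classifier on epoch covariance matrices
  with the Euclidean (Frobenius) mean and distance,
* a constrained Gaussian classifier on vectorized latent trajectories: the
  class mean is static in time and the class covariance is block-diagonal
  (one shared p x p block per time step), which makes the (pT)-dimensional
  Gaussian tractable as a sum of per-bin log-densities.  With per-class
  covariances this is a constrained QDA; with a pooled covariance it is the
  LDA control.

All evaluation runs through the buffered blocked CV plan with class-balanced
training and test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .validation import CVPlan, balance_classes

logger = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    """Per-fold balanced-test accuracies of one decoder run."""

    per_fold: np.ndarray  # fraction correct per fold
    n_test_per_fold: np.ndarray
    n_classes: int

    @property
    def mean_pct(self) -> float:
        return 100.0 * float(self.per_fold.mean())

    @property
    def se_pct(self) -> float:
        if self.per_fold.size < 2:
            return float("nan")
        return 100.0 * float(self.per_fold.std(ddof=1) / np.sqrt(self.per_fold.size))

    @property
    def n_balanced_total(self) -> int:
        return int(self.n_test_per_fold.sum())


def evaluate_folds(
    labels: np.ndarray,
    plan: CVPlan,
    fit_predict,
    seed: int = 0,
    balance_test: bool = True,
) -> DecodingResult:
    """Run a fit/predict callable over every fold of a buffered CV plan.

    ``fit_predict(train_idx, test_idx) -> predicted labels`` receives
    class-balanced index sets (balancing is seeded per fold).  Returns
    per-fold accuracies.
    """
    labels = np.asarray(labels)
    accs, ns = [], []
    for fold in range(plan.n_folds):
        rng = np.random.default_rng([seed, fold])
        train = balance_classes(plan.train_indices(fold), labels, rng)
        test = plan.test_indices(fold)
        if balance_test:
            test = balance_classes(test, labels, rng)
        pred = np.asarray(fit_predict(train, test))
        accs.append(np.mean(pred == labels[test]))
        ns.append(test.size)
    return DecodingResult(np.asarray(accs), np.asarray(ns), np.unique(labels).size)


# --------------------------------------------------------------------------- #
# linear SVM on feature vectors
# --------------------------------------------------------------------------- #

def train_eval_svm(
    features: np.ndarray,
    labels: np.ndarray,
    plan: CVPlan,
    seed: int = 0,
    C: float = 1.0,
    standardize: bool = True,
) -> DecodingResult:
    """Linear one-versus-one SVM under buffered blocked CV.

    Features are standardized per fold using training-set statistics (set
    ``standardize=False`` to disable).
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")

    def fit_predict(train, test):
        X_tr, X_te = features[train], features[test]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(X_tr, labels[train])
        return clf.predict(X_te)

    return evaluate_folds(labels, plan, fit_predict, seed=seed)


# --------------------------------------------------------------------------- #
# minimum distance to mean on covariance matrices
# --------------------------------------------------------------------------- #

@dataclass
class MDMModel:
    """Class-mean covariance matrices (Euclidean/arithmetic mean)."""

    classes: np.ndarray
    class_means: np.ndarray  # (n_classes, q, q)

    @classmethod
    def fit(cls, matrices: np.ndarray, labels: np.ndarray) -> "MDMModel":
        labels = np.asarray(labels)
        classes = np.unique(labels)
        means = np.stack([matrices[labels == c].mean(axis=0) for c in classes])
        return cls(classes, means)

    def predict(self, matrices: np.ndarray) -> np.ndarray:
        """Assign each matrix to the class with nearest Frobenius-mean.

        Ties go to the first class in canonical (sorted) order.
        """
        diffs = matrices[:, None] - self.class_means[None]
        dists = np.linalg.norm(diffs.reshape(matrices.shape[0], self.classes.size, -1), axis=2)
        ties = (dists == dists.min(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            logger.info("MDM tie on %d instance(s); first class wins", int(ties.sum()))
        return self.classes[np.argmin(dists, axis=1)]


def train_eval_mdm(
    matrices: np.ndarray, labels: np.ndarray, plan: CVPlan, seed: int = 0
) -> DecodingResult:
    """Minimum-distance-to-mean decoding of epoch covariances under blocked CV."""
    matrices = np.asarray(matrices, dtype=float)
    if not np.allclose(matrices, matrices.transpose(0, 2, 1), atol=1e-8):
        raise ValueError("covariance matrices must be symmetric")

    def fit_predict(train, test):
        model = MDMModel.fit(matrices[train], labels[train])
        return model.predict(matrices[test])

    return evaluate_folds(labels, plan, fit_predict, seed=seed)


# --------------------------------------------------------------------------- #
# constrained Gaussian (QDA/LDA) on latent trajectories
# --------------------------------------------------------------------------- #

@dataclass
class ConstrainedGaussianModel:
    """Gaussian classifier over vectorized (p x T) latent trajectories.

    The vectorized class mean tiles a static p-vector across time; the
    vectorized class covariance is block-diagonal with the same p x p block at
    every time step (time points treated as independent).  ``shared_covariance``
    pools one block across classes (the LDA control).
    """

    classes: np.ndarray
    means: np.ndarray  # (n_classes, p)
    covs: np.ndarray  # (n_classes, p, p); identical blocks when shared
    shared_covariance: bool = False

    @classmethod
    def fit(
        cls,
        trajs: np.ndarray,
        labels: np.ndarray,
        shared_covariance: bool = False,
        ridge_rel: float = 1e-6,
    ) -> "ConstrainedGaussianModel":
        """Fit from (E, p, T) latent trajectories.

        Per class: the mean over all bins of all its epochs, and the sample
        covariance of the p-dimensional bins pooled across the concatenated
        class epochs.  A singular covariance is ridge-regularized by
        ``ridge_rel * trace / p`` on the diagonal.
        """
        trajs = np.asarray(trajs, dtype=float)
        labels = np.asarray(labels)
        classes = np.unique(labels)
        counts = {c: int((labels == c).sum()) for c in classes}
        if any(n < 2 for n in counts.values()):
            raise ValueError("need at least 2 epochs per class")
        p = trajs.shape[1]
        means, covs = [], []
        for c in classes:
            X = trajs[labels == c].transpose(1, 0, 2).reshape(p, -1)  # p x (T*E_c)
            means.append(X.mean(axis=1))
            covs.append(np.atleast_2d(np.cov(X, ddof=1)))
        means, covs = np.stack(means), np.stack(covs)
        if shared_covariance:
            n_bins = np.array([counts[c] for c in classes], dtype=float)
            pooled = np.einsum("c,cij->ij", n_bins / n_bins.sum(), covs)
            covs = np.broadcast_to(pooled, covs.shape).copy()
        for i in range(covs.shape[0]):
            covs[i] = _ensure_pd(covs[i], ridge_rel)
        return cls(classes, means, covs, shared_covariance)

    def log_scores(self, traj: np.ndarray) -> np.ndarray:
        """Per-class log-density of one (p, T) trajectory plus log prior.

        Equals the full (pT)-dimensional Gaussian log-density with tiled mean
        and block-diagonal covariance, computed as a sum over time bins.
        Priors are uniform.
        """
        traj = np.atleast_2d(np.asarray(traj, dtype=float))
        if traj.shape[0] != self.means.shape[1]:
            raise ValueError("trajectory dimensionality does not match the model")
        p, T = traj.shape
        scores = np.empty(self.classes.size)
        for i in range(self.classes.size):
            z = traj - self.means[i][:, None]
            cho = cho_factor(self.covs[i], lower=True)
            logdet = 2.0 * np.log(np.diag(cho[0])).sum()
            quad = float(np.sum(z * cho_solve(cho, z)))
            scores[i] = -0.5 * (T * (p * np.log(2 * np.pi) + logdet) + quad)
        return scores - np.log(self.classes.size)

    def predict(self, trajs: np.ndarray) -> np.ndarray:
        """Argmax class per (p, T) trajectory; ties go to the first class."""
        trajs = np.asarray(trajs, dtype=float)
        if trajs.ndim == 2:
            trajs = trajs[None]
        out = [self.classes[int(np.argmax(self.log_scores(t)))] for t in trajs]
        return np.asarray(out)


def _ensure_pd(cov: np.ndarray, ridge_rel: float) -> np.ndarray:
    """Return ``cov`` made positive definite by a relative ridge if needed."""
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        lam = ridge_rel * np.trace(cov) / cov.shape[0]
        lam = max(lam, ridge_rel)
        logger.info("singular class covariance; adding ridge %.3g", lam)
        return cov + lam * np.eye(cov.shape[0])
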