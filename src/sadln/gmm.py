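"""Gaussian mixture clustering of the integrated representation.

Subtypes are the maximum-posterior components of a full-covariance
Gaussian mixture fitted to Z by expectation-maximization. The EM here is
in-package so the per-iteration log-likelihood trace is observable (it
must be non-decreasing); means are seeded by k-means++ with multiple
restarts and the best final log-likelihood kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import adjusted_rand_score

__all__ = ["GmmFit", "ClusterAssignment", "gmm_fit", "gmm_assign", "ari"]


@dataclass
class GmmFit:
    """Fitted mixture: weights, components, posteriors and the EM trace."""

    K: int
    pi: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    converged: bool

    def bic(self, n: int | None = None) -> float:
        """Bayesian information criterion (report-only; K is user-supplied)."""
        n = n if n is not None else self.responsibilities.shape[0]
        d = self.means.shape[1]
        n_params = self.K - 1 + self.K * d + self.K * d * (d + 1) / 2
        return float(n_params * np.log(n) - 2.0 * self.loglik_trace[-1] * n)


@dataclass
class ClusterAssignment:
    """Max-posterior subtype labels, 1-based; ties go to the lowest index."""

    sample_ids: list[str]
    labels: np.ndarray
    max_posterior: np.ndarray


def _log_gaussians(z: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """N x K matrix of component log-densities via Cholesky factors."""
    n, d = z.shape
    out = np.empty((n, len(means)))
    for k in range(len(means)):
        try:
            chol, lower = cho_factor(covs[k], lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"component {k}: covariance not positive definite") from exc
        diff = (z - means[k]).T
        sol = cho_solve((chol, lower), diff)
        maha = np.sum(diff * sol, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _e_step(z, pi, means, covs):
    logp = _log_gaussians(z, means, covs) + np.log(pi)
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    resp = np.exp(logp - lse[:, None])
    return resp, float(lse.mean())


def _m_step(z, resp, ridge):
    nk = resp.sum(axis=0)
    pi = nk / len(z)
    means = (resp.T @ z) / nk[:, None]
    d = z.shape[1]
    covs = np.empty((len(nk), d, d))
    for k in range(len(nk)):
        diff = z - means[k]
        covs[k] = (resp[:, k] * diff.T) @ diff / nk[k]
        covs[k].flat[:: d + 1] += ridge
    return pi, means, covs


def gmm_fit(
    z: np.ndarray,
    K: int,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-4,
    seed: int | None = 0,
    ridge: float = 1e-6,
) -> GmmFit:
    """Fit a K-component full-covariance Gaussian mixture to Z by EM.

    Each restart seeds the means by k-means++, hard-assigns every sample to
    its nearest seed to form initial responsibilities, takes one M-step, and
    then iterates EM until the mean log-likelihood gain drops below ``tol``.
    The restart with the best final log-likelihood wins. The log-likelihood
    reported is the per-sample mean.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if K >= n:
        raise ValueError(f"need more samples than components (N={n}, K={K})")
    if not np.all(np.isfinite(z)):
        raise ValueError("Z contains non-finite values")
    rng = np.random.default_rng(seed)

    pooled = np.cov(z, rowvar=False, ddof=0).reshape(z.shape[1], z.shape[1]).copy()
    pooled.flat[:: z.shape[1] + 1] += ridge

    best: GmmFit | None = None
    for _ in range(n_init):
        if K == 1:
            pi = np.ones(1)
            means = z.mean(axis=0, keepdims=True)
            covs = pooled[None].copy()
        else:
            seeds, _ = kmeans_plusplus(z, n_clusters=K, random_state=int(rng.integers(2**31 - 1)))
            # hard-assign to the nearest seed; empty seeds keep a uniform sliver
            d2 = ((z[:, None, :] - seeds[None]) ** 2).sum(axis=2)
            resp0 = np.zeros((n, K))
            resp0[np.arange(n), d2.argmin(axis=1)] = 1.0
            resp0 = resp0 * (1 - 1e-6 * K) + 1e-6
            pi, means, covs = _m_step(z, resp0, ridge)

        trace = []
        converged = False
        resp = None
        for _ in range(max_iter):
            resp, ll = _e_step(z, pi, means, covs)
            trace.append(ll)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                converged = True
                break
            pi, means, covs = _m_step(z, resp, ridge)

        fit = GmmFit(K, pi, means, covs, resp, np.asarray(trace), converged)
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    return best


def gmm_assign(fit: GmmFit, sample_ids: list[str]) -> ClusterAssignment:
    """Assign each sample to its maximum-posterior component (1-based)."""
    labels = np.argmax(fit.responsibilities, axis=1) + 1
    max_post = fit.responsibilities[np.arange(len(labels)), labels - 1]
    return ClusterAssignment(list(sample_ids), labels, max_post)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (pair-counting formula)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
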