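"""Binomial logistic regression by Newton iteration, with a Firth option.

The maximum-likelihood fit uses iteratively reweighted least squares
(Newton scoring with step halving).  Under complete or quasi separation the
MLE diverges; the bias-reduced (Firth) fit penalizes the likelihood with
the Jeffreys prior, adding h_i (1/2 - p_i) x_i to the score, and always has
a finite maximizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogisticFit", "fit_logistic"]


@dataclass
class LogisticFit:
    coef: np.ndarray
    converged: bool
    n_iter: int
    firth: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def diverged(self) -> bool:
        return (not self.converged) or bool(np.abs(self.coef).max() > 15.0)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth: bool = False,
) -> LogisticFit:
    """Fit P(y=1) = logit^{-1}(X beta).

    ``X`` must contain its own intercept column.  Convergence is declared
    when the score (Firth: modified score) has max-norm below ``tol`` or
    the step is numerically null.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        if firth:
            # hat diagonal of the weighted design
            try:
                winv = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                winv = np.linalg.pinv(info)
            h = np.einsum("ij,jk,ik->i", X * w[:, None], winv, X)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        if np.abs(score).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step halving against overshoot
        if np.abs(step).max() > 5.0:
            step *= 5.0 / np.abs(step).max()
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    return LogisticFit(coef=beta, converged=converged, n_iter=it, firth=firth)
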