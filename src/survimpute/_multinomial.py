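"""Ridge-penalized multinomial logistic regression by damped Newton.

Internal engine for the FCS conditional models.  The fixed ridge penalty keeps
the fit defined under perfect separation, and the penalized observed
information doubles as the normal approximation from which coefficient
perturbations are drawn (proper imputation).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular


class MultinomialFitError(RuntimeError):
    pass


class RidgeMultinomial:
    """Softmax regression with K classes (class 0 baseline) and ridge penalty.

    Parameters are Theta with shape (K-1, p); the design X must already carry
    an intercept column (the penalty applies to every entry, which is what
    keeps separated fits finite)."""

    def __init__(self, n_classes: int, ridge: float = 0.5, tol: float = 1e-6,
                 max_iter: int = 50):
        if n_classes < 2:
            raise ValueError("need >= 2 classes")
        self.K = n_classes
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter
        self.theta: np.ndarray | None = None
        self._chol = None

    def _probs(self, X: np.ndarray, theta: np.ndarray) -> np.ndarray:
        scores = np.zeros((X.shape[0], self.K))
        scores[:, 1:] = X @ theta.T
        scores -= scores.max(axis=1, keepdims=True)
        np.exp(scores, out=scores)
        scores /= scores.sum(axis=1, keepdims=True)
        return scores

    def _objective(self, X, Y, theta, w):
        scores = np.zeros((X.shape[0], self.K))
        scores[:, 1:] = X @ theta.T
        mx = scores.max(axis=1)
        lse = mx + np.log(np.exp(scores - mx[:, None]).sum(axis=1))
        ll = float(np.sum(w * (scores[np.arange(len(Y)), Y] - lse)))
        return ll - 0.5 * self.ridge * float(np.sum(theta**2))

    def fit(self, X: np.ndarray, y_codes: np.ndarray,
            warm_start: np.ndarray | None = None,
            sample_weight: np.ndarray | None = None) -> "RidgeMultinomial":
        n, p = X.shape
        Km1 = self.K - 1
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        sqw = np.sqrt(w)
        theta = (warm_start.copy() if warm_start is not None
                 else np.zeros((Km1, p)))
        obj = self._objective(X, y_codes, theta, w)
        Y_onehot = np.zeros((n, Km1))
        for k in range(1, self.K):
            Y_onehot[:, k - 1] = y_codes == k

        for _ in range(self.max_iter):
            P = self._probs(X, theta)
            Pk = P[:, 1:]  # n x (K-1)
            grad = X.T @ (w[:, None] * (Y_onehot - Pk)) - self.ridge * theta.T
            if np.max(np.abs(grad)) < self.tol * max(1.0, w.sum()):
                break
            H = self._hessian(X * sqw[:, None], Pk)
            g = grad.T.reshape(-1)  # (K-1)*p, ordered (class, column)
            try:
                c = cho_factor(H, lower=True, check_finite=False)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise MultinomialFitError("Hessian not positive definite") from exc
            step = cho_solve(c, g, check_finite=False).reshape(Km1, p)
            t = 1.0
            for _ in range(30):
                cand = theta + t * step
                obj_new = self._objective(X, y_codes, cand, w)
                if np.isfinite(obj_new) and obj_new >= obj - 1e-10 * max(1.0, abs(obj)):
                    break
                t *= 0.5
            else:
                raise MultinomialFitError("line search failed")
            theta = theta + t * step
            obj = obj_new
        else:
            P = self._probs(X, theta)
            grad = X.T @ (w[:, None] * (Y_onehot - P[:, 1:])) - self.ridge * theta.T
            if np.max(np.abs(grad)) > 1e-2 * max(1.0, w.sum()):
                raise MultinomialFitError("Newton did not converge")
        # factorize the penalized information at the final iterate (used for
        # the posterior coefficient draw)
        P = self._probs(X, theta)
        self._chol = cho_factor(self._hessian(X * sqw[:, None], P[:, 1:]),
                                lower=True, check_finite=False)
        self.theta = theta
        return self

    def _hessian(self, X: np.ndarray, Pk: np.ndarray) -> np.ndarray:
        """Penalized observed information, block (k,l) ordered (class, column):
        X' diag(p_k (delta_kl - p_l)) X + ridge*I, computed with matmuls.
        Row weights enter via pre-scaled X (rows times sqrt(w))."""
        n, p = X.shape
        Km1 = Pk.shape[1]
        C = (Pk[:, :, None] * X[:, None, :]).reshape(n, Km1 * p)
        H = -(C.T @ C)
        for k in range(Km1):
            sl = slice(k * p, (k + 1) * p)
            H[sl, sl] += X.T @ C[:, sl]
        H[np.arange(Km1 * p), np.arange(Km1 * p)] += self.ridge
        return H

    def sample_coefficients(self, rng: np.random.Generator) -> np.ndarray:
        """Draw Theta* ~ N(Theta_hat, H^-1) via the stored Cholesky factor."""
        if self.theta is None or self._chol is None:
            raise MultinomialFitError("fit first")
        Km1, p = self.theta.shape
        z = rng.standard_normal(Km1 * p)
        # H = L L'; draw = theta + L'^{-T} z has covariance H^{-1}
        L = np.tril(self._chol[0]) if self._chol[1] else np.triu(self._chol[0]).T
        draw = solve_triangular(L.T, z, lower=False, check_finite=False)
        return self.theta + draw.reshape(Km1, p)

    def predict_proba(self, X: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        th = self.theta if theta is None else theta
        if th is None:
            raise MultinomialFitError("fit first")
        return self._probs(X, th)
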