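"""Memory-lean IRLS fitting of logistic and log-link Poisson regressions.

The person-period datasets produced by four-week discretization of a large
cohort run to millions of rows; the normal equations are therefore
accumulated in row chunks so peak memory stays at roughly the size of the
design matrix itself.  Estimates are plain maximum likelihood (canonical
links), with the observed-information covariance ``(X'WX)^{-1}`` evaluated at
convergence; they agree with any standard GLM implementation to solver
tolerance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

__all__ = ["FitError", "GlmResult", "fit_glm"]

_CHUNK = 1_000_000
_ETA_CLIP = 30.0


class FitError(RuntimeError):
    """Raised when a regression cannot be fitted (separation, divergence,
    rank deficiency); never return silently wrong coefficients."""


@dataclasses.dataclass
class GlmResult:
    coefficients: np.ndarray
    covariance: np.ndarray
    deviance: float
    n_iter: int
    n_obs: int


def _normal_equations(X, w, z):
    """Accumulate X'WX and X'Wz in chunks."""
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for s in range(0, X.shape[0], _CHUNK):
        Xc = X[s : s + _CHUNK]
        Xw = Xc * w[s : s + _CHUNK, None]
        A += Xw.T @ Xc
        b += Xw.T @ z[s : s + _CHUNK]
    return A, b


def _deviance(y, mu, family):
    if family == "binomial":
        # y log(y/mu) + (1-y) log((1-y)/(1-mu)), with 0 log 0 = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return 2.0 * float(np.sum(t1 + t2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(t - (y - mu)))


def fit_glm(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    model_name: str = "glm",
) -> GlmResult:
    """Fit a canonical-link GLM (``family`` in {"binomial", "poisson"}) by IRLS.

    Convergence is on relative deviance change below ``tol``.  Raises
    :class:`FitError` on non-convergence or a singular information matrix.
    """
    if family not in ("binomial", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n == 0:
        raise FitError(f"{model_name}: no observations")

    beta = np.zeros(p)
    ybar = float(np.mean(y))
    if family == "binomial":
        ybar = min(max(ybar, 1e-10), 1 - 1e-10)
        beta[0] = np.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0
    else:
        beta[0] = np.log(max(ybar, 1e-10)) if np.allclose(X[:, 0], 1.0) else 0.0

    # staged warm start: recursively fit on a quarter systematic subsample so
    # each stage begins near its optimum and the full data needs only ~3
    # IRLS passes to reach the 1e-8 deviance tolerance
    if n > 1_200_000:
        try:
            sub = fit_glm(
                np.ascontiguousarray(X[::4]),
                y[::4],
                family,
                tol=1e-6,
                max_iter=max_iter,
                model_name=f"{model_name} (warm start)",
            )
            beta = sub.coefficients
        except FitError:
            pass  # fall back to the default start

    dev_old = np.inf
    A = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
        else:
            mu = np.exp(eta)
            w = mu
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        A, b = _normal_equations(X, w, z)
        try:
            c, low = scipy.linalg.cho_factor(A)
            beta = scipy.linalg.cho_solve((c, low), b)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                f"{model_name}: singular information matrix (collinear design)"
            ) from exc
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta)) if family == "binomial" else np.exp(eta)
        dev = _deviance(y, mu, family)
        if not np.isfinite(dev):
            raise FitError(f"{model_name}: deviance diverged (separation or bad data)")
        if abs(dev - dev_old) / (abs(dev) + 0.1) < tol:
            w = mu * (1.0 - mu) if family == "binomial" else mu
            A, _ = _normal_equations(X, np.maximum(w, 1e-12), z)
            try:
                cov = scipy.linalg.inv(A)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"{model_name}: singular information at optimum") from exc
            cov = (cov + cov.T) / 2.0
            return GlmResult(beta, cov, dev, it, n)
        dev_old = dev
    raise FitError(f"{model_name}: IRLS did not converge in {max_iter} iterations")
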