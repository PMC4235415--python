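"""Frequentist reference fit via spectral rotation and 1-D profile likelihood.

For the Gaussian model Var(y) = sigma_g^2 A + sigma_e^2 I, rotate each
family block by the eigenvectors of A_f: with A_f = U_f diag(d_f) U_f',
the rotated data y* = U_f' y_f have diagonal covariance
sigma_e^2 (1 + gamma d_i) where gamma = sigma_g^2 / sigma_e^2.  The
likelihood then factorizes over individuals, beta has a weighted
least-squares closed form, sigma_e^2 profiles out analytically, and only
the variance ratio gamma remains, maximized by bounded 1-D search on
log gamma.  This is the same eigendecomposition trick used by
spectrally transformed mixed-model software for fast REML, and serves
here as the deterministic cross-check for the MCMC estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .lmm import LMMSpec, heritability

__all__ = ["REMLResult", "fit_reml", "profile_loglik"]

_LOG_GAMMA_BOUNDS = (-10.0, 10.0)


@dataclass
class REMLResult:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    gamma: float
    loglik: float
    method: str
    covariate_names: list[str]
    boundary: bool = False
    non_identifiable: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Summary table mirroring a classical mixed-model printout: no SE
        is reported for variance components."""
        rows = {
            name: (b, se)
            for name, b, se in zip(self.covariate_names, self.beta, self.beta_se)
        }
        rows["Heritability"] = (self.h2, np.nan)
        rows["Residual variance"] = (self.sigma_e2, np.nan)
        rows["Genetic variance"] = (self.sigma_g2, np.nan)
        return pd.DataFrame(rows, index=["PE", "SE"]).T.rename_axis("parameter")


def _rotate(spec: LMMSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block eigen-rotation: returns (y*, X*, d) concatenated over blocks."""
    ys, Xs, ds = [], [], []
    for blk, sl in zip(spec.G.blocks, spec.off.slices()):
        A_f = blk @ blk.T
        d, U = np.linalg.eigh(A_f)
        ys.append(U.T @ spec.y[sl])
        Xs.append(U.T @ spec.X[sl])
        ds.append(np.clip(d, 0.0, None))
    return np.concatenate(ys), np.vstack(Xs), np.concatenate(ds)


def _profile(y, X, d, log_gamma: float, method: str):
    """Profile log-likelihood at fixed gamma; returns (ll, beta, cov_beta, s2e)."""
    n, p = X.shape
    gamma = np.exp(log_gamma)
    v = 1.0 + gamma * d  # variance in sigma_e^2 units
    w = 1.0 / v
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * y)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ beta
    rss = float(resid @ (w * resid))
    logdet_v = float(np.sum(np.log(v)))
    if method == "ML":
        s2e = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2e) + logdet_v + n)
    else:  # REML
        s2e = rss / (n - p)
        sign, logdet_i = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * s2e) + logdet_v + logdet_i + (n - p)
        )
    cov_beta = s2e * np.linalg.inv(XtWX)
    return ll, beta, cov_beta, s2e


def profile_loglik(spec: LMMSpec, gamma: float, method: str = "REML") -> float:
    """Profile (restricted) log-likelihood at variance ratio gamma."""
    y, X, d = _rotate(spec)
    return _profile(y, X, d, np.log(gamma), method)[0]


def fit_reml(spec: LMMSpec, method: str = "REML") -> REMLResult:
    """Maximize the profiled (restricted) likelihood over the variance ratio.

    Returns point estimates of beta (with asymptotic SEs from the inverse
    expected information), the variance components, and h^2.  A solution at
    the edge of the search box log(gamma) in [-10, 10] is flagged
    ``boundary`` (h^2 effectively 0 or 1); a relationship matrix that is
    numerically the identity leaves the two components confounded and is
    flagged ``non_identifiable``.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    y, X, d = _rotate(spec)
    if np.allclose(d, 1.0, atol=1e-10):
        warnings.warn(
            "relationship matrix is the identity: sigma_g^2 and sigma_e^2 are "
            "confounded and only their sum is estimable",
            RuntimeWarning,
            stacklevel=2,
        )

    def neg(lg: float) -> float:
        ll = _profile(y, X, d, lg, method)[0]
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite likelihood at log gamma = {lg}")
        return -ll

    res = minimize_scalar(neg, bounds=_LOG_GAMMA_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    lg = float(res.x)
    ll, beta, cov_beta, s2e = _profile(y, X, d, lg, method)
    gamma = float(np.exp(lg))
    boundary = lg < _LOG_GAMMA_BOUNDS[0] + 1e-3 or lg > _LOG_GAMMA_BOUNDS[1] - 1e-3
    if boundary:
        warnings.warn(
            "variance ratio at search boundary; heritability estimate is "
            "effectively 0 or 1",
            RuntimeWarning,
            stacklevel=2,
        )
    s2g = gamma * s2e
    return REMLResult(
        beta=beta,
        beta_se=np.sqrt(np.diag(cov_beta)),
        sigma_g2=s2g,
        sigma_e2=s2e,
        h2=heritability(s2g, s2e),
        gamma=gamma,
        loglik=float(ll),
        method=method,
        covariate_names=list(spec.covariate_names),
        boundary=boundary,
        non_identifiable=bool(np.allclose(d, 1.0, atol=1e-10)),
    )
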