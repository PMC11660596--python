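"""Shared variance-component machinery for the single-kinship mixed model.

Model: y = X b + g + e with g ~ N(0, σ²_g K) and e ~ N(0, σ²_e I).
Writing δ = σ²_e / σ²_g, the covariance is σ²_g (K + δ I); one
eigendecomposition K = U D U′ reduces every likelihood evaluation to
weighted least squares in the rotated basis, so the profile likelihood in
δ is cheap.  δ is located on a log grid and refined by bounded scalar
minimization to relative tolerance 1e-8.

REML profiles the restricted likelihood (valid for variance estimation
under a fixed X); ML maximizes the full likelihood and is the one to use
for likelihood-ratio tests of fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["KinshipEigen", "VarianceFit", "fit_variance_components"]

_LOG_DELTA_GRID = np.linspace(-6.0, 6.0, 49)


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix (eigenvalues clipped at 0)."""

    d: np.ndarray
    u: np.ndarray

    @classmethod
    def from_kinship(cls, k: np.ndarray) -> "KinshipEigen":
        d, u = np.linalg.eigh(k)
        return cls(np.clip(d, 0.0, None), u)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.u.T @ a


@dataclass
class VarianceFit:
    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    beta: np.ndarray
    method: str


def _profile_loglik(
    log_delta: float,
    yt: np.ndarray,
    xt: np.ndarray,
    d: np.ndarray,
    method: str,
) -> tuple[float, np.ndarray, float]:
    """(log-likelihood, GLS beta, sigma_g2) at a given log10(delta)."""
    n, p = xt.shape
    v = d + 10.0 ** log_delta
    xw = xt / v[:, None]
    a = xt.T @ xw
    b = xw.T @ yt
    beta = np.linalg.solve(a, b)
    r = yt - xt @ beta
    rss = float(np.sum(r * r / v))
    logv = float(np.sum(np.log(v)))
    if method == "reml":
        df = n - p
        sigma_g2 = rss / df
        _, logdet_a = np.linalg.slogdet(a)
        ll = -0.5 * (df * np.log(2 * np.pi * sigma_g2) + logv + logdet_a + df)
    else:
        sigma_g2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_g2) + logv + n)
    return ll, beta, sigma_g2


def fit_variance_components(
    y: np.ndarray,
    x: np.ndarray,
    eig: KinshipEigen,
    method: str = "reml",
) -> VarianceFit:
    """Profile (RE)ML over δ = σ²_e/σ²_g given a kinship eigendecomposition.

    Raises on constant phenotypes and on rank-deficient fixed-effect
    designs, the two degenerate inputs that make the profile undefined.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n, p = x.shape
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")
    if n <= p + 1:
        raise ValueError("too few observations for the fixed-effect design")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("fixed-effect design is rank deficient")
    yt = eig.rotate(y)
    xt = eig.rotate(x)

    def neg_ll(ld: float) -> float:
        return -_profile_loglik(ld, yt, xt, eig.d, method)[0]

    grid_vals = np.array([neg_ll(ld) for ld in _LOG_DELTA_GRID])
    k = int(np.argmin(grid_vals))
    lo = _LOG_DELTA_GRID[max(k - 1, 0)]
    hi = _LOG_DELTA_GRID[min(k + 1, len(_LOG_DELTA_GRID) - 1)]
    if lo == hi:
        best_ld = lo
    else:
        res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
        if not res.success:
            raise RuntimeError(f"variance-component optimization failed: {res.message}")
        best_ld = float(res.x)
    ll, beta, sigma_g2 = _profile_loglik(best_ld, yt, xt, eig.d, method)
    delta = 10.0 ** best_ld
    return VarianceFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_g2 * delta,
        delta=delta,
        loglik=ll,
        beta=beta,
        method=method,
    )
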