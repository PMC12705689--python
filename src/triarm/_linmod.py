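"""Lean least-squares helpers used inside simulation and bootstrap loops.

The user-facing ANCOVA (:mod:`triarm.ancova_mi`) goes through statsmodels;
these routines exist so that Monte-Carlo loops (thousands of refits on
150-row designs) do not pay per-fit model-construction overhead.  A unit
test pins their output to the statsmodels fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class FastOLS:
    """Minimal OLS fit: coefficients, covariance, residuals, df."""

    params: np.ndarray
    cov: np.ndarray
    resid: np.ndarray
    df_resid: int
    rank: int

    @property
    def sigma2(self) -> float:
        return float(self.resid @ self.resid / self.df_resid)

    def wald_f(self, idx: list[int]) -> tuple[float, float]:
        """F-test that params[idx] are jointly zero; returns (F, p)."""
        q = self.params[idx]
        v = self.cov[np.ix_(idx, idx)]
        k = len(idx)
        f = float(q @ np.linalg.solve(v, q)) / k
        p = float(stats.f.sf(f, k, self.df_resid))
        return f, p


def fast_ols(X: np.ndarray, y: np.ndarray) -> FastOLS:
    """OLS via QR-backed lstsq; raises on rank deficiency."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {p} columns)"
        )
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return FastOLS(params=beta, cov=sigma2 * xtx_inv, resid=resid,
                   df_resid=df, rank=rank)
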