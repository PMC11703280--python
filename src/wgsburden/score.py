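"""Vectorised logistic score tests against a shared null model.

Genome-wide scans test thousands of burdens (or dosages) against the
same outcome and covariates.  Fitting the covariate-only null model once
and score-testing each predictor is the standard trick (RVTESTS, SAIGE,
WGScan all do it): the score statistic for predictor ``b`` is

    U = b' (y - mu),   V = b' W b - b' W X (X' W X)^-1 X' W b

with ``mu`` the null fitted probabilities and ``W = diag(mu (1 - mu))``,
and ``U^2 / V`` is chi-square(1) under the null.  Everything reduces to
matrix products, so testing all windows of a scan is a single GEMM.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, stats

__all__ = ["LogisticScoreEngine"]


class LogisticScoreEngine:
    """Null logistic fit plus vectorised score tests.

    Parameters
    ----------
    y : (n,) 0/1 outcome
    covariates : (n, k) covariate matrix without intercept (may be empty)
    """

    def __init__(self, y, covariates=None):
        import statsmodels.api as sm

        y = np.asarray(y, dtype=np.float64)
        n = y.shape[0]
        X = np.column_stack(
            [np.ones(n)] + ([] if covariates is None else [np.asarray(covariates)])
        )
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        self.y = y
        self.X = X
        self.mu = np.asarray(res.fittedvalues)
        self.eta = X @ res.params
        self.w = self.mu * (1.0 - self.mu)
        self.resid = y - self.mu
        XtWX = (X.T * self.w) @ X
        try:
            self._XtWX_chol = linalg.cho_factor(XtWX)
            self._XtWX_pinv = None
        except linalg.LinAlgError:
            # singular information (e.g. collinear covariates): pinv solve
            self._XtWX_chol = None
            self._XtWX_pinv = linalg.pinvh(XtWX)
        self.null_result = res

    def _solve(self, C):
        if self._XtWX_chol is not None:
            return linalg.cho_solve(self._XtWX_chol, C)
        return self._XtWX_pinv @ C

    def variance(self, B) -> np.ndarray:
        """Score variances for predictor columns ``B`` (n x m)."""
        B = np.asarray(B, dtype=np.float64)
        WB = self.w[:, None] * B
        C = self.X.T @ WB  # k x m
        S = self._solve(C)
        v = np.einsum("nm,nm->m", B, WB) - np.einsum("km,km->m", C, S)
        return np.clip(v, 0.0, None)

    def test(self, B):
        """Two-sided score test per column of ``B``.

        Returns (z, p); z carries the direction (positive = enrichment in
        the y=1 group).  Columns with zero variance get z=0, p=1.
        """
        B = np.atleast_2d(np.asarray(B, dtype=np.float64))
        if B.shape[0] != self.y.shape[0]:
            B = B.T
        U = B.T @ self.resid
        V = self.variance(B)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(V > 0, U / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        return z, p

    def effect_estimates(self, B):
        """One-step score-based effect estimates: beta ~ U/V, se ~ V^-1/2.

        The standard fast-GWAS approximation for reporting ORs without a
        per-predictor refit; accurate for modest effects.
        """
        B = np.atleast_2d(np.asarray(B, dtype=np.float64))
        if B.shape[0] != self.y.shape[0]:
            B = B.T
        U = B.T @ self.resid
        V = self.variance(B)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(V > 0, U / np.where(V > 0, V, 1.0), 0.0)
            se = np.where(V > 0, 1.0 / np.sqrt(np.where(V > 0, V, 1.0)), np.inf)
        return beta, se

    def strata(self, n_strata: int = 10) -> np.ndarray:
        """Deciles (by default) of the null linear predictor, for
        stratified permutation that respects the covariate structure."""
        ranks = stats.rankdata(self.eta, method="ordinal") - 1
        return (ranks * n_strata // self.y.shape[0]).astype(np.intp)

    def permuted_residuals(self, n_perm: int, rng, n_strata: int = 10) -> np.ndarray:
        """(n_perm, n) matrix of null residuals permuted within strata of
        the covariate-only linear predictor."""
        strata = self.strata(n_strata)
        n = self.y.shape[0]
        out = np.empty((n_perm, n))
        idx_by_stratum = [np.where(strata == s)[0] for s in np.unique(strata)]
        for b in range(n_perm):
            perm = np.empty(n, dtype=np.intp)
            for idx in idx_by_stratum:
                perm[idx] = rng.permutation(idx)
            out[b] = self.resid[perm]
        return out
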