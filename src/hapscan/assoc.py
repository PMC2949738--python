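"""Association statistics for case-control window models.

The workhorse is the Rao score test of the omnibus null (all genetic
parameters zero) against a window design, with nuisance parameters
(intercept and optional covariates such as principal-component scores)
profiled out through the efficient Fisher information:

    U = G' (y - pi),    J = G'WG - G'WM (M'WM)^{-1} M'WG,
    S = U' J^+ U,       W = diag(pi (1 - pi)),

where M is the null design, G the tested block, and pi the fitted null
probabilities.  J^+ is the Moore-Penrose pseudo-inverse, so linearly
dependent tested columns (e.g. SNPs fully determined by their neighbours)
cost nothing: S and the reported df (the numerical rank of J) are
invariant under invertible reparameterizations of the tested block.
Because the binomial family is exponential, the covariance of the score
equals the Fisher information, which makes the score test robust to
errors in the inferred haplotype frequencies — the reason it, rather than
the likelihood-ratio test, is used for expectation-substitution designs
on unphased data.  The LR test is provided for phased data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignMatrix


@dataclass
class NullFit:
    """Null (intercept + covariates) logistic fit."""

    pi: np.ndarray               # fitted probabilities
    M: np.ndarray                # null design incl. intercept
    y: np.ndarray
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return self.pi * (1.0 - self.pi)


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    model: str = ""
    notes: str = ""


def _as_y(phenotype) -> np.ndarray:
    y = getattr(phenotype, "y", phenotype)
    return np.asarray(y, dtype=float)


def fit_null(phenotype, covariates=None) -> NullFit:
    """ML logistic fit of intercept + covariates (IRLS via statsmodels).

    Without covariates the fit is closed-form: pi = case fraction.
    Raises on one-class phenotypes and on separation/non-convergence.
    """
    y = _as_y(phenotype)
    if y.min() == y.max():
        raise ValueError("phenotype has a single class; null model is degenerate")
    n = len(y)
    if covariates is None:
        pi = np.full(n, y.mean())
        return NullFit(pi=pi, M=np.ones((n, 1)), y=y)
    C = getattr(covariates, "values", covariates)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match phenotype length")
    import statsmodels.api as sm

    M = np.column_stack([np.ones(n), C])
    res = sm.GLM(y, M, family=sm.families.Binomial()).fit()
    pi = np.asarray(res.fittedvalues)
    if not res.converged or np.any(pi <= 1e-10) or np.any(pi >= 1 - 1e-10):
        raise ValueError("null logistic fit failed (separation or non-convergence)")
    score = M.T @ (y - pi)
    if np.linalg.norm(score) > 1e-6 * n:
        raise ValueError("null fit score not at zero; fit did not converge")
    return NullFit(pi=pi, M=M, y=y, converged=True)


def _efficient_information(G: np.ndarray, null_fit: NullFit) -> np.ndarray:
    w = null_fit.weights
    M = null_fit.M
    Gw = G * w[:, None]
    A = G.T @ Gw
    B = Gw.T @ M
    C = (M * w[:, None]).T @ M
    return A - B @ np.linalg.solve(C, B.T)


def score_test(design, null_fit: NullFit, model: str | None = None) -> TestResult:
    """Rao score test of the tested block against the null fit.

    ``design`` is a DesignMatrix (intercept excluded automatically) or a
    plain array of tested columns.  Uses the generalized inverse of the
    efficient information; df is its numerical rank.
    """
    if isinstance(design, DesignMatrix):
        G = design.tested()
        tag = model or design.model
    else:
        G = np.asarray(design, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        tag = model or ""
    if G.shape[0] != len(null_fit.y):
        raise ValueError("design rows do not align with the phenotype")
    U = G.T @ (null_fit.y - null_fit.pi)
    J = _efficient_information(G, null_fit)
    J = (J + J.T) / 2.0
    eigval, eigvec = np.linalg.eigh(J)
    cutoff = max(J.shape) * np.finfo(float).eps * max(eigval.max(initial=0.0), 0.0)
    keep = eigval > cutoff
    rank = int(keep.sum())
    notes = ""
    if rank == 0:
        return TestResult(0.0, 0, 1.0, model=tag, notes="zero-rank information")
    if rank < G.shape[1]:
        notes = f"g-inverse used (rank {rank} < {G.shape[1]} columns)"
    proj = eigvec[:, keep].T @ U
    S = float(np.sum(proj**2 / eigval[keep]))
    p = float(stats.chi2.sf(S, rank))
    return TestResult(S, rank, p, model=tag, notes=notes)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    from scipy import linalg

    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def _null_loglik(y: np.ndarray) -> float:
    ybar = y.mean()
    return float(len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))


def lr_test(design, phenotype, model: str | None = None) -> TestResult:
    """Likelihood-ratio omnibus test against the intercept-only null.

    Intended for phased data.  Collinear alternative columns are reduced
    before fitting; df is the number of fitted non-intercept parameters.
    On separation / non-convergence falls back to the score test.
    """
    y = _as_y(phenotype)
    if isinstance(design, DesignMatrix):
        X = design.values
        terms = design.terms
        tag = model or design.model
    else:
        X = np.asarray(design, dtype=float)
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["intercept"] + [f"x{j}" for j in range(X.shape[1] - 1)]
        tag = model or ""
    if "intercept" not in terms:
        X = np.column_stack([np.ones(len(y)), X])
    if X.shape[0] != len(y):
        raise ValueError("design rows do not align with the phenotype")

    keep = _independent_columns(X)
    Xr = X[:, keep]
    df = Xr.shape[1] - 1
    if df <= 0:
        return TestResult(0.0, 0, 1.0, model=tag, notes="no tested parameters")
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xr).fit(disp=0, maxiter=100)
            ok = res.mle_retvals.get("converged", False)
        except Exception:
            ok = False
    if not ok:
        null = fit_null(y)
        out = score_test(Xr[:, 1:], null, model=tag)
        out.notes = (out.notes + "; " if out.notes else "") + "LR fell back to score test"
        return out
    lr = max(0.0, 2.0 * (float(res.llf) - _null_loglik(y)))
    p = float(stats.chi2.sf(lr, df))
    return TestResult(lr, df, p, model=tag)


def single_snp_tests(columns, phenotype, covariates=None) -> tuple[np.ndarray, float]:
    """1-df logistic score test per SNP column; returns (p-values, min p).

    Columns are dosages (individuals) or alleles (haplotype copies);
    monomorphic columns score p = 1.  Asymptotically equivalent to the
    Cochran-Armitage trend test; with covariates it is the PC-adjusted
    logistic score test.
    """
    X = np.asarray(getattr(columns, "dosage", columns), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    null = fit_null(phenotype, covariates)
    ps = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        res = score_test(X[:, [j]], null, model="single")
        ps[j] = res.p
    return ps, float(ps.min())


def inflation_lambda(statistics, df: int) -> float:
    """Median-based inflation factor: median(stats) / median of chi^2_df."""
    s = np.asarray(statistics, dtype=float)
    if s.size == 0:
        raise ValueError("no statistics supplied")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(np.median(s) / stats.chi2.ppf(0.5, df))
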