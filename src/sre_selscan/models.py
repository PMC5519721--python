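"""Fitted models: the logistic SRE-overlap model and the two-component
GREML heritability partition.

The logistic model regresses the binary SRE-overlap indicator on per-SNP
features (derived allele frequency, F_ST, B-value, LD extent); the intercept
absorbs genome-wide effects such as demography while the coefficients carry
locus-specific effects.  Fitting is by IRLS (statsmodels GLM) on internally
z-scored features, with coefficients reported back on the original scale and
Wald tests per coefficient.

The heritability partition fits
    var(y) = A_SRE sigma2_SRE + A_nonSRE sigma2_nonSRE + I sigma2_e
by average-information REML with EM fallback steps, components constrained
non-negative, and reports h2_SRE = sigma2_SRE / sigma2_Y with a delta-method
standard error from the inverse AI matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats
import statsmodels.api as sm

from .types import ConfigurationError


class SeparationError(RuntimeError):
    """A feature perfectly separates the outcome."""


class NotIdentifiableError(RuntimeError):
    """Variance components cannot be separated (collinear relatedness)."""


# ---------------------------------------------------------------------------
# Logistic SRE-overlap model

@dataclass
class LogisticFit:
    intercept: float
    coef: np.ndarray          # original feature scale
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    converged: bool
    n: int
    feature_names: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "beta": self.coef,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


def fit_sre_logistic(
    overlap: np.ndarray,
    features: np.ndarray,
    feature_names: list[str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of SRE overlap on features.

    Features are z-scored internally for numerical stability; reported
    coefficients and standard errors are back-transformed to the original
    scale.  Raises on rank-deficient design, perfect separation (naming the
    offending feature), or sample size below 10 x (n_features + 1).
    """
    y = np.asarray(overlap, dtype=float)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    names = feature_names or [f"x{j}" for j in range(p)]
    if n < 10 * (p + 1):
        raise ConfigurationError(f"n={n} too small for {p} features")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmin(sd))
        raise ConfigurationError(f"feature {names[j]!r} is constant (rank deficiency)")
    for j in range(p):
        x = X[:, j]
        if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
            raise SeparationError(f"feature {names[j]!r} perfectly separates the outcome")
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    design = sm.add_constant(Z)
    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        return LogisticFit(
            np.nan, np.full(p, np.nan), np.full(p, np.nan), np.full(p, np.nan),
            np.full(p, np.nan), False, n, names,
        )
    beta_std = res.params[1:]
    coef = beta_std / sd
    se = res.bse[1:] / sd
    intercept = res.params[0] - float(np.sum(beta_std * mu / sd))
    z = coef / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(float(intercept), coef, se, z, pvals, True, n, names)


# ---------------------------------------------------------------------------
# Genetic relatedness matrix

def compute_grm(dosages: np.ndarray) -> tuple[np.ndarray, int]:
    """Standard normalized GRM from an n x m dosage matrix in {0, 1, 2}:

        A = (1/m) sum_k (g_k - 2 p_k)(g_k - 2 p_k)' / (2 p_k (1 - p_k))

    Monomorphic SNPs are excluded; returns (A, number excluded)."""
    G = np.asarray(dosages, dtype=np.float64)
    p = G.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    n_excluded = int(np.sum(~keep))
    G = G[:, keep]
    p = p[keep]
    if G.shape[1] == 0:
        raise ConfigurationError("all SNPs monomorphic")
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (Z @ Z.T) / G.shape[1], n_excluded


# ---------------------------------------------------------------------------
# Two-variance-component REML

@dataclass
class VarianceComponents:
    var_sre: float
    var_non: float
    var_e: float
    h2_sre: float
    h2_se: float
    loglik: float
    iterations: int
    converged: bool

    @property
    def var_total(self) -> float:
        return self.var_sre + self.var_non + self.var_e


def reml_two_vc(
    y: np.ndarray,
    A_sre: np.ndarray,
    A_non: np.ndarray,
    X: np.ndarray | None = None,
    tol: float = 1e-6,
    maxiter: int = 200,
) -> VarianceComponents:
    """AI-REML for var(y) = A_SRE s1 + A_nonSRE s2 + I s3.

    Average-information updates with EM-REML fallback when an AI step
    leaves the parameter space or decreases the restricted likelihood;
    components are floored at a small positive multiple of var(y).
    Convergence when |delta logL| < tol.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if np.allclose(A_sre, A_non):
        raise NotIdentifiableError("relatedness matrices are identical; components not separable")
    vary = float(y.var())
    floor = max(vary, 1e-12) * 1e-6
    comps = np.full(3, vary / 3.0)
    As = (A_sre, A_non, None)  # None stands for the identity
    eye = np.eye(n)

    def build_V(c):
        return c[0] * A_sre + c[1] * A_non + c[2] * eye

    def reml_pieces(c):
        V = build_V(c)
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        Vi = sla.cho_solve(cf, eye, check_finite=False)
        ViX = Vi @ X
        XtViX = X.T @ ViX
        cf2 = sla.cho_factor(XtViX)
        logdetX = 2.0 * np.log(np.diag(cf2[0])).sum()

        def Pv(v):
            return Vi @ v - ViX @ sla.cho_solve(cf2, ViX.T @ v)

        Py = Pv(y)
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return Vi, ViX, cf2, Pv, Py, ll

    def trPA(Vi, ViX, cf2, A):
        if A is None:
            tr1 = np.trace(Vi)
            M = ViX
        else:
            tr1 = float(np.sum(Vi * A))
            M = A @ ViX
        corr = float(np.trace(sla.cho_solve(cf2, ViX.T @ M)))
        return tr1 - corr

    Vi, ViX, cf2, Pv, Py, ll = reml_pieces(comps)
    converged = False
    it = 0
    AI = np.eye(3)
    for it in range(1, maxiter + 1):
        t = [A @ Py if A is not None else Py for A in As]
        Pt = [Pv(ti) for ti in t]
        grad = np.array(
            [-0.5 * (trPA(Vi, ViX, cf2, As[i]) - float(Py @ t[i])) for i in range(3)]
        )
        AI = 0.5 * np.array([[float(t[i] @ Pt[j]) for j in range(3)] for i in range(3)])
        AI = 0.5 * (AI + AI.T)
        # active set: components pinned at the floor stay there unless the
        # gradient points back into the parameter space
        free = (comps > 1.5 * floor) | (grad > 0)
        if not free.any():
            converged = True
            break
        step = np.zeros(3)
        try:
            step[free] = np.linalg.solve(AI[np.ix_(free, free)], grad[free])
        except np.linalg.LinAlgError:
            raise NotIdentifiableError("singular average-information matrix")
        proposal = np.maximum(comps + step, floor)
        proposal[~free] = floor
        try:
            pieces = reml_pieces(proposal)
            ok = pieces[-1] >= ll - 1e-10
        except np.linalg.LinAlgError:
            ok = False
        if not ok:
            # EM-REML fallback step (guaranteed uphill, slower)
            em = np.array(
                [
                    comps[i]
                    + comps[i] ** 2 / n * (float(Py @ t[i]) - trPA(Vi, ViX, cf2, As[i]))
                    for i in range(3)
                ]
            )
            proposal = np.maximum(em, floor)
            pieces = reml_pieces(proposal)
        new_ll = pieces[-1]
        delta = new_ll - ll
        param_move = float(np.max(np.abs(proposal - comps)))
        comps = proposal
        Vi, ViX, cf2, Pv, Py, ll = pieces
        if abs(delta) < tol or param_move < 1e-10 * max(vary, 1e-12):
            converged = True
            break

    s1, s2, s3 = comps
    total = s1 + s2 + s3
    h2 = s1 / total
    try:
        cov = np.linalg.inv(AI)
        g = np.array([(total - s1), -s1, -s1]) / total**2
        h2_se = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except np.linalg.LinAlgError:
        h2_se = np.nan
    return VarianceComponents(
        var_sre=float(s1), var_non=float(s2), var_e=float(s3),
        h2_sre=float(h2), h2_se=h2_se, loglik=float(ll),
        iterations=it, converged=converged,
    )
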