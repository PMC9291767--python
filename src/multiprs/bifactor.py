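"""Bifactor measurement model for general and specific child psychopathology.

One general factor loads on every symptom subscale; two orthogonal specific
factors (internalizing, externalizing) each load on the subscales of their own
domain only.  The model for the standardized subscale vector y is

    y = L_g g + L_s s + e,    Sigma = L_g L_g' + L_s L_s' + Psi

with unit-variance orthogonal factors and diagonal uniquenesses Psi.  The fit
is Gaussian maximum likelihood on the sample correlation matrix; factor scores
are regression (Thurstone) scores L' Sigma^-1 y.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger("multiprs.bifactor")

__all__ = ["BifactorFit", "fit_bifactor", "factor_scores"]

PSI_FLOOR = 1e-4  # Heywood clamp on uniquenesses


@dataclass
class BifactorFit:
    general_loadings: np.ndarray
    specific_loadings: np.ndarray
    domain_map: list[str]
    uniquenesses: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    history: list[float] = field(default_factory=list, repr=False)
    means: np.ndarray | None = field(default=None, repr=False)
    sds: np.ndarray | None = field(default=None, repr=False)

    @property
    def lambda_matrix(self) -> np.ndarray:
        """p x 3 loading matrix, columns (general, specific_ext, specific_int)."""
        dom = np.asarray(self.domain_map)
        lam = np.zeros((len(dom), 3))
        lam[:, 0] = self.general_loadings
        lam[dom == "ext", 1] = self.specific_loadings[dom == "ext"]
        lam[dom == "int", 2] = self.specific_loadings[dom == "int"]
        return lam

    @property
    def implied_covariance(self) -> np.ndarray:
        lam = self.lambda_matrix
        return lam @ lam.T + np.diag(self.uniquenesses)


def _discrepancy_and_grad(theta: np.ndarray, r: np.ndarray,
                          dom_ext: np.ndarray) -> tuple[float, np.ndarray]:
    """ML discrepancy F = log|Sigma| + tr(R Sigma^-1) - log|R| - p and its
    gradient w.r.t. (L_g, L_s, log Psi)."""
    p = r.shape[0]
    lg = theta[:p]
    ls = theta[p:2 * p]
    psi = np.exp(theta[2 * p:])
    me = np.where(dom_ext, ls, 0.0)
    mi = np.where(dom_ext, 0.0, ls)
    sigma = (np.outer(lg, lg) + np.outer(me, me) + np.outer(mi, mi)
             + np.diag(psi))
    sign, logdet_s = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10, np.zeros_like(theta)
    sigma_inv = np.linalg.inv(sigma)
    _, logdet_r = np.linalg.slogdet(r)
    f = logdet_s + float(np.trace(r @ sigma_inv)) - logdet_r - p
    d = sigma_inv @ (sigma - r) @ sigma_inv     # dF/dSigma
    g_lg = 2.0 * d @ lg
    g_ls = np.where(dom_ext, 2.0 * d @ me, 2.0 * d @ mi)
    g_psi = np.diag(d) * psi
    return f, np.concatenate([g_lg, g_ls, g_psi])


def fit_bifactor(subscales: pd.DataFrame | np.ndarray,
                 domain_map: list[str],
                 gtol: float = 1e-8, max_iter: int = 2000) -> BifactorFit:
    """Maximum-likelihood bifactor fit to the sample correlation matrix.

    Subscales are standardized internally.  Start values: general loadings
    from the first principal component, specific loadings at 0.2.  Quasi-Newton
    (L-BFGS-B) on (L_g, L_s, log Psi) with uniquenesses floored at 1e-4
    (Heywood cases clamped with a warning).  Non-convergence is flagged, not
    raised.  Sign convention: mean general loading and mean per-domain
    specific loading positive.
    """
    x = np.asarray(subscales, dtype=float)
    if isinstance(subscales, pd.DataFrame):
        names = list(subscales.columns)
    else:
        names = [f"y{i+1}" for i in range(x.shape[1])]
    dom = np.asarray(domain_map)
    p = x.shape[1]
    if len(dom) != p:
        raise ValueError("domain_map length must match number of subscales")
    for d in ("int", "ext"):
        if (dom == d).sum() < 3:
            raise ValueError(f"need at least 3 subscales for the {d} factor")
    dom_ext = dom == "ext"

    means, sds = x.mean(axis=0), x.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("constant subscale column")
    r = np.corrcoef(x, rowvar=False)
    return _fit_to_corr(r, dom_ext, list(dom), names, gtol, max_iter,
                        means=means, sds=sds)


def fit_bifactor_corr(r: np.ndarray, domain_map: list[str],
                      gtol: float = 1e-8, max_iter: int = 2000) -> BifactorFit:
    """Fit directly to a correlation matrix (no raw data)."""
    dom = np.asarray(domain_map)
    return _fit_to_corr(np.asarray(r, float), dom == "ext", list(dom),
                        [f"y{i+1}" for i in range(r.shape[0])],
                        gtol, max_iter, means=None, sds=None)


def _fit_to_corr(r: np.ndarray, dom_ext: np.ndarray, dom: list[str],
                 names: list[str], gtol: float, max_iter: int,
                 means, sds) -> BifactorFit:
    p = r.shape[0]
    off = r - np.diag(np.diag(r))
    if np.max(np.abs(off)) < 0.01:
        # no common variance: the factor model is vacuous, and spurious exact
        # fits exist (a single spiked loading reproduces an identity matrix)
        warnings.warn("degenerate solution: no common variance in input")
        return BifactorFit(general_loadings=np.zeros(p),
                           specific_loadings=np.zeros(p),
                           domain_map=dom, uniquenesses=np.diag(r).copy(),
                           loglik=0.0, converged=True, n_iter=0,
                           history=[], means=means, sds=sds)
    starts = []
    # principal-component start
    evals, evecs = np.linalg.eigh(r)
    v1 = evecs[:, -1] * np.sign(evecs[:, -1].sum() or 1.0)
    starts.append(np.clip(np.sqrt(max(evals[-1], 1.0)) * v1, 0.05, 0.95))
    # centroid start from the cross-domain block: for i, j in different
    # domains R_ij = lg_i lg_j, which pins down the general loadings and
    # avoids the local optimum where a specific factor absorbs them
    if dom_ext.any() and (~dom_ext).any():
        cross = r[np.ix_(~dom_ext, dom_ext)]
        row_int = np.clip(cross.mean(axis=1), 1e-3, None)
        row_ext = np.clip(cross.mean(axis=0), 1e-3, None)
        denom = math.sqrt(max(float(cross.mean()), 1e-3))
        lg_c = np.empty(p)
        lg_c[~dom_ext] = row_int / denom
        lg_c[dom_ext] = row_ext / denom
        starts.append(np.clip(lg_c, 0.05, 0.95))

    bounds = ([(-2.0, 2.0)] * (2 * p)) + ([(np.log(PSI_FLOOR), 2.0)] * p)
    res, history = None, []
    for lg0 in starts:
        ls0 = np.full(p, 0.2)
        psi0 = np.clip(1.0 - lg0**2 - ls0**2, 0.05, 1.0)
        theta0 = np.concatenate([lg0, ls0, np.log(psi0)])
        run_history: list[float] = []
        cand = optimize.minimize(
            _discrepancy_and_grad, theta0, args=(r, dom_ext), jac=True,
            method="L-BFGS-B", bounds=bounds,
            callback=lambda th, h=run_history: h.append(
                _discrepancy_and_grad(th, r, dom_ext)[0]),
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol})
        if res is None or cand.fun < res.fun:
            res, history = cand, run_history

    lg = res.x[:p].copy()
    ls = res.x[p:2 * p].copy()
    psi = np.exp(res.x[2 * p:])
    if np.any(psi <= PSI_FLOOR * (1 + 1e-6)):
        warnings.warn("Heywood case: uniqueness clamped at floor")
    # sign conventions
    if lg.mean() < 0:
        lg = -lg
    for d in (True, False):
        mask = dom_ext == d
        if ls[mask].mean() < 0:
            ls[mask] = -ls[mask]
    if np.all(np.abs(lg) < 0.05) and np.all(np.abs(ls) < 0.05):
        warnings.warn("degenerate solution: all loadings near zero")

    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-5
    if not converged:
        logger.warning("bifactor fit did not converge: %s", res.message)
    fit = BifactorFit(general_loadings=lg, specific_loadings=ls,
                      domain_map=dom, uniquenesses=np.maximum(psi, PSI_FLOOR),
                      loglik=-0.5 * float(res.fun), converged=converged,
                      n_iter=int(res.nit), history=history,
                      means=means, sds=sds)
    fit.names = names  # type: ignore[attr-defined]
    return fit


def factor_scores(fit: BifactorFit,
                  subscales: pd.DataFrame | np.ndarray,
                  method: str = "regression") -> pd.DataFrame:
    """Factor scores for (general, spec_ext, spec_int), one row per individual.

    ``method="regression"`` (default) gives Thurstone scores Lambda' Sigma^-1 y
    — minimum-MSE but mutually correlated even for orthogonal factors, so a
    specific-factor score retains some general-factor variance.
    ``method="bartlett"`` gives (L' Psi^-1 L)^-1 L' Psi^-1 y — conditionally
    unbiased, so each score is uncorrelated with the *other* true factors.
    Subscales are standardized with the statistics stored at fit time (or
    their own when the fit was made from a correlation matrix).
    """
    if not fit.converged:
        warnings.warn("scoring from a non-converged fit")
    x = np.asarray(subscales, dtype=float)
    if fit.means is not None:
        y = (x - fit.means) / fit.sds
    else:
        sds = x.std(axis=0)
        y = (x - x.mean(axis=0)) / np.where(sds == 0, 1.0, sds)
    sigma = fit.implied_covariance
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("implied covariance is singular")
    lam = fit.lambda_matrix
    if method == "regression":
        weights = np.linalg.solve(sigma, lam)             # Sigma^-1 Lambda
    elif method == "bartlett":
        lam_w = lam / fit.uniquenesses[:, None]           # Psi^-1 Lambda
        weights = lam_w @ np.linalg.inv(lam.T @ lam_w)
    else:
        raise ValueError(f"unknown scoring method: {method}")
    scores = y @ weights
    index = subscales.index if isinstance(subscales, pd.DataFrame) else None
    out = pd.DataFrame(scores, columns=["general", "spec_ext", "spec_int"],
                       index=index)
    if index is not None:
        out.index.name = "iid"
    return out
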