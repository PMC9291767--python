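"""Random-effects meta-analysis across cohorts and multiple-testing control.

Per-cohort standardized PRS coefficients are pooled with a DerSimonian–Laird
between-study variance and inverse-variance weights; the p-value comes from the
Han–Eskin RE2 likelihood-ratio test, which tests beta = 0 and tau^2 = 0 jointly
against a half-half mixture of chi-square(1) and chi-square(2) — heterogeneity
contributes evidence instead of only inflating the pooled SE.  Multiplicity over
the trait-by-threshold grid is controlled by Bonferroni at the Li–Ji effective
number of independent tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MetaInput",
    "MetaResult",
    "EffectiveTests",
    "dl_tau2",
    "pool",
    "han_eskin_p",
    "meta_analyze",
    "meff_li_ji",
    "adjust_alpha",
    "flag_independent",
]


@dataclass(frozen=True)
class MetaInput:
    """Per-cohort estimates entering one meta-analysis.

    ``betas`` are standardized regression coefficients (SD units), ``ses`` their
    standard errors; ``ns`` are cohort sample sizes (used only for the combined-n
    accounting, not for weighting).
    """

    betas: tuple[float, ...]
    ses: tuple[float, ...]
    labels: tuple[str, ...] = ()
    ns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        object.__setattr__(self, "ses", tuple(float(s) for s in self.ses))
        if len(self.betas) != len(self.ses):
            raise ValueError("betas and ses must have equal length")
        if len(self.betas) < 2:
            raise ValueError("meta-analysis needs at least 2 cohorts")
        if any(s <= 0 for s in self.ses):
            raise ValueError("standard errors must be positive")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"study{i+1}" for i in range(len(self.betas)))
            )
        if self.ns and len(self.ns) != len(self.betas):
            raise ValueError("ns must match number of studies")

    @property
    def k(self) -> int:
        return len(self.betas)


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity and the RE2 test."""

    beta: float
    tau: float
    se: float
    statistic: float
    p: float
    n: int
    inputs: MetaInput = field(repr=False, default=None)  # type: ignore[assignment]


def dl_tau2(inputs: MetaInput) -> float:
    """DerSimonian–Laird moment estimate of the between-study variance tau^2.

    Fixed-effects weights w_i = 1/s_i^2 give Cochran's
    Q = sum w_i (y_i - ybar_FE)^2; with C = sum w - sum w^2 / sum w the
    estimate is tau^2 = max(0, (Q - (k-1)) / C).
    """
    y = np.asarray(inputs.betas)
    w = 1.0 / np.asarray(inputs.ses) ** 2
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (inputs.k - 1)) / c)


def pool(inputs: MetaInput, tau2: float) -> tuple[float, float]:
    """Inverse-variance pooled (beta, SE) under between-study variance ``tau2``.

    Weights are w*_i = 1/(s_i^2 + tau^2); beta is their weighted mean and
    SE = sqrt(1 / sum w*).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    y = np.asarray(inputs.betas)
    w = 1.0 / (np.asarray(inputs.ses) ** 2 + tau2)
    beta = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    return beta, se


def _re_loglik(beta: float, tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Normal random-effects log-likelihood at (beta, tau2)."""
    s2 = v + tau2
    return float(-0.5 * np.sum(np.log(2 * np.pi * s2) + (y - beta) ** 2 / s2))


def _profile_beta(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    return float(np.sum(w * y) / np.sum(w))


def han_eskin_p(inputs: MetaInput) -> tuple[float, float]:
    """Han–Eskin RE2 likelihood-ratio statistic and p-value.

    Maximizes the random-effects log-likelihood l(beta, tau^2) over beta and
    tau^2 >= 0 (beta profiled out analytically, tau^2 by bounded scalar search)
    and forms S = 2(l(betahat, tau2hat) - l(0, 0)).  Under the null the
    asymptotic reference is the equal mixture 1/2 chi2_1 + 1/2 chi2_2.
    """
    y = np.asarray(inputs.betas)
    v = np.asarray(inputs.ses) ** 2

    def neg_profile(tau2: float) -> float:
        return -_re_loglik(_profile_beta(tau2, y, v), tau2, y, v)

    # bracket: between-study variance cannot usefully exceed the spread of y
    hi = max(float(np.var(y)) * 10.0, float(np.max(v)) * 10.0, 1e-6)
    res = optimize.minimize_scalar(neg_profile, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-12})
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        warnings.warn("RE2 profile optimizer failed; falling back to grid search")
        grid = np.linspace(0.0, hi, 20001)
        vals = [neg_profile(t) for t in grid]
        tau2_hat = float(grid[int(np.argmin(vals))])
    else:
        tau2_hat = float(res.x)
    # tau2 = 0 is a boundary candidate the bounded search can skim past
    if neg_profile(0.0) <= neg_profile(tau2_hat):
        tau2_hat = 0.0
    beta_hat = _profile_beta(tau2_hat, y, v)
    s = 2.0 * (_re_loglik(beta_hat, tau2_hat, y, v) - _re_loglik(0.0, 0.0, y, v))
    s = max(0.0, s)
    p = 0.5 * stats.chi2.sf(s, 1) + 0.5 * stats.chi2.sf(s, 2)
    return s, float(p)


def meta_analyze(inputs: MetaInput) -> MetaResult:
    """Full meta-analysis of one trait/threshold/outcome cell.

    Reported beta, tau and SE are DerSimonian–Laird / inverse-variance; the
    p-value is the Han–Eskin RE2 mixture p.
    """
    tau2 = dl_tau2(inputs)
    beta, se = pool(inputs, tau2)
    s, p = han_eskin_p(inputs)
    n = int(sum(inputs.ns)) if inputs.ns else 0
    return MetaResult(beta=beta, tau=math.sqrt(tau2), se=se, statistic=s, p=p,
                      n=n, inputs=inputs)


@dataclass(frozen=True)
class EffectiveTests:
    """Li–Ji effective number of independent tests for a correlation matrix."""

    eigenvalues: np.ndarray
    meff: int
    alpha: float
    adjusted_alpha: float


def meff_li_ji(corr: np.ndarray, alpha: float = 0.05) -> EffectiveTests:
    """Effective number of tests from the eigenvalues of a correlation matrix.

    Each eigenvalue contributes f(|l|) = 1(|l| >= 1) + (|l| - floor(|l|)); the
    effective count is the ceiling of the sum, so perfectly correlated columns
    collapse to one test and orthogonal columns count fully.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 9)  # guard floor(3 - eps)
    contrib = (lam >= 1.0).astype(float) + (lam - np.floor(lam))
    meff = int(math.ceil(round(float(np.sum(contrib)), 10)))
    meff = max(1, min(meff, corr.shape[0]))
    return EffectiveTests(eigenvalues=lam, meff=meff, alpha=alpha,
                          adjusted_alpha=adjust_alpha(alpha, meff))


def adjust_alpha(alpha: float, meff: int) -> float:
    """Bonferroni threshold alpha / Meff."""
    if meff < 1:
        raise ValueError("Meff must be at least 1")
    return alpha / meff


def flag_independent(p_separate: float, p_mutual: float,
                     adjusted_alpha: float) -> bool:
    """Independence rule for a PRS effect on general psychopathology.

    A PRS counts as an independent contributor when it survives multiplicity
    adjustment in its separate model and stays nominally significant (p < .05)
    with all other PRSs in the model.
    """
    return (p_separate < adjusted_alpha) and (p_mutual < 0.05)
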