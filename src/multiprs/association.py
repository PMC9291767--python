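"""Per-cohort PRS-outcome regressions and effect comparisons.

Factor scores (general, specific externalizing, specific internalizing) are
regressed on each polygenic score separately — adjusted for age, sex and four
ancestry components — and jointly in a mutually adjusted model with all traits'
PRSs.  Outcome and PRS are z-scored before fitting, so coefficients are
standardized (SD units).  Incremental variance explained is reported in-sample
(Delta R^2 against the covariates-only model) and, for the joint model, by
repeated k-fold cross-validation.  The Clogg z-test compares the general-factor
effect of a PRS against its specific-factor effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

__all__ = [
    "AssocResult",
    "CvConfig",
    "fit_separate_model",
    "fit_mutual_model",
    "select_best_threshold",
    "cv_delta_r2",
    "compare_general_specific",
    "compare_estimates",
    "average_r2",
]


@dataclass(frozen=True)
class AssocResult:
    """One PRS-outcome regression in one cohort."""

    trait: str
    threshold: float
    outcome: str
    beta_std: float
    se: float
    p: float
    delta_r2: float
    n: int


@dataclass(frozen=True)
class CvConfig:
    """Repeated k-fold cross-validation settings."""

    k: int = 10
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns whose removal restores full rank
        bad = [c for c in design.columns
               if np.linalg.matrix_rank(design.drop(columns=c).to_numpy(float))
               == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _complete_cases(*frames: pd.DataFrame) -> pd.Index:
    joined = pd.concat(frames, axis=1)
    return joined.dropna().index


def fit_separate_model(outcome: pd.Series, prs: pd.Series,
                       covariates: pd.DataFrame,
                       trait: str = "", threshold: float = np.nan,
                       outcome_name: str = "") -> AssocResult:
    """OLS of one factor score on one PRS plus covariates.

    Complete cases only; outcome and PRS are z-scored so the PRS coefficient
    is in SD units.  Delta R^2 is the in-sample R^2 gain over the
    covariates-only model.
    """
    idx = _complete_cases(outcome.to_frame("y"), prs.to_frame("prs"), covariates)
    y = _zscore(outcome.loc[idx].to_numpy(float))
    x_prs = _zscore(prs.loc[idx].to_numpy(float))
    cov = covariates.loc[idx].astype(float)

    design = cov.copy()
    design.insert(0, "prs", x_prs)
    design.insert(0, "const", 1.0)
    _check_rank(design)

    full = sm.OLS(y, design).fit()
    covonly = sm.OLS(y, design.drop(columns="prs")).fit()
    return AssocResult(trait=trait, threshold=float(threshold),
                       outcome=outcome_name,
                       beta_std=float(full.params["prs"]),
                       se=float(full.bse["prs"]),
                       p=float(full.pvalues["prs"]),
                       delta_r2=float(full.rsquared - covonly.rsquared),
                       n=len(idx))


def fit_mutual_model(outcome: pd.Series, prs_table: pd.DataFrame,
                     covariates: pd.DataFrame,
                     thresholds: dict[str, float] | None = None,
                     outcome_name: str = "") -> dict[str, AssocResult]:
    """Joint OLS with all traits' PRSs as simultaneous predictors.

    ``prs_table`` has one column per trait (each at its selected threshold).
    Returns one AssocResult per trait; delta_r2 is the joint gain of the full
    PRS block over covariates only (identical across traits by construction).
    """
    idx = _complete_cases(outcome.to_frame("y"), prs_table, covariates)
    y = _zscore(outcome.loc[idx].to_numpy(float))
    prs_std = pd.DataFrame({c: _zscore(prs_table.loc[idx, c].to_numpy(float))
                            for c in prs_table.columns}, index=idx)
    cov = covariates.loc[idx].astype(float)
    design = pd.concat([prs_std, cov], axis=1)
    design.insert(0, "const", 1.0)
    _check_rank(design)

    full = sm.OLS(y, design).fit()
    covonly = sm.OLS(y, design[["const"] + list(cov.columns)]).fit()
    joint_dr2 = float(full.rsquared - covonly.rsquared)
    out = {}
    for trait in prs_table.columns:
        thr = thresholds.get(trait, np.nan) if thresholds else np.nan
        out[trait] = AssocResult(
            trait=trait, threshold=float(thr), outcome=outcome_name,
            beta_std=float(full.params[trait]), se=float(full.bse[trait]),
            p=float(full.pvalues[trait]), delta_r2=joint_dr2, n=len(idx))
    return out


def select_best_threshold(meta_p: pd.Series) -> float:
    """Threshold with the smallest meta-analysis p; ties go to the larger
    threshold.  The index holds thresholds, values are p-values."""
    if meta_p.isna().any() or len(meta_p) == 0:
        raise ValueError("missing meta p-values in threshold grid")
    best_p = meta_p.min()
    candidates = meta_p.index[meta_p == best_p]
    return float(max(candidates))


def cv_delta_r2(outcome: pd.Series, predictors: pd.DataFrame,
                covariates: pd.DataFrame, cfg: CvConfig = CvConfig()) -> float:
    """Out-of-sample incremental R^2 of the predictor block via repeated
    k-fold cross-validation.

    Per repeat, out-of-fold predictions are pooled and R^2 = 1 - SSE/SST is
    computed for the full (covariates + predictors) and the covariates-only
    model; the estimate is the mean difference over repeats.  Deterministic
    given ``cfg.seed``.
    """
    idx = _complete_cases(outcome.to_frame("y"), predictors, covariates)
    n = len(idx)
    if cfg.k > n:
        raise ValueError("more folds than observations")
    y = outcome.loc[idx].to_numpy(float)
    xf = np.column_stack([np.ones(n), predictors.loc[idx].to_numpy(float),
                          covariates.loc[idx].to_numpy(float)])
    xc = np.column_stack([np.ones(n), covariates.loc[idx].to_numpy(float)])
    sst = float(np.sum((y - y.mean()) ** 2))

    rng = np.random.SeedSequence(cfg.seed)
    deltas = []
    for rep_seed in rng.spawn(cfg.repeats):
        kf = KFold(n_splits=cfg.k, shuffle=True,
                   random_state=int(rep_seed.generate_state(1)[0] % 2**31))
        sse_f = sse_c = 0.0
        for train, test in kf.split(xf):
            bf, *_ = np.linalg.lstsq(xf[train], y[train], rcond=None)
            bc, *_ = np.linalg.lstsq(xc[train], y[train], rcond=None)
            sse_f += float(np.sum((y[test] - xf[test] @ bf) ** 2))
            sse_c += float(np.sum((y[test] - xc[test] @ bc) ** 2))
        deltas.append((1.0 - sse_f / sst) - (1.0 - sse_c / sst))
    return float(np.mean(deltas))


def compare_estimates(beta1: float, se1: float,
                      beta2: float, se2: float) -> tuple[float, float]:
    """Clogg z-test for the difference of two regression coefficients:
    z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta1 - beta2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def compare_general_specific(meta_general, meta_specific) -> tuple[float, float]:
    """Clogg comparison of a PRS's pooled general-factor effect against its
    pooled specific-factor effect (MetaResult-like inputs with .beta/.se)."""
    return compare_estimates(meta_general.beta, meta_general.se,
                             meta_specific.beta, meta_specific.se)


def average_r2(r_values, sample_sizes) -> float:
    """Sample-size weighted average R^2 across cohorts: (sum n_i r_i / sum n_i)^2.

    Signed r values enter the weighted mean, so opposing directions cancel
    before squaring.
    """
    r = np.asarray(r_values, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if r.shape != n.shape:
        raise ValueError("r values and sample sizes must have equal length")
    if np.any(np.abs(r) > 1):
        raise ValueError("|r| must be at most 1")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    return float((np.sum(n * r) / np.sum(n)) ** 2)
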