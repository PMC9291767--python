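"""Orchestration of the full multi-PRS study.

Per cohort: C+T polygenic scores for every trait -> bifactor factor scores ->
separate PRS regressions at every threshold for all three outcomes.  Across
cohorts: Han-Eskin random-effects meta-analysis of every trait x threshold x
outcome cell, Li-Ji multiplicity adjustment over the PRS grid of the largest
cohort, per-trait best-threshold selection by meta p, a mutually adjusted
16-PRS model of the general factor, independence flags, and repeated 10-fold
cross-validated joint Delta R^2.

Two entry points: :func:`run_synthetic_study` runs everything in memory from a
:class:`~multiprs.synthetic_data.SimConfig`; :func:`run_cohort` /
:func:`run_meta` operate on files described by a YAML :class:`PipelineConfig`.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import bifactor as bf
from . import meta as meta_mod
from . import prs_engine as prs
from . import synthetic_data as synth

logger = logging.getLogger("multiprs.pipeline")

__all__ = [
    "PipelineConfig",
    "CohortSpec",
    "CohortBundle",
    "StudyResult",
    "stage_seed",
    "run_cohort",
    "run_meta",
    "run_synthetic_study",
]

OUTCOMES = ("general", "spec_ext", "spec_int")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (zlib.crc32(stage.encode()) ^ master_seed) % (2**31)


@dataclass
class CohortSpec:
    name: str
    genotypes: str = ""
    sumstats: dict[str, str] = field(default_factory=dict)
    subscales: str = ""
    covariates: str = ""
    clump_kb: float = 250.0
    clump_r2: float = 0.1


@dataclass
class PipelineConfig:
    cohorts: list[CohortSpec]
    thresholds: tuple[float, ...] = prs.DEFAULT_THRESHOLDS
    alpha: float = 0.05
    cv_folds: int = 10
    cv_repeats: int = 100
    outdir: str = "multiprs_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        traits = None
        for c in self.cohorts:
            t = set(c.sumstats)
            if traits is None:
                traits = t
            elif t != traits:
                missing = traits.symmetric_difference(t)
                raise ValueError(f"trait mismatch across cohorts: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortSpec(**c) for c in raw.pop("cohorts")]
        if "thresholds" in raw:
            raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
        return cls(cohorts=cohorts, **raw)


@dataclass
class CohortBundle:
    """Everything the meta stage needs from one cohort."""

    name: str
    n: int
    scores: pd.DataFrame                       # factor scores (3 columns)
    covariates: pd.DataFrame
    profiles: dict[str, prs.PrsProfile]        # trait -> PRS profile
    associations: pd.DataFrame                 # separate-model results
    fit: bf.BifactorFit | None = None
    reports: dict[str, dict] = field(default_factory=dict)


@dataclass
class StudyResult:
    separate: pd.DataFrame          # per-cohort association rows
    meta_table: pd.DataFrame        # trait x threshold x outcome meta rows
    best: pd.DataFrame              # selected-threshold meta rows (Tables 2/3 style)
    mutual: pd.DataFrame            # mutually adjusted model (Table 4 style)
    meff: meta_mod.EffectiveTests
    adjusted_alpha: float
    combined_n: int
    cv_delta_r2: dict[str, float]   # per-cohort and weighted average
    cv_delta_r2_all: dict[str, float]


# ---------------------------------------------------------------------------
# Per-cohort stage
# ---------------------------------------------------------------------------

def _cohort_bundle(name: str, sumstats: dict[str, pd.DataFrame],
                   panel: synth.GenotypePanel, subscales: pd.DataFrame,
                   covariates: pd.DataFrame, domain_map: list[str],
                   clump_params: prs.ClumpParams,
                   thresholds: tuple[float, ...]) -> CohortBundle:
    """Run the per-cohort stages: PRS, bifactor scores, separate models."""
    fit = bf.fit_bifactor(subscales, domain_map)
    scores = bf.factor_scores(fit, subscales)

    profiles: dict[str, prs.PrsProfile] = {}
    reports: dict[str, dict] = {}
    rows = []
    for trait, table in sumstats.items():
        profile, report = prs.compute_prs(table, panel, clump_params, thresholds)
        if report["n_matched"] == 0:
            logger.warning("cohort %s trait %s: no overlapping SNPs, skipped",
                           name, trait)
            continue
        profiles[trait] = profile
        reports[trait] = report
        pframe = profile.to_frame()
        pframe.index = scores.index  # same individuals, same order
        for outcome in OUTCOMES:
            for t in profile.thresholds:
                col = pframe[f"T{t:g}"]
                if col.std() == 0:     # no SNPs survive this cutoff
                    continue
                res = assoc.fit_separate_model(
                    scores[outcome], col, covariates, trait=trait,
                    threshold=t, outcome_name=outcome)
                rows.append({"cohort": name, "trait": trait, "threshold": t,
                             "outcome": outcome, "beta": res.beta_std,
                             "se": res.se, "p": res.p,
                             "delta_r2": res.delta_r2, "n": res.n})
    associations = pd.DataFrame(rows)
    logger.info("cohort %s: %d individuals, %d traits, %d association rows",
                name, panel.n, len(profiles), len(associations))
    return CohortBundle(name=name, n=panel.n, scores=scores,
                        covariates=covariates, profiles=profiles,
                        associations=associations, fit=fit, reports=reports)


def run_cohort(config: PipelineConfig, spec: CohortSpec,
               domain_map: list[str] | None = None) -> CohortBundle:
    """File-based per-cohort stage: read inputs, compute, write outputs."""
    panel = synth.read_dosage_matrix(spec.genotypes)
    sumstats = {t: synth.read_sumstats(p) for t, p in spec.sumstats.items()}
    subscales = pd.read_csv(spec.subscales, index_col=0)
    covariates = pd.read_csv(spec.covariates, index_col=0)
    if domain_map is None:
        domain_map = ["int" if c.startswith("int") else "ext"
                      for c in subscales.columns]
    bundle = _cohort_bundle(spec.name, sumstats, panel, subscales, covariates,
                            domain_map,
                            prs.ClumpParams(spec.clump_kb, spec.clump_r2),
                            config.thresholds)
    out = Path(config.outdir) / spec.name
    out.mkdir(parents=True, exist_ok=True)
    bundle.scores.to_csv(out / "factor_scores.csv")
    for trait, profile in bundle.profiles.items():
        profile.to_tsv(out / f"prs_{trait}.tsv")
    bundle.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    return bundle


# ---------------------------------------------------------------------------
# Study-level stage
# ---------------------------------------------------------------------------

def _prs_grid_matrix(bundle: CohortBundle) -> pd.DataFrame:
    """All trait x threshold PRS columns of one cohort (zero-variance columns
    dropped — thresholds that admit no SNPs)."""
    cols = {}
    for trait, profile in bundle.profiles.items():
        for k, t in enumerate(profile.thresholds):
            col = profile.scores[:, k]
            if col.std() > 0:
                cols[f"{trait}@T{t:g}"] = col
    return pd.DataFrame(cols)


def run_meta(bundles: list[CohortBundle], alpha: float = 0.05,
             cv: assoc.CvConfig | None = None,
             outdir: str | Path | None = None) -> StudyResult:
    """Meta-analyze cohort bundles and run the mutually adjusted stage."""
    if len(bundles) < 2:
        raise ValueError("meta-analysis requires at least 2 cohorts; got "
                         f"{len(bundles)}")
    cv = cv or assoc.CvConfig()
    separate = pd.concat([b.associations for b in bundles], ignore_index=True)
    trait_sets = [set(b.profiles) for b in bundles]
    if any(t != trait_sets[0] for t in trait_sets[1:]):
        raise ValueError("trait sets differ across cohorts: "
                         f"{set.union(*trait_sets) - set.intersection(*trait_sets)}")
    combined_n = int(sum(b.n for b in bundles))

    # -- meta-analysis of every cell -----------------------------------
    rows = []
    for (trait, thr, outcome), cell in separate.groupby(
            ["trait", "threshold", "outcome"]):
        if len(cell) < 2:
            continue
        mi = meta_mod.MetaInput(betas=tuple(cell["beta"]),
                                ses=tuple(cell["se"]),
                                labels=tuple(cell["cohort"]),
                                ns=tuple(int(x) for x in cell["n"]))
        mr = meta_mod.meta_analyze(mi)
        rows.append({"trait": trait, "threshold": thr, "outcome": outcome,
                     "beta": mr.beta, "tau": mr.tau, "se": mr.se,
                     "statistic": mr.statistic, "p": mr.p, "n": mr.n})
    meta_table = pd.DataFrame(rows)

    # -- multiplicity: Li-Ji Meff on the largest cohort's PRS grid -----
    largest = max(bundles, key=lambda b: b.n)
    grid = _prs_grid_matrix(largest)
    corr = np.corrcoef(grid.to_numpy(), rowvar=False)
    eff = meta_mod.meff_li_ji(corr, alpha)
    adj_alpha = eff.adjusted_alpha

    # -- best threshold per trait x outcome ----------------------------
    best_rows = []
    for (trait, outcome), sub in meta_table.groupby(["trait", "outcome"]):
        pseries = sub.set_index("threshold")["p"]
        thr = assoc.select_best_threshold(pseries)
        row = sub[sub["threshold"] == thr].iloc[0].to_dict()
        row["significant_adjusted"] = row["p"] < adj_alpha
        best_rows.append(row)
    best = pd.DataFrame(best_rows)

    # -- mutually adjusted model on the general factor -----------------
    sel = {r["trait"]: r["threshold"] for _, r in
           best[best["outcome"] == "general"].iterrows()}
    mutual_percohort = []
    for b in bundles:
        prs_table = pd.DataFrame(
            {trait: b.profiles[trait].column(thr)
             for trait, thr in sel.items() if trait in b.profiles},
            index=b.scores.index)
        res = assoc.fit_mutual_model(b.scores["general"], prs_table,
                                     b.covariates, thresholds=sel,
                                     outcome_name="general")
        for trait, r in res.items():
            mutual_percohort.append({"cohort": b.name, "trait": trait,
                                     "threshold": r.threshold,
                                     "beta": r.beta_std, "se": r.se,
                                     "p": r.p, "n": r.n,
                                     "joint_delta_r2": r.delta_r2})
    mut_df = pd.DataFrame(mutual_percohort)
    mut_rows = []
    sep_best_gen = best[best["outcome"] == "general"].set_index("trait")
    for trait, cell in mut_df.groupby("trait"):
        mi = meta_mod.MetaInput(betas=tuple(cell["beta"]),
                                ses=tuple(cell["se"]),
                                labels=tuple(cell["cohort"]),
                                ns=tuple(int(x) for x in cell["n"]))
        mr = meta_mod.meta_analyze(mi)
        p_sep = float(sep_best_gen.loc[trait, "p"])
        mut_rows.append({
            "trait": trait, "threshold": sel[trait], "beta": mr.beta,
            "tau": mr.tau, "se": mr.se, "p": mr.p, "n": mr.n,
            "p_separate": p_sep,
            "significant_adjusted": p_sep < adj_alpha,
            "independent": meta_mod.flag_independent(p_sep, mr.p, adj_alpha),
        })
    mutual = pd.DataFrame(mut_rows)

    # -- cross-validated joint Delta R^2 -------------------------------
    sig_traits = list(mutual.loc[mutual["significant_adjusted"], "trait"])
    cv_sig: dict[str, float] = {}
    cv_all: dict[str, float] = {}
    for b in bundles:
        prs_table = pd.DataFrame(
            {trait: b.profiles[trait].column(sel[trait])
             for trait in sel if trait in b.profiles}, index=b.scores.index)
        cohort_cv = assoc.CvConfig(cv.k, cv.repeats,
                                   stage_seed(cv.seed, f"cv:{b.name}"))
        cv_all[b.name] = assoc.cv_delta_r2(b.scores["general"], prs_table,
                                           b.covariates, cohort_cv)
        if sig_traits:
            cv_sig[b.name] = assoc.cv_delta_r2(
                b.scores["general"], prs_table[sig_traits], b.covariates,
                cohort_cv)
    ns = np.array([b.n for b in bundles], dtype=float)
    if cv_sig:
        cv_sig["average"] = float(np.sum(
            ns * np.array([cv_sig[b.name] for b in bundles])) / ns.sum())
    cv_all["average"] = float(np.sum(
        ns * np.array([cv_all[b.name] for b in bundles])) / ns.sum())

    result = StudyResult(separate=separate, meta_table=meta_table, best=best,
                         mutual=mutual, meff=eff, adjusted_alpha=adj_alpha,
                         combined_n=combined_n, cv_delta_r2=cv_sig,
                         cv_delta_r2_all=cv_all)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta_table.to_csv(out / "meta_full_grid.tsv", sep="\t", index=False)
        best.to_csv(out / "meta_best_threshold.tsv", sep="\t", index=False)
        mutual.to_csv(out / "mutual_model.tsv", sep="\t", index=False)
        pd.DataFrame({"meff": [eff.meff], "alpha": [alpha],
                      "adjusted_alpha": [adj_alpha],
                      "combined_n": [combined_n]}).to_csv(
            out / "multiplicity.tsv", sep="\t", index=False)
    logger.info("meta stage: combined n=%d, Meff=%d, adjusted alpha=%.3g",
                combined_n, eff.meff, adj_alpha)
    return result


# ---------------------------------------------------------------------------
# All-synthetic study
# ---------------------------------------------------------------------------

def run_synthetic_study(config: synth.SimConfig,
                        cohort_sizes: tuple[int, ...] | None = None,
                        clump_params: tuple[prs.ClumpParams, ...] | None = None,
                        thresholds: tuple[float, ...] = prs.DEFAULT_THRESHOLDS,
                        alpha: float = 0.05,
                        cv: assoc.CvConfig | None = None,
                        master_seed: int | None = None) -> StudyResult:
    """Generate the synthetic cohorts and run the whole study in memory.

    Cohort sizes default to ``config.n_individuals`` each; clump parameters
    default to 250 kb / r^2 0.1 for the first two cohorts and 500 kb / 0.25
    for the third (the two settings the real cohorts used).
    """
    master = config.seed if master_seed is None else master_seed
    sizes = cohort_sizes or tuple([config.n_individuals] * config.n_cohorts)
    if clump_params is None:
        default = [prs.ClumpParams(250.0, 0.1)] * len(sizes)
        if len(sizes) >= 3:
            default[2] = prs.ClumpParams(500.0, 0.25)
        clump_params = tuple(default)

    variants = synth.draw_variants(
        config, np.random.default_rng(stage_seed(master, "variants")))
    effects = synth.draw_true_effects(
        config, np.random.default_rng(stage_seed(master, "effects")),
        maf=variants["maf"].to_numpy())
    sumstats = synth.simulate_discovery_gwas(
        config, effects, variants,
        np.random.default_rng(stage_seed(master, "gwas")))

    bundles = []
    for i, (n_i, cp) in enumerate(zip(sizes, clump_params)):
        label = f"cohort{i+1}"
        panel = synth.simulate_genotypes(
            config, n_i, np.random.default_rng(stage_seed(master, f"geno:{label}")),
            cohort_label=label, variants=variants)
        phen = synth.simulate_cohort_phenotypes(
            config, panel, effects,
            np.random.default_rng(stage_seed(master, f"pheno:{label}")),
            cohort_index=i)
        bundles.append(_cohort_bundle(
            label, sumstats, panel, phen.subscales, phen.covariates,
            config.domain_map, cp, thresholds))

    cv = cv or assoc.CvConfig(seed=stage_seed(master, "cv"))
    return run_meta(bundles, alpha=alpha, cv=cv)
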