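"""Synthetic cohorts with known ground truth for the multi-PRS analysis.

Three ingredients are generated, mirroring the statistical structure the
downstream pipeline assumes:

* **Genotypes** — LD-blocked dosages via a Gaussian-copula haplotype model:
  within a block, latent normals follow a Toeplitz (AR-1 style) correlation,
  each is thresholded at the allele-frequency quantile to give a 0/1 haplotype,
  and two independent haplotypes sum to a dosage in {0, 1, 2}.  The latent
  correlation is calibrated numerically so the *realized haplotype* correlation
  between adjacent SNPs matches ``within_block_rho`` (plain thresholding would
  attenuate it).
* **Discovery GWAS summary statistics** — sparse causal effects drawn with a
  specified cross-trait genetic correlation and scaled to a per-trait SNP
  heritability; the reported (marginal) effect of each SNP is the LD-implied
  convolution of the causal effects in its block plus Wald noise with
  SE = 1/sqrt(2 N f (1-f)).
* **Phenotypes** — multi-informant-style symptom subscales produced by a
  bifactor structure: a general factor (a weighted sum of true standardized
  polygenic values plus residual, unit variance), orthogonal specific
  internalizing/externalizing factors, loadings and uniquenesses per subscale,
  and covariates (sex, age, four ancestry-proxy components).

Everything is driven by a single integer seed; identical configs and seeds
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SimConfig",
    "GenotypePanel",
    "CohortPhenotypes",
    "draw_variants",
    "simulate_genotypes",
    "draw_true_effects",
    "simulate_discovery_gwas",
    "simulate_cohort_phenotypes",
    "write_sumstats",
    "read_sumstats",
    "write_dosage_matrix",
    "read_dosage_matrix",
    "write_vcf",
]

#: default age windows per cohort (years), cycled by cohort index; they mirror
#: the assessment-age ranges of three school-age cohorts.
AGE_WINDOWS = ((7.5, 8.3), (6.0, 8.1), (4.1, 6.2))

#: non-strand-ambiguous allele pairs (effect, other)
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


def _default_genetic_corr(n_traits: int) -> np.ndarray:
    """Compound-symmetric genetic correlation, off-diagonal 0.4.

    Psychiatric traits show average pairwise genetic correlations around 0.4;
    a single exchangeable value keeps the matrix trivially PSD.
    """
    c = np.full((n_traits, n_traits), 0.4)
    np.fill_diagonal(c, 1.0)
    return c


def _default_effects(n_traits: int, value: float, index: int | None) -> np.ndarray:
    w = np.zeros(n_traits)
    if index is not None:
        w[index] = value
    return w


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults describe the simulated study the test-suite runs: three cohorts,
    a 2,000-SNP genome in 5-SNP LD blocks, 16 genetically correlated discovery
    traits with a sparse causal architecture, twelve symptom subscales (six
    internalizing, six externalizing) loading 0.6 on the general factor and
    0.4 on their domain factor, and one trait with a planted 0.10 SD effect on
    the general factor.
    """

    n_individuals: int = 6000
    n_cohorts: int = 3
    n_snps: int = 2000
    block_size: int = 5
    within_block_rho: float = 0.25
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 16
    genetic_corr: np.ndarray | None = None
    discovery_n: int = 100_000
    causal_fraction: float = 0.25
    h2: float = 0.3
    n_subscales_int: int = 6
    n_subscales_ext: int = 6
    general_loadings: np.ndarray | None = None
    specific_loadings: np.ndarray | None = None
    prs_effects_general: np.ndarray | None = None
    prs_effects_specific_ext: np.ndarray | None = None
    prs_effects_specific_int: np.ndarray | None = None
    confound_strength: float = 0.0
    snp_spacing_bp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genetic_corr is None:
            self.genetic_corr = _default_genetic_corr(self.n_traits)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        if self.general_loadings is None:
            # heterogeneous loadings, non-proportional within each domain:
            # with constant loadings the general and a specific factor are
            # rotationally exchangeable and the bifactor fit is empirically
            # underidentified
            self.general_loadings = np.concatenate([
                np.linspace(0.75, 0.90, self.n_subscales_int),
                np.linspace(0.75, 0.90, self.n_subscales_ext)])
        if self.specific_loadings is None:
            self.specific_loadings = np.concatenate([
                np.linspace(0.35, 0.20, self.n_subscales_int),
                np.linspace(0.35, 0.20, self.n_subscales_ext)])
        self.general_loadings = np.asarray(self.general_loadings, dtype=float)
        self.specific_loadings = np.asarray(self.specific_loadings, dtype=float)
        if self.prs_effects_general is None:
            self.prs_effects_general = _default_effects(self.n_traits, 0.10, 0)
        if self.prs_effects_specific_ext is None:
            self.prs_effects_specific_ext = _default_effects(self.n_traits, 0.0, None)
        if self.prs_effects_specific_int is None:
            self.prs_effects_specific_int = _default_effects(self.n_traits, 0.0, None)
        self.prs_effects_general = np.asarray(self.prs_effects_general, float)
        self.prs_effects_specific_ext = np.asarray(self.prs_effects_specific_ext, float)
        self.prs_effects_specific_int = np.asarray(self.prs_effects_specific_int, float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must be in (0, 1]")
        c = self.genetic_corr
        if c.shape != (self.n_traits, self.n_traits):
            raise ValueError("genetic_corr must be n_traits x n_traits")
        if not np.allclose(c, c.T):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("genetic_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("genetic_corr must be positive semidefinite")
        uniq = 1.0 - self.general_loadings**2 - self.specific_loadings**2
        if np.any(uniq <= 0):
            raise ValueError("loadings imply non-positive unique variance")

    @property
    def n_subscales(self) -> int:
        return self.n_subscales_int + self.n_subscales_ext

    @property
    def domain_map(self) -> list[str]:
        return ["int"] * self.n_subscales_int + ["ext"] * self.n_subscales_ext


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x SNPs) with variant metadata.

    ``variants`` columns: snp_id, chrom, pos, a1 (counted/effect allele),
    a2, maf (drawn allele frequency of a1), eaf_sample, info, block.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    variants: pd.DataFrame

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class CohortPhenotypes:
    subscales: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Gaussian-copula genotypes
# ---------------------------------------------------------------------------

def _binary_corr(latent_rho: float, f1: float, f2: float) -> float:
    """Pearson correlation of two thresholded-normal Bernoulli haplotypes."""
    if latent_rho == 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    cov = np.array([[1.0, latent_rho], [latent_rho, 1.0]])
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2])
    return float((p11 - f1 * f2) / math.sqrt(f1 * (1 - f1) * f2 * (1 - f2)))


@lru_cache(maxsize=4096)
def _calibrate_latent_rho(target: float, f: float) -> float:
    """Latent-normal correlation whose thresholded haplotype correlation is
    ``target`` at allele frequency ``f`` (both thresholds equal)."""
    if target == 0.0:
        return 0.0
    lo, hi = target, 0.999999
    if _binary_corr(hi, f, f) < target:  # pragma: no cover - extreme MAF guard
        return hi
    return float(optimize.brentq(lambda r: _binary_corr(r, f, f) - target,
                                 lo, hi, xtol=1e-6))


def _block_latent_corr(maf_block: np.ndarray, rho: float) -> np.ndarray:
    """Toeplitz latent correlation for one block, calibrated at the block's
    mean allele frequency so adjacent haplotype correlation matches ``rho``."""
    b = len(maf_block)
    if rho == 0.0 or b == 1:
        return np.eye(b)
    f = round(float(np.mean(maf_block)), 3)
    base = _calibrate_latent_rho(round(rho, 6), f)
    d = np.abs(np.subtract.outer(np.arange(b), np.arange(b)))
    return base ** d


def implied_dosage_corr(maf_block: np.ndarray, rho: float) -> np.ndarray:
    """LD (dosage correlation) matrix implied by the copula for one block."""
    latent = _block_latent_corr(maf_block, rho)
    b = len(maf_block)
    out = np.eye(b)
    for i in range(b):
        for j in range(i + 1, b):
            r = _binary_corr(float(latent[i, j]), float(maf_block[i]),
                             float(maf_block[j]))
            out[i, j] = out[j, i] = r
    return out


def draw_variants(config: SimConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the variant frame (ids, positions, alleles, MAFs, INFO) shared by
    every cohort panel and by the discovery GWAS."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m, bs = config.n_snps, config.block_size
    lo, hi = config.maf_range
    n_blocks = math.ceil(m / bs)
    # one frequency per LD block: tightly linked variants share similar
    # allele frequencies, and equal thresholds keep the copula calibration exact
    maf = np.repeat(rng.uniform(lo, hi, size=n_blocks), bs)[:m]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    return pd.DataFrame({
        "snp_id": [f"rs{i+1}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * config.snp_spacing_bp,
        "a1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "a2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "maf": maf,
        "eaf_sample": np.nan,
        "info": rng.uniform(0.90, 1.0, size=m),
        "block": np.repeat(np.arange(n_blocks), bs)[:m],
    })


def simulate_genotypes(config: SimConfig, n_individuals: int | None = None,
                       rng: np.random.Generator | None = None,
                       cohort_label: str = "C1",
                       variants: pd.DataFrame | None = None) -> GenotypePanel:
    """Draw an LD-blocked dosage panel.

    Dosages count copies of the effect allele ``a1``; adjacent SNPs within a
    block have dosage correlation approximately ``within_block_rho`` and
    blocks are independent.  Pass a shared ``variants`` frame (from
    :func:`draw_variants`) to simulate several cohorts on the same SNP set.
    """
    config.validate()
    n = n_individuals or config.n_individuals
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if variants is None:
        variants = draw_variants(config, rng)
    m, bs = config.n_snps, config.block_size
    maf = variants["maf"].to_numpy()
    dosages = np.empty((n, m), dtype=np.float64)
    n_blocks = math.ceil(m / bs)
    for b in range(n_blocks):
        sl = slice(b * bs, min((b + 1) * bs, m))
        fb = maf[sl]
        corr = _block_latent_corr(fb, config.within_block_rho)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(fb)))
        thresh = stats.norm.ppf(fb)
        block = np.zeros((n, len(fb)))
        for _hap in range(2):
            z = rng.standard_normal((n, len(fb))) @ chol.T
            block += (z < thresh)
        dosages[:, sl] = block

    variants = variants.copy()
    variants["eaf_sample"] = dosages.mean(axis=0) / 2.0
    ids = [f"{cohort_label}_{i+1:05d}" for i in range(n)]
    return GenotypePanel(dosages=dosages, individual_ids=ids, variants=variants)


# ---------------------------------------------------------------------------
# Discovery GWAS
# ---------------------------------------------------------------------------

def draw_true_effects(config: SimConfig,
                      rng: np.random.Generator | None = None,
                      maf: np.ndarray | None = None) -> np.ndarray:
    """Draw causal per-allele effects (SNPs x traits).

    A shared causal set of size ``causal_fraction * n_snps`` receives effect
    vectors that are multivariate normal across traits with correlation
    ``genetic_corr``; each trait column is then rescaled so the causal
    variance sum(beta^2 * 2 f (1-f)) equals ``h2``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    m = config.n_snps
    if maf is None:
        lo, hi = config.maf_range
        maf = rng.uniform(lo, hi, size=m)
    n_causal = max(1, int(round(config.causal_fraction * m)))
    causal = rng.choice(m, size=n_causal, replace=False)
    chol = np.linalg.cholesky(config.genetic_corr +
                              1e-10 * np.eye(config.n_traits))
    raw = rng.standard_normal((n_causal, config.n_traits)) @ chol.T
    effects = np.zeros((m, config.n_traits))
    effects[causal, :] = raw
    v = 2.0 * maf * (1.0 - maf)
    for t in range(config.n_traits):
        s = float(np.sum(effects[:, t] ** 2 * v))
        if s > 0:
            effects[:, t] *= math.sqrt(config.h2 / s)
    return effects


def simulate_discovery_gwas(config: SimConfig, true_effects: np.ndarray,
                            variants: pd.DataFrame,
                            rng: np.random.Generator | None = None,
                            ld_aware: bool = True) -> dict[str, pd.DataFrame]:
    """Per-trait discovery summary statistics.

    The reported effect of SNP j is its marginal association: the LD-implied
    combination of causal effects in its block (``ld_aware=True``; with
    independent SNPs this reduces to the causal effect itself) plus Gaussian
    noise with SE = 1/sqrt(2 N f (1-f)).  P-values are two-sided Wald.
    """
    if config.discovery_n <= 0:
        raise ValueError("discovery_n must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    maf = variants["maf"].to_numpy()
    m = len(maf)
    true_effects = np.asarray(true_effects, float)
    if true_effects.shape[0] != m:
        raise ValueError("true_effects rows must match number of variants")

    if ld_aware and config.within_block_rho > 0:
        marginal = np.zeros_like(true_effects)
        # marginal beta_i = sum_j r_ij * beta_j * sd_j / sd_i over the block
        sd = np.sqrt(2.0 * maf * (1.0 - maf))
        for _, idx in variants.groupby("block").groups.items():
            idx = np.asarray(idx)
            r = implied_dosage_corr(maf[idx], config.within_block_rho)
            scale = np.outer(1.0 / sd[idx], sd[idx])
            marginal[idx, :] = (r * scale) @ true_effects[idx, :]
    else:
        marginal = true_effects

    se = 1.0 / np.sqrt(2.0 * config.discovery_n * maf * (1.0 - maf))
    out: dict[str, pd.DataFrame] = {}
    for t in range(config.n_traits):
        beta_hat = marginal[:, t] + rng.standard_normal(m) * se
        z = beta_hat / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        eaf = maf + rng.standard_normal(m) * np.sqrt(
            maf * (1 - maf) / (2.0 * config.discovery_n))
        out[f"trait{t+1:02d}"] = pd.DataFrame({
            "SNP": variants["snp_id"].to_numpy(),
            "CHR": variants["chrom"].to_numpy(),
            "BP": variants["pos"].to_numpy(),
            "A1": variants["a1"].to_numpy(),
            "A2": variants["a2"].to_numpy(),
            "BETA": beta_hat,
            "SE": se,
            "P": np.clip(p, 1e-300, 1.0),
            "EAF": np.clip(eaf, 1e-3, 1 - 1e-3),
            "INFO": rng.uniform(0.90, 1.0, size=m),
        })
    return out


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _standardize_cols(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _factor(rng: np.random.Generator, u_std: np.ndarray, weights: np.ndarray,
            genetic_corr: np.ndarray, n: int) -> np.ndarray:
    """Weighted polygenic combination plus residual, total variance one."""
    explained = float(weights @ genetic_corr @ weights)
    if explained >= 1.0:
        raise ValueError("prs effects imply factor variance above 1")
    resid_sd = math.sqrt(1.0 - explained)
    return u_std @ weights + resid_sd * rng.standard_normal(n)


def simulate_cohort_phenotypes(config: SimConfig, panel: GenotypePanel,
                               true_effects: np.ndarray,
                               rng: np.random.Generator | None = None,
                               cohort_index: int = 0) -> CohortPhenotypes:
    """Bifactor-structured subscales, covariates and true factor values.

    The general factor is a weighted sum of true standardized polygenic values
    (weights ``prs_effects_general``) plus a Gaussian residual sized for unit
    variance; specific factors are built the same way from independent
    residuals, so the three factors are orthogonal in expectation.  Subscale
    j is lg_j*g + ls_j*s_domain(j) + sqrt(psi_j)*noise with
    psi_j = 1 - lg_j^2 - ls_j^2.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    n = panel.n
    lg, ls = config.general_loadings, config.specific_loadings
    psi = 1.0 - lg**2 - ls**2
    if np.any(psi <= 0):
        raise ValueError("loadings imply negative unique variance")

    g_centered = panel.dosages - panel.dosages.mean(axis=0)
    u = g_centered @ true_effects                     # true polygenic values
    u_std = _standardize_cols(u)

    c = config.genetic_corr
    g = _factor(rng, u_std, config.prs_effects_general, c, n)
    s_ext = _factor(rng, u_std, config.prs_effects_specific_ext, c, n)
    s_int = _factor(rng, u_std, config.prs_effects_specific_int, c, n)

    pcs = rng.standard_normal((n, 4))
    if config.confound_strength:
        g = g + config.confound_strength * pcs[:, 0]

    dom = config.domain_map
    s_mat = np.where(np.array(dom) == "ext", s_ext[:, None], s_int[:, None])
    noise = rng.standard_normal((n, config.n_subscales))
    y = g[:, None] * lg + s_mat * ls + noise * np.sqrt(psi)

    ids = panel.individual_ids
    sub_cols = ([f"int{i+1}" for i in range(config.n_subscales_int)] +
                [f"ext{i+1}" for i in range(config.n_subscales_ext)])
    subscales = pd.DataFrame(y, columns=sub_cols, index=ids)
    subscales.index.name = "iid"

    lo_age, hi_age = AGE_WINDOWS[cohort_index % len(AGE_WINDOWS)]
    covariates = pd.DataFrame({
        "sex": rng.integers(0, 2, size=n),
        "age": rng.uniform(lo_age, hi_age, size=n),
        "pc1": pcs[:, 0], "pc2": pcs[:, 1],
        "pc3": pcs[:, 2], "pc4": pcs[:, 3],
    }, index=ids)
    covariates.index.name = "iid"

    truth = pd.DataFrame({"general": g, "spec_ext": s_ext, "spec_int": s_int},
                         index=ids)
    truth.index.name = "iid"
    for t in range(config.n_traits):
        truth[f"poly_trait{t+1:02d}"] = u_std[:, t]
    return CohortPhenotypes(subscales=subscales, covariates=covariates,
                            truth=truth)


# ---------------------------------------------------------------------------
# Text-format writers / readers
# ---------------------------------------------------------------------------

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "EAF", "INFO"]


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    table[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CHR": str})


def write_dosage_matrix(panel: GenotypePanel, path: str | Path) -> None:
    """Dosage TSV: one row per individual, one column per SNP, plus a
    side-car ``<path>.vars`` TSV with variant metadata."""
    df = pd.DataFrame(panel.dosages, index=panel.individual_ids,
                      columns=panel.variants["snp_id"])
    df.index.name = "iid"
    df.to_csv(path, sep="\t", float_format="%g")
    panel.variants.to_csv(str(path) + ".vars", sep="\t", index=False)


def read_dosage_matrix(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col="iid")
    variants = pd.read_csv(str(path) + ".vars", sep="\t", dtype={"chrom": str})
    return GenotypePanel(dosages=df.to_numpy(dtype=float),
                         individual_ids=[str(i) for i in df.index],
                         variants=variants)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF 4.2 with a DS (dosage) FORMAT field, a2 as REF and the
    counted allele a1 as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" +
                 "\t".join(panel.individual_ids) + "\n")
        v = panel.variants
        for j in range(panel.m):
            row = [str(v.chrom.iat[j]), str(int(v.pos.iat[j])), v.snp_id.iat[j],
                   v.a2.iat[j], v.a1.iat[j], ".", "PASS", ".", "DS"]
            row += [f"{d:g}" for d in panel.dosages[:, j]]
            fh.write("\t".join(row) + "\n")
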