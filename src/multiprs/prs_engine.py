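"""Clumping + thresholding (C+T) polygenic scoring from GWAS summary statistics.

The classic PRSice-style pipeline: QC-filter summary statistics against the
target panel (MAF and imputation INFO cutoffs), harmonize effect alleles to the
panel's counted allele (sign flips for swapped alleles, strand-ambiguous A/T
and C/G variants dropped), greedily clump correlated SNPs (smallest p first,
removing neighbours within a window whose dosage r^2 exceeds the cutoff, LD
measured in the target panel itself), and finally score individuals at a
descending grid of p-value thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import GenotypePanel

logger = logging.getLogger("multiprs.prs")

__all__ = [
    "ClumpParams",
    "PrsProfile",
    "DEFAULT_THRESHOLDS",
    "qc_filter",
    "harmonize_alleles",
    "clump",
    "score",
    "compute_prs",
    "read_vcf_panel",
]

#: the standard 15-threshold grid of p-value cutoffs
DEFAULT_THRESHOLDS = (1.0, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01,
                      1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 5e-8, 1e-8)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping settings: half-window in kb and the r^2 cutoff."""

    window_kb: float = 250.0
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValueError("r2_max must be in [0, 1]")


@dataclass
class PrsProfile:
    """Polygenic scores for one trait: individuals x thresholds."""

    individual_ids: list[str]
    thresholds: tuple[float, ...]
    scores: np.ndarray
    n_snps: tuple[int, ...]
    standardized: bool

    def column(self, threshold: float) -> np.ndarray:
        return self.scores[:, self.thresholds.index(threshold)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.individual_ids,
                          columns=[f"T{t:g}" for t in self.thresholds])
        df.index.name = "iid"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def validate_records(records: pd.DataFrame) -> None:
    """Sanity checks on a canonical summary-stat table."""
    bad_p = ~((records["P"] > 0) & (records["P"] <= 1))
    if bad_p.any():
        raise ValueError(f"{int(bad_p.sum())} records with p outside (0, 1]")
    valid = records["A1"].isin(list("ACGT")) & records["A2"].isin(list("ACGT"))
    if (~valid).any() or (records["A1"] == records["A2"]).any():
        raise ValueError("alleles must be distinct single nucleotides ACGT")
    if "EAF" in records and not ((records["EAF"] > 0) & (records["EAF"] < 1)).all():
        raise ValueError("EAF must lie strictly in (0, 1)")


def qc_filter(records: pd.DataFrame, panel_variants: pd.DataFrame | None = None,
              maf_min: float = 0.01, info_min: float = 0.80) -> pd.DataFrame:
    """Drop variants with MAF below ``maf_min`` or INFO below ``info_min``.

    MAF/INFO are taken from the target panel metadata when provided (joined on
    snp_id), otherwise from the records themselves (MAF folded from EAF).
    """
    if panel_variants is not None:
        meta = panel_variants.set_index("snp_id")
        keep_ids = records["SNP"].isin(meta.index)
        if not keep_ids.any():
            warnings.warn("no summary-stat variants overlap the panel")
            return records.iloc[0:0]
        sub = records[keep_ids]
        maf = meta.loc[sub["SNP"], "maf"].to_numpy()
        maf = np.minimum(maf, 1.0 - maf)
        info = meta.loc[sub["SNP"], "info"].to_numpy()
    else:
        sub = records
        maf = np.minimum(sub["EAF"].to_numpy(), 1.0 - sub["EAF"].to_numpy())
        info = sub["INFO"].to_numpy()
    mask = (maf >= maf_min) & (info >= info_min)
    out = sub[mask]
    logger.info("qc_filter: retained %d of %d variants", len(out), len(records))
    return out


def harmonize_alleles(records: pd.DataFrame,
                      panel_variants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Match summary-stat effect alleles to the panel's counted allele.

    Joined on (chrom, pos), falling back to snp_id for records without a
    positional match.  Matching orientation keeps beta; swapped alleles negate
    beta and complement EAF; strand-ambiguous (A/T, C/G) and unmatched or
    allele-mismatched variants are dropped.  Returns the matched table plus a
    tally report.
    """
    pv = panel_variants.copy()
    dup = pv.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        raise ValueError("duplicate panel positions: "
                         + ", ".join(pv.loc[dup, "snp_id"].astype(str)))
    report = {"n_input": len(records), "n_matched": 0, "n_flipped": 0,
              "n_ambiguous": 0, "n_unmatched": 0, "n_mismatch": 0}

    pv_pos = pv.set_index(["chrom", "pos"])
    pv_id = pv.set_index("snp_id")
    rows = []
    for rec in records.itertuples(index=False):
        key = (str(rec.CHR), int(rec.BP))
        if key in pv_pos.index:
            pan = pv_pos.loc[key]
        elif rec.SNP in pv_id.index:
            pan = pv_id.loc[rec.SNP]
        else:
            report["n_unmatched"] += 1
            continue
        if frozenset((rec.A1, rec.A2)) in _AMBIGUOUS:
            report["n_ambiguous"] += 1
            continue
        if (rec.A1, rec.A2) == (pan["a1"], pan["a2"]):
            beta, eaf = rec.BETA, rec.EAF
        elif (rec.A1, rec.A2) == (pan["a2"], pan["a1"]):
            beta, eaf = -rec.BETA, 1.0 - rec.EAF
            report["n_flipped"] += 1
        else:
            report["n_mismatch"] += 1
            continue
        rows.append({"SNP": pan["snp_id"] if "snp_id" in pan else rec.SNP,
                     "CHR": str(rec.CHR), "BP": int(rec.BP),
                     "BETA": beta, "P": rec.P, "EAF": eaf})
    out = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "BETA", "P", "EAF"])
    report["n_matched"] = len(out)
    logger.info("harmonize: %s", report)
    return out, report


def _fast_harmonize(records: pd.DataFrame,
                    panel_variants: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Vectorized harmonization for large tables (same contract as
    :func:`harmonize_alleles`; used internally by :func:`compute_prs`)."""
    pv = panel_variants
    dup = pv.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        raise ValueError("duplicate panel positions: "
                         + ", ".join(pv.loc[dup, "snp_id"].astype(str)))
    merged = records.merge(
        pv[["snp_id", "chrom", "pos", "a1", "a2"]],
        left_on=["CHR", "BP"], right_on=["chrom", "pos"], how="inner")
    amb = merged.apply(lambda r: frozenset((r.A1, r.A2)) in _AMBIGUOUS, axis=1) \
        if len(merged) else pd.Series(dtype=bool)
    same = (merged["A1"] == merged["a1"]) & (merged["A2"] == merged["a2"])
    swap = (merged["A1"] == merged["a2"]) & (merged["A2"] == merged["a1"])
    keep = (~amb) & (same | swap)
    out = merged[keep].copy()
    flip = swap[keep]
    out["BETA"] = np.where(flip, -out["BETA"], out["BETA"])
    out["EAF"] = np.where(flip, 1.0 - out["EAF"], out["EAF"])
    out["SNP"] = out["snp_id"]
    report = {"n_input": len(records), "n_matched": int(keep.sum()),
              "n_flipped": int(flip.sum()),
              "n_ambiguous": int(amb.sum()),
              "n_unmatched": len(records) - len(merged),
              "n_mismatch": int(((~amb) & ~(same | swap)).sum())}
    return out[["SNP", "CHR", "BP", "BETA", "P", "EAF"]], report


def clump(records: pd.DataFrame, panel: GenotypePanel,
          params: ClumpParams = ClumpParams()) -> pd.DataFrame:
    """Greedy LD clumping: smallest-p SNP claims its neighbourhood.

    Repeatedly takes the unclaimed SNP with the smallest p (ties broken by
    chrom, then position) as an index SNP and removes all unclaimed SNPs
    within +/- window_kb whose dosage r^2 with it exceeds ``r2_max``.  Returns
    the index-SNP subset of ``records`` in input order.  Monomorphic SNPs have
    undefined r^2, treated as 0 with a warning.
    """
    if len(records) == 0:
        return records
    snp_col = {s: i for i, s in enumerate(panel.variants["snp_id"])}
    recs = (records[records["SNP"].isin(snp_col)]
            .sort_values(["CHR", "BP"], kind="mergesort")
            .reset_index(drop=True))
    if len(recs) == 0:
        return recs
    pos = recs["BP"].to_numpy(dtype=np.int64)
    chrom = recs["CHR"].astype(str).to_numpy()
    pvals = recs["P"].to_numpy()

    # standardized dosages, restricted to the record SNPs in position order
    cols = np.array([snp_col[s] for s in recs["SNP"]], dtype=int)
    z = panel.dosages[:, cols]
    z = z - z.mean(axis=0)
    sd = z.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs: r^2 treated as 0")
    z /= np.where(mono, 1.0, sd)
    n = panel.n

    # per-chromosome contiguous segments (records are position-sorted)
    seg: dict[str, tuple[int, int]] = {}
    for c in np.unique(chrom):
        w = np.flatnonzero(chrom == c)
        seg[c] = (int(w[0]), int(w[-1]) + 1)

    window_bp = int(params.window_kb * 1000)
    # claim order: smallest p first, ties by (chrom, pos) ascending
    order = np.lexsort((pos, chrom, pvals))
    claimed = np.zeros(len(recs), dtype=bool)
    keep = np.zeros(len(recs), dtype=bool)
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        keep[i] = True
        s0, s1 = seg[chrom[i]]
        lo = s0 + int(np.searchsorted(pos[s0:s1], pos[i] - window_bp, "left"))
        hi = s0 + int(np.searchsorted(pos[s0:s1], pos[i] + window_bp, "right"))
        r = (z[:, lo:hi].T @ z[:, i]) / n
        remove = (r * r > params.r2_max) & ~claimed[lo:hi]
        claimed[lo:hi] |= remove
    return recs[keep]


def score(panel: GenotypePanel, effects: pd.DataFrame,
          thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
          standardize: bool = True) -> PrsProfile:
    """Sum dosage * beta over SNPs with p <= T, for each threshold T.

    Missing dosages are mean-imputed per SNP.  With ``standardize`` each
    threshold column is z-scored (columns with zero variance stay zero).
    """
    if len(thresholds) == 0:
        raise ValueError("threshold grid must not be empty")
    thresholds = tuple(sorted(set(float(t) for t in thresholds), reverse=True))
    snp_col = {s: i for i, s in enumerate(panel.variants["snp_id"])}
    eff = effects[effects["SNP"].isin(snp_col)]
    cols = np.array([snp_col[s] for s in eff["SNP"]], dtype=int)
    betas = eff["BETA"].to_numpy()
    pvals = eff["P"].to_numpy()

    d = panel.dosages[:, cols] if len(cols) else np.zeros((panel.n, 0))
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d = d.copy()
        d[nan_r, nan_c] = col_mean[nan_c]

    mat = np.zeros((panel.n, len(thresholds)))
    counts = []
    for k, t in enumerate(thresholds):
        mask = pvals <= t
        counts.append(int(mask.sum()))
        if mask.any():
            mat[:, k] = d[:, mask] @ betas[mask]
    if standardize:
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        nz = sd > 0
        mat[:, nz] = (mat[:, nz] - mu[nz]) / sd[nz]
    return PrsProfile(individual_ids=list(panel.individual_ids),
                      thresholds=thresholds, scores=mat,
                      n_snps=tuple(counts), standardized=standardize)


def compute_prs(sumstats: pd.DataFrame, panel: GenotypePanel,
                params: ClumpParams = ClumpParams(),
                thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                maf_min: float = 0.01, info_min: float = 0.80,
                standardize: bool = True) -> tuple[PrsProfile, dict]:
    """Full C+T pipeline: QC -> harmonize -> clump -> score."""
    filtered = qc_filter(sumstats, panel.variants, maf_min, info_min)
    matched, report = _fast_harmonize(filtered, panel.variants)
    index_snps = clump(matched, panel, params)
    profile = score(panel, index_snps, thresholds, standardize)
    report["n_clumped"] = len(index_snps)
    return profile, report


def read_vcf_panel(path: str | Path) -> GenotypePanel:
    """Read a dosage panel from a VCF with a DS FORMAT field (ALT counted)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    rows, meta = [], []
    for rec in vf.fetch():
        ds = [rec.samples[s]["DS"] for s in ids]
        rows.append(ds)
        alt = rec.alts[0] if rec.alts else "N"
        rows_arr = np.asarray(ds, float)
        af = float(rows_arr.mean() / 2.0)
        meta.append({"snp_id": rec.id or f"{rec.chrom}:{rec.pos}",
                     "chrom": str(rec.chrom), "pos": int(rec.pos),
                     "a1": alt, "a2": rec.ref,
                     "maf": min(af, 1 - af), "eaf_sample": af, "info": 1.0})
    dos = np.asarray(rows, float).T
    return GenotypePanel(dosages=dos, individual_ids=ids,
                         variants=pd.DataFrame(meta))
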