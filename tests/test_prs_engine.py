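"""QC, allele harmonization, LD clumping and threshold scoring."""

import numpy as np
import pandas as pd
import pytest

from multiprs import prs_engine as pe
from multiprs import synthetic_data as sd
from multiprs.synthetic_data import GenotypePanel


def _records(**cols):
    base = {"SNP": ["rs1"], "CHR": ["1"], "BP": [100], "A1": ["A"],
            "A2": ["G"], "BETA": [0.2], "SE": [0.02], "P": [0.01],
            "EAF": [0.3], "INFO": [0.95]}
    base.update(cols)
    n = max(len(v) for v in base.values())
    return pd.DataFrame({k: (v * n if len(v) == 1 else v)
                         for k, v in base.items()})


def _panel(dosages, snp_ids=None, pos=None, a1=None, a2=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "snp_id": snp_ids or [f"rs{i+1}" for i in range(m)],
        "chrom": "1",
        "pos": pos if pos is not None else (np.arange(m) + 1) * 100,
        "a1": a1 or ["A"] * m,
        "a2": a2 or ["G"] * m,
        "maf": dosages.mean(axis=0) / 2,
        "eaf_sample": dosages.mean(axis=0) / 2,
        "info": 1.0,
        "block": 0,
    })
    ids = [f"I{i+1}" for i in range(dosages.shape[0])]
    return GenotypePanel(dosages=dosages, individual_ids=ids, variants=variants)


class TestQcFilter:
    def test_stated_cutoffs_on_toy_records(self, toy_sumstats):
        # MAFs (.005,.02,.30,.15,.40) x INFO (.90,.70,.95,.85,.81) -> 3 pass
        out = pe.qc_filter(toy_sumstats)
        assert len(out) == 3
        assert list(out["SNP"]) == ["rs3", "rs4", "rs5"]

    def test_maf_just_below_one_percent_is_excluded(self):
        recs = _records(EAF=[0.009])
        assert len(pe.qc_filter(recs)) == 0

    def test_all_passing_is_identity(self):
        recs = _records(EAF=[0.3, 0.4], INFO=[0.9, 0.95],
                        SNP=["rs1", "rs2"], BP=[100, 200])
        out = pe.qc_filter(recs)
        pd.testing.assert_frame_equal(out, recs)

    def test_empty_panel_overlap_warns(self):
        recs = _records()
        panel = _panel(np.ones((4, 1)), snp_ids=["rsX"])
        with pytest.warns(UserWarning, match="overlap"):
            out = pe.qc_filter(recs, panel.variants)
        assert len(out) == 0


class TestHarmonize:
    def test_matching_orientation_keeps_beta(self):
        panel = _panel(np.ones((4, 1)), a1=["A"], a2=["G"])
        out, rep = pe.harmonize_alleles(_records(), panel.variants)
        assert out["BETA"].iloc[0] == 0.2
        assert rep["n_flipped"] == 0

    def test_swapped_alleles_flip_sign_and_eaf(self):
        panel = _panel(np.ones((4, 1)), a1=["G"], a2=["A"])
        out, rep = pe.harmonize_alleles(_records(), panel.variants)
        assert out["BETA"].iloc[0] == pytest.approx(-0.2)
        assert out["EAF"].iloc[0] == pytest.approx(0.7)
        assert rep["n_flipped"] == 1

    def test_strand_ambiguous_dropped_and_tallied(self):
        panel = _panel(np.ones((4, 1)), a1=["A"], a2=["T"])
        out, rep = pe.harmonize_alleles(_records(A1=["A"], A2=["T"]),
                                        panel.variants)
        assert len(out) == 0
        assert rep["n_ambiguous"] == 1

    def test_duplicate_positions_raise(self):
        variants = _panel(np.ones((4, 2)), pos=[100, 100]).variants
        with pytest.raises(ValueError, match="rs1"):
            pe.harmonize_alleles(_records(), variants)

    def test_fast_path_agrees_with_reference(self, small_panel):
        cfg, panel = small_panel
        eff = sd.draw_true_effects(cfg, np.random.default_rng(1),
                                   maf=panel.variants["maf"].to_numpy())
        ss = sd.simulate_discovery_gwas(cfg, eff, panel.variants,
                                        np.random.default_rng(2))
        table = ss["trait01"]
        slow, rep_slow = pe.harmonize_alleles(table, panel.variants)
        fast, rep_fast = pe._fast_harmonize(table, panel.variants)
        assert rep_slow == rep_fast
        pd.testing.assert_frame_equal(slow.reset_index(drop=True),
                                      fast.reset_index(drop=True))


def _brute_force_clump(records, panel, params):
    """Literal step-by-step greedy trace, kept deliberately naive."""
    recs = records.copy()
    d = pd.DataFrame(panel.dosages, columns=panel.variants["snp_id"])
    alive = {r.SNP for r in recs.itertuples()}
    kept = []
    pool = sorted(recs.itertuples(),
                  key=lambda r: (r.P, str(r.CHR), r.BP))
    for rec in pool:
        if rec.SNP not in alive:
            continue
        kept.append(rec.SNP)
        alive.discard(rec.SNP)
        for other in list(alive):
            o = recs[recs["SNP"] == other].iloc[0]
            if str(o["CHR"]) != str(rec.CHR):
                continue
            if abs(o["BP"] - rec.BP) > params.window_kb * 1000:
                continue
            x, y = d[rec.SNP], d[other]
            r = 0.0 if x.std() == 0 or y.std() == 0 else np.corrcoef(x, y)[0, 1]
            if r * r > params.r2_max:
                alive.discard(other)
    return sorted(kept)


class TestClump:
    def test_smallest_p_snp_claims_correlated_neighbours(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(2000)
        # three SNPs with pairwise dosage r^2 ~ 0.5, within 250 kb
        d = np.column_stack([base + 1.0 * rng.standard_normal(2000)
                             for _ in range(3)])
        panel = _panel(d - d.min(), pos=[1000, 2000, 3000])
        recs = _records(SNP=["rs1", "rs2", "rs3"], BP=[1000, 2000, 3000],
                        P=[1e-8, 1e-5, 1e-3])
        out = pe.clump(recs, panel, pe.ClumpParams(250, 0.1))
        assert list(out["SNP"]) == ["rs1"]

    def test_snps_outside_window_both_retained(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(500)
        d = np.column_stack([base, base])  # perfectly correlated but far apart
        panel = _panel(d - d.min(), pos=[1000, 301_000])
        recs = _records(SNP=["rs1", "rs2"], BP=[1000, 301_000], P=[1e-8, 1e-5])
        out = pe.clump(recs, panel, pe.ClumpParams(250, 0.1))
        assert sorted(out["SNP"]) == ["rs1", "rs2"]

    def test_matches_brute_force_oracle_on_random_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, m = 400, 20
            # random LD: mixture of shared and independent signal
            shared = rng.standard_normal((n, 4))
            load = rng.uniform(-1, 1, size=(4, m))
            d = shared @ load + rng.standard_normal((n, m))
            d = d - d.min(axis=0)
            pos = np.sort(rng.choice(np.arange(1, 500) * 1000, m, replace=False))
            panel = _panel(d, pos=pos)
            recs = _records(SNP=[f"rs{i+1}" for i in range(m)], BP=list(pos),
                            P=list(rng.uniform(1e-8, 1, m)))
            params = pe.ClumpParams(window_kb=rng.choice([50, 250]),
                                    r2_max=rng.choice([0.1, 0.25, 0.5]))
            got = sorted(pe.clump(recs, panel, params)["SNP"])
            assert got == _brute_force_clump(recs, panel, params), seed

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0, 2, size=(300, 10))
        pos = (np.arange(10) + 1) * 1000
        panel = _panel(d, pos=pos)
        recs = _records(SNP=[f"rs{i+1}" for i in range(10)], BP=list(pos),
                        P=list(rng.uniform(0, 1, 10)))
        out1 = pe.clump(recs, panel, pe.ClumpParams(250, 0.1))
        shuffled = recs.sample(frac=1, random_state=3).reset_index(drop=True)
        out2 = pe.clump(shuffled, panel, pe.ClumpParams(250, 0.1))
        assert list(out1["SNP"]) == list(out2["SNP"])

    def test_monomorphic_snp_warns_and_survives(self):
        d = np.column_stack([np.full(100, 1.0),
                             np.random.default_rng(0).uniform(0, 2, 100)])
        panel = _panel(d, pos=[1000, 2000])
        recs = _records(SNP=["rs1", "rs2"], BP=[1000, 2000], P=[1e-4, 1e-3])
        with pytest.warns(UserWarning, match="monomorphic"):
            out = pe.clump(recs, panel, pe.ClumpParams(250, 0.1))
        assert sorted(out["SNP"]) == ["rs1", "rs2"]


class TestScore:
    def test_direct_arithmetic(self):
        panel = _panel(np.array([[0.0, 1.0, 2.0]]).T.reshape(1, 3))
        eff = _records(SNP=["rs1", "rs2", "rs3"], BP=[100, 200, 300],
                       BETA=[0.2, -0.1, 0.4], P=[0.01, 0.02, 0.03])
        prof = pe.score(panel, eff, thresholds=(1.0,), standardize=False)
        assert prof.scores[0, 0] == pytest.approx(0.0 * 0.2 + 1 * -0.1 + 2 * 0.4)

    def test_threshold_excludes_large_p(self):
        panel = _panel(np.array([[0.0, 1.0, 2.0]]).reshape(1, 3))
        eff = _records(SNP=["rs1", "rs2", "rs3"], BP=[100, 200, 300],
                       BETA=[0.2, -0.1, 0.4], P=[0.01, 0.02, 0.2])
        prof = pe.score(panel, eff, thresholds=(0.05,), standardize=False)
        assert prof.scores[0, 0] == pytest.approx(-0.1)
        assert prof.n_snps == (2,)

    def test_standardized_columns(self, small_panel):
        cfg, panel = small_panel
        eff = _records(SNP=list(panel.variants["snp_id"][:10]),
                       BP=list(panel.variants["pos"][:10]),
                       BETA=list(np.linspace(-0.2, 0.2, 10)),
                       P=list(np.linspace(0.001, 0.5, 10)))
        prof = pe.score(panel, eff, thresholds=(1.0, 0.05), standardize=True)
        assert np.allclose(prof.scores.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(prof.scores.std(axis=0), 1, atol=1e-12)

    def test_nesting_in_threshold(self, small_panel):
        cfg, panel = small_panel
        rng = np.random.default_rng(3)
        m = panel.m
        eff = _records(SNP=list(panel.variants["snp_id"]),
                       BP=list(panel.variants["pos"]),
                       BETA=list(rng.standard_normal(m) * 0.05),
                       P=list(rng.uniform(0, 1, m)))
        prof = pe.score(panel, eff, standardize=False)
        # thresholds descend, so SNP counts must not increase
        assert all(a >= b for a, b in zip(prof.n_snps, prof.n_snps[1:]))

    def test_missing_dosages_mean_imputed(self):
        d = np.array([[0.0], [2.0], [np.nan], [2.0]])
        panel = _panel(np.nan_to_num(d))
        panel.dosages = d
        eff = _records(BETA=[1.0])
        prof = pe.score(panel, eff, thresholds=(1.0,), standardize=False)
        assert prof.scores[2, 0] == pytest.approx(4.0 / 3.0)

    def test_empty_threshold_grid_rejected(self):
        panel = _panel(np.ones((2, 1)))
        with pytest.raises(ValueError):
            pe.score(panel, _records(), thresholds=())


def test_prs_validity_grows_with_discovery_n(small_panel):
    """A larger discovery GWAS gives a PRS closer to the true polygenic value."""
    corrs = {}
    for dn in (2_000, 200_000):
        cfg = sd.SimConfig(n_individuals=2000, n_snps=50, block_size=5,
                           within_block_rho=0.25, n_traits=2,
                           genetic_corr=np.eye(2), discovery_n=dn,
                           causal_fraction=0.5, seed=99)
        variants = sd.draw_variants(cfg, np.random.default_rng(90))
        panel = sd.simulate_genotypes(cfg, rng=np.random.default_rng(91),
                                      variants=variants)
        eff = sd.draw_true_effects(cfg, np.random.default_rng(92),
                                   maf=variants["maf"].to_numpy())
        ss = sd.simulate_discovery_gwas(cfg, eff, variants,
                                        np.random.default_rng(93))
        prof, _ = pe.compute_prs(ss["trait01"], panel)
        u = (panel.dosages - panel.dosages.mean(0)) @ eff[:, 0]
        corrs[dn] = np.corrcoef(prof.column(1.0), u)[0, 1]
    assert corrs[200_000] > corrs[2_000]


def test_vcf_round_trip(tmp_path, small_panel):
    _, panel = small_panel
    sub = GenotypePanel(dosages=panel.dosages[:20, :10],
                        individual_ids=panel.individual_ids[:20],
                        variants=panel.variants.iloc[:10].reset_index(drop=True))
    path = tmp_path / "panel.vcf"
    sd.write_vcf(sub, path)
    back = pe.read_vcf_panel(path)
    assert back.individual_ids == sub.individual_ids
    np.testing.assert_allclose(back.dosages, sub.dosages, atol=1e-6)
    assert list(back.variants["pos"]) == list(sub.variants["pos"])
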