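import numpy as np
import pandas as pd
import pytest

from multiprs import synthetic_data as sd


@pytest.fixture(scope="session")
def small_panel():
    """10k-individual panel with strong-LD blocks, for LD/clumping checks."""
    cfg = sd.SimConfig(n_individuals=10_000, n_snps=50, block_size=5,
                       within_block_rho=0.9, seed=42)
    return cfg, sd.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def toy_sumstats():
    """Five hand-written summary-stat records spanning the QC cutoffs."""
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(1, 6)],
        "CHR": ["1"] * 5,
        "BP": [100, 200, 300, 400, 500],
        "A1": ["A", "C", "G", "T", "A"],
        "A2": ["G", "T", "A", "C", "C"],
        "BETA": [0.2, -0.1, 0.4, 0.05, -0.3],
        "SE": [0.02] * 5,
        "P": [1e-8, 1e-5, 1e-3, 0.2, 0.6],
        "EAF": [0.005, 0.02, 0.30, 0.15, 0.40],
        "INFO": [0.90, 0.70, 0.95, 0.85, 0.81],
    })


@pytest.fixture(scope="session")
def cohort_with_truth():
    """One simulated cohort (n=10k) with known factor structure."""
    cfg = sd.SimConfig(n_individuals=10_000, n_snps=400, seed=7)
    variants = sd.draw_variants(cfg, np.random.default_rng(70))
    panel = sd.simulate_genotypes(cfg, rng=np.random.default_rng(71),
                                  variants=variants)
    effects = sd.draw_true_effects(cfg, np.random.default_rng(72),
                                   maf=variants["maf"].to_numpy())
    phen = sd.simulate_cohort_phenotypes(cfg, panel, effects,
                                         np.random.default_rng(73))
    return cfg, panel, effects, phen
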