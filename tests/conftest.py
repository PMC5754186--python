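import numpy as np
import pytest

import qrgwas as q


@pytest.fixture(scope="session")
def small_trial():
    """A small balanced trial: 20 genotypes x 30 SNPs, 2 envs x 2 blocks."""
    cfg = q.SimConfig(
        n_geno=20, n_snp=30, n_env=2, n_rep=2,
        sigma_g_poly=2.0, sigma_ga=0.7, sigma_b=0.5, sigma_e=1.0, seed=42,
    )
    g, gt = q.simulate_genotypes(cfg)
    ph, pt = q.simulate_phenotypes(g, cfg)
    return cfg, g, ph


@pytest.fixture(scope="session")
def study_panel():
    """Study-dimension panel (80 x 384) with mild structure, no causal SNPs."""
    cfg = q.SimConfig(seed=7)
    g, _ = q.simulate_genotypes(cfg)
    ph, _ = q.simulate_phenotypes(g, cfg)
    g2, _ = q.drop_unusable_snps(q.impute_missing(g))
    return cfg, g2, ph


@pytest.fixture(scope="session")
def study_ystar(study_panel):
    cfg, g2, ph = study_panel
    fit = q.fit_lmm(ph, q.MixedModelSpec("trait"))
    ys = q.adjusted_phenotypes(fit)
    pc = q.genotype_pca(g2)
    return g2, ys, pc
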