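"""Synthetic genotype/phenotype generator mirroring a multi-environment bean trial.

Genotypes are independent biallelic SNPs drawn under the Balding–Nichols
model: an ancestral allele frequency per SNP, Beta-perturbed per
subpopulation at a chosen F_ST, then binomial dosages 0/1/2. Phenotypes
follow the plot-level model of a randomized complete block trial repeated
over environments,

    y_ijk = mu + g_i + a_j + ga_ij + b_k(j) + e_ijk,

with genotype effects g_i = sum_c x_ic * beta_c + u_i (causal mean effects
plus a polygenic normal deviate), fixed equally spaced environment effects
a_j, and normal ga, block and residual terms. Causal SNPs may also act on
the *scale* of the residual: e_ijk ~ N(0, [sigma_e * (1 + sum_c x_ic *
gamma_c)]^2), the canonical architecture producing quantile-specific
(tail) effects with a closed-form population quantile-regression slope
beta + gamma * sigma_e * z_tau.

Defaults reproduce the study dimensions this package is aimed at: 80
genotypes x 384 SNPs, 4 environments x 3 blocks, a days-to-flowering-like
trait mean of 42, and mild two-subpopulation structure.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np

from .data_model import PV_CHROMOSOMES, GenotypeMatrix, PhenotypeRecords, SnpMap

import pandas as pd

__all__ = ["CausalEffect", "SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes"]

#: residual-scale multiplier is floored here to keep standard deviations positive
SCALE_FLOOR = 0.1


@dataclasses.dataclass(frozen=True)
class CausalEffect:
    """A causal SNP acting on the trait mean (beta) and/or scale (gamma).

    beta is in trait units per alternate allele; gamma is the fractional
    change of the residual standard deviation per alternate allele.
    """

    snp_index: int
    beta: float = 0.0
    gamma: float = 0.0


@dataclasses.dataclass(frozen=True)
class SimConfig:
    n_geno: int = 80
    n_snp: int = 384
    maf_range: tuple = (0.05, 0.5)
    n_subpop: int = 2
    fst: float = 0.05
    causal: tuple = ()
    mu: float = 42.0
    sigma_g_poly: float = 2.0   # SD of the polygenic genotype effect u_i
    sigma_ga: float = 1.0       # SD of genotype-by-environment deviations
    sigma_b: float = math.sqrt(0.5)  # SD of block-within-environment effects
    sigma_e: float = 1.0        # baseline residual (plot error) SD
    n_env: int = 4
    n_rep: int = 3
    env_effect_step: float = 2.0  # spacing of the fixed environment effects
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if self.n_subpop < 1:
            raise ValueError("n_subpop must be >= 1")
        causal = tuple(
            c if isinstance(c, CausalEffect) else CausalEffect(*c) for c in self.causal
        )
        for c in causal:
            if not (0 <= c.snp_index < self.n_snp):
                raise ValueError(f"causal snp_index {c.snp_index} out of range")
        for name in ("sigma_g_poly", "sigma_ga", "sigma_b", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        object.__setattr__(self, "causal", causal)


@dataclasses.dataclass
class SimTruth:
    """Ground truth stored alongside every simulated dataset."""

    subpop: Optional[np.ndarray] = None
    ancestral_freq: Optional[np.ndarray] = None
    genetic_values: Optional[np.ndarray] = None
    scale_factors: Optional[np.ndarray] = None
    causal: tuple = ()
    env_effects: Optional[np.ndarray] = None
    variance_components: Optional[dict] = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, tuple):
                return [dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c for c in v]
            return v
        return {k: conv(v) for k, v in dataclasses.asdict(self).items()}


def _default_map(n_snp: int) -> SnpMap:
    """Spread SNPs over the 11 bean chromosomes in contiguous 1-Mb-spaced blocks."""
    chrom = np.empty(n_snp, dtype=object)
    pos = np.zeros(n_snp, dtype=np.int64)
    blocks = np.array_split(np.arange(n_snp), len(PV_CHROMOSOMES))
    for label, idx in zip(PV_CHROMOSOMES, blocks):
        chrom[idx] = label
        pos[idx] = (np.arange(len(idx)) + 1) * 1_000_000
    ids = np.array([f"snp{i:04d}" for i in range(n_snp)], dtype=object)
    return SnpMap(ids, chrom, pos)


def simulate_genotypes(cfg: SimConfig):
    """Draw a Balding–Nichols dosage matrix.

    Returns ``(GenotypeMatrix, SimTruth)``; the truth carries subpopulation
    labels and ancestral allele frequencies.
    """
    rng = np.random.default_rng([int(cfg.seed), 101])
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snp) if hi > lo else np.full(cfg.n_snp, lo)

    subpop = np.arange(cfg.n_geno) * cfg.n_subpop // cfg.n_geno  # equal blocks
    if cfg.fst > 0 and cfg.n_subpop > 1:
        f = cfg.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a[None, :], b[None, :], size=(cfg.n_subpop, cfg.n_snp))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpop, 1))
    dosages = rng.binomial(2, p_sub[subpop, :]).astype(float)

    g = GenotypeMatrix(
        tuple(f"G{i:03d}" for i in range(cfg.n_geno)), dosages, _default_map(cfg.n_snp)
    )
    truth = SimTruth(subpop=subpop, ancestral_freq=p_anc, causal=cfg.causal)
    return g, truth


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig):
    """Draw plot-level phenotypes for an existing genotype matrix.

    Returns ``(PhenotypeRecords, SimTruth)``. The truth records realized
    genetic values, per-genotype residual scale factors, the fixed
    environment effects, and the variance components used.
    """
    rng = np.random.default_rng([int(cfg.seed), 202])
    n, J, K = g.n_genotypes, cfg.n_env, cfg.n_rep
    x = g.dosages

    beta = np.zeros(g.n_snps)
    gamma = np.zeros(g.n_snps)
    for c in cfg.causal:
        beta[c.snp_index] += c.beta
        gamma[c.snp_index] += c.gamma

    u = rng.normal(0.0, cfg.sigma_g_poly, size=n) if cfg.sigma_g_poly > 0 else np.zeros(n)
    g_i = x @ beta + u
    a_j = cfg.env_effect_step * (np.arange(J) - (J - 1) / 2.0)
    ga = rng.normal(0.0, cfg.sigma_ga, size=(n, J)) if cfg.sigma_ga > 0 else np.zeros((n, J))
    b = rng.normal(0.0, cfg.sigma_b, size=(J, K)) if cfg.sigma_b > 0 else np.zeros((J, K))

    scale = 1.0 + x @ gamma
    n_floored = int((scale <= 0).sum())
    if n_floored > 0.01 * n:
        snp = [c.snp_index for c in cfg.causal if c.gamma != 0]
        warnings.warn(
            f"residual scale factor non-positive for {n_floored}/{n} genotypes "
            f"(scale-effect SNP index {snp}); flooring at {SCALE_FLOOR}"
        )
    scale = np.maximum(scale, SCALE_FLOOR)

    e = rng.normal(size=(n, J, K)) * (cfg.sigma_e * scale)[:, None, None]
    y = (
        cfg.mu
        + g_i[:, None, None]
        + a_j[None, :, None]
        + ga[:, :, None]
        + b[None, :, :]
        + e
    )

    gi_idx, jj, kk = np.meshgrid(np.arange(n), np.arange(J), np.arange(K), indexing="ij")
    df = pd.DataFrame(
        {
            "genotype": np.asarray(g.genotype_ids, dtype=object)[gi_idx.ravel()],
            "environment": np.char.add("E", (jj.ravel() + 1).astype(str)),
            "block": np.char.add("B", (kk.ravel() + 1).astype(str)),
            "trait": cfg.trait_name,
            "value": y.ravel(),
        }
    )
    truth = SimTruth(
        genetic_values=g_i,
        scale_factors=scale,
        causal=cfg.causal,
        env_effects=a_j,
        variance_components={
            "sigma2_g_poly": cfg.sigma_g_poly ** 2,
            "sigma2_ga": cfg.sigma_ga ** 2,
            "sigma2_b": cfg.sigma_b ** 2,
            "sigma2_e": cfg.sigma_e ** 2,
        },
    )
    return PhenotypeRecords(df), truth
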