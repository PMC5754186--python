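"""REML mixed model for multi-environment trials and adjusted phenotypes.

The plot-level model is

    y_ijk = mu + a_j + g_i + ga_ij + b_k(j) + e_ijk

with fixed environment effects a_j and independent normal random effects:
genotype g_i ~ N(0, sigma2_g), genotype-by-environment ga_ij ~ N(0,
sigma2_ga) (optional), block-within-environment b_k(j) ~ N(0, sigma2_b),
and residual e_ijk ~ N(0, sigma2_e).

Variance components are estimated by restricted maximum likelihood.
Writing V = sigma2_e * H(gamma) with H = I + sum_r gamma_r Z_r Z_r' and
gamma_r = sigma2_r / sigma2_e, the residual variance profiles out in
closed form and the restricted log-likelihood reduces to

    -2 l_R(gamma) = (n - p) (log 2*pi + 1 + log s2hat)
                    + sum_r m_r log gamma_r + log|C(gamma)|,

where C is Henderson's mixed-model coefficient matrix
[[X'X, X'Z], [Z'X, Z'Z + diag(1/gamma_r)]] and s2hat = y'P y / (n - p) is
the profiled residual variance. Each evaluation is one Cholesky of the
(p+q)x(p+q) C matrix, so fits at trial scale (960 plots, ~400 random
levels) take fractions of a second. The maximizer runs over log(gamma)
(Nelder–Mead), which handles the zero boundary by letting log(gamma)
drift to its lower clamp.

BLUPs and fixed-effect estimates come from the mixed-model equations at
the optimum; the per-genotype BLUP g_hat_i is the default adjusted
phenotype Y* handed to the association scan.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import PhenotypeRecords

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "MixedModelFit",
    "ModelComparison",
    "GeneticParameters",
    "AdjustedPhenotypes",
    "fit_lmm",
    "information_criteria",
    "lr_test",
    "heritability",
    "adjusted_phenotypes",
    "genetic_parameters",
]

_LOG_GAMMA_MIN = -16.0
_LOG_GAMMA_MAX = 16.0


@dataclasses.dataclass(frozen=True)
class MixedModelSpec:
    """Which trait to fit and whether the G-by-E term is included."""

    trait: str
    include_gxe: bool = True


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_b: float
    sigma2_e: float
    sigma2_ga: Optional[float] = None  # None when the GxE term is excluded

    def as_dict(self) -> dict:
        d = {"sigma2_g": self.sigma2_g, "sigma2_b": self.sigma2_b, "sigma2_e": self.sigma2_e}
        if self.sigma2_ga is not None:
            d["sigma2_ga"] = self.sigma2_ga
        return d


@dataclasses.dataclass
class MixedModelFit:
    spec: MixedModelSpec
    vc: VarianceComponents
    fixed_estimates: pd.Series          # intercept + environment contrasts
    blups: Dict[str, pd.Series]         # per random term, indexed by level
    residuals: np.ndarray               # per plot, in data row order
    fitted: np.ndarray
    reml_loglik: float
    n_obs: int
    n_fixed: int
    converged: bool
    n_iter: int
    data_fingerprint: str
    levels: Dict[str, pd.Index]
    row_index: pd.DataFrame             # genotype/environment/block per row

    @property
    def n_vc(self) -> int:
        """Number of estimated variance parameters (residual included)."""
        return 3 + (1 if self.spec.include_gxe else 0)


@dataclasses.dataclass(frozen=True)
class ModelComparison:
    aic_full: float
    bic_full: float
    aic_reduced: float
    bic_reduced: float
    lrt_stat: float
    lrt_pvalue: float


@dataclasses.dataclass(frozen=True)
class GeneticParameters:
    traits: tuple
    heritability: pd.Series
    genetic_correlations: pd.DataFrame
    phenotypic_correlations: pd.DataFrame


@dataclasses.dataclass(frozen=True)
class AdjustedPhenotypes:
    trait: str
    mode: str
    values: pd.Series  # indexed by genotype id

    def aligned(self, genotype_ids) -> np.ndarray:
        missing = [g for g in genotype_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genotypes without adjusted phenotype: {missing[:5]}")
        return self.values.loc[list(genotype_ids)].to_numpy()


# ---------------------------------------------------------------------------
# design construction


def _indicator(labels: pd.Series):
    levels = pd.Index(sorted(labels.unique()))
    codes = levels.get_indexer(labels)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z, levels


def _build_design(df: pd.DataFrame, include_gxe: bool):
    env_levels = pd.Index(sorted(df["environment"].unique()))
    # fixed effects: intercept + environment treatment contrasts
    X = np.ones((len(df), len(env_levels)))
    for j, lev in enumerate(env_levels[1:], start=1):
        X[:, j] = (df["environment"] == lev).to_numpy(float)

    terms, Zs, levels = [], [], {}
    Zg, lev_g = _indicator(df["genotype"])
    terms.append("genotype"); Zs.append(Zg); levels["genotype"] = lev_g
    if include_gxe:
        Zga, lev_ga = _indicator(df["genotype"] + ":" + df["environment"])
        terms.append("gxe"); Zs.append(Zga); levels["gxe"] = lev_ga
    Zb, lev_b = _indicator(df["environment"] + ":" + df["block"])
    terms.append("block"); Zs.append(Zb); levels["block"] = lev_b

    for t, Z in zip(terms, Zs):
        if Z.shape[1] < 2:
            raise ValueError(f"random term {t!r} has a single level")
    return X, terms, Zs, levels, env_levels


class _RemlWorkspace:
    """Precomputed cross-products; one Cholesky per likelihood evaluation."""

    def __init__(self, X, Zs, y):
        self.n, self.p = X.shape
        self.m = [Z.shape[1] for Z in Zs]
        Z = np.hstack(Zs)
        self.q = Z.shape[1]
        A = np.hstack([X, Z])
        self.AtA = A.T @ A
        self.Aty = A.T @ y
        self.yty = float(y @ y)
        self.slices = []
        off = self.p
        for m in self.m:
            self.slices.append(slice(off, off + m))
            off += m
        d = self.p + self.q
        # flat indices of each term's diagonal block, for the 1/gamma ridge
        self.diag_idx = [
            (np.arange(sl.start, sl.stop) * (d + 1)) for sl in self.slices
        ]

    def neg2_profiled_reml(self, log_gamma):
        from scipy import linalg as sla

        lg = np.clip(log_gamma, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
        gam = np.exp(lg)
        C = self.AtA.copy()
        flat = C.reshape(-1)
        logdet_G = 0.0
        for g, idx, m in zip(gam, self.diag_idx, self.m):
            flat[idx] += 1.0 / g
            logdet_G += m * np.log(g)
        try:
            L, low = sla.cho_factor(C, lower=True, overwrite_a=True, check_finite=False)
        except sla.LinAlgError:
            return np.inf, None, None
        logdet_C = 2.0 * np.sum(np.log(np.diag(L)))
        sol = sla.cho_solve((L, low), self.Aty, check_finite=False)
        ypy = max(self.yty - self.Aty @ sol, 1e-300)
        npf = self.n - self.p
        s2 = ypy / npf
        neg2 = npf * (np.log(2 * np.pi) + 1.0 + np.log(s2)) + logdet_G + logdet_C
        return neg2, sol, s2


def fit_lmm(records: PhenotypeRecords, spec: MixedModelSpec, max_iter: int = 2000) -> MixedModelFit:
    """REML fit of the trial model for one trait.

    Raises on non-convergence of the simplex search or on a random term
    with a single level.
    """
    df = records.for_trait(spec.trait)
    y = df["value"].to_numpy(float)
    fingerprint = hashlib.sha1(
        np.ascontiguousarray(np.round(y, 10)).tobytes()
        + "|".join(df["genotype"] + df["environment"] + df["block"]).encode()
    ).hexdigest()
    X, terms, Zs, levels, env_levels = _build_design(df, spec.include_gxe)
    n, p = X.shape
    row_index = df[["genotype", "environment", "block"]].copy()

    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        # constant response: all components zero, mean equals the constant
        fe = pd.Series(np.r_[y[0], np.zeros(p - 1)],
                       index=["intercept"] + [f"env[{e}]" for e in env_levels[1:]])
        blups = {t: pd.Series(np.zeros(len(levels[t])), index=levels[t]) for t in terms}
        vc = VarianceComponents(
            sigma2_g=0.0, sigma2_b=0.0, sigma2_e=0.0,
            sigma2_ga=0.0 if spec.include_gxe else None,
        )
        return MixedModelFit(spec, vc, fe, blups, np.zeros(n), y.copy(), np.nan, n, p,
                             True, 0, fingerprint, levels, row_index)

    ws = _RemlWorkspace(X, Zs, y)

    def objective(theta):
        return ws.neg2_profiled_reml(theta)[0]

    x0 = np.zeros(len(terms))
    # quasi-Newton pass (finite differences), then a simplex polish: the
    # profiled surface is smooth away from the gamma=0 clamp, where L-BFGS-B
    # stalls and Nelder-Mead finishes the job
    pre = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * len(terms),
        options={"maxiter": 200},
    )
    start = pre.x if np.isfinite(pre.fun) else x0
    res = optimize.minimize(
        objective, start, method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-5, "fatol": 1e-8, "adaptive": True},
    )
    if pre.fun < res.fun:
        res = pre
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML optimization failed; last iterate {res.x}")
    neg2, sol, s2 = ws.neg2_profiled_reml(res.x)
    gam = np.exp(np.clip(res.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
    # treat ratios at the clamp as exact zeros
    sigma2 = {t: (0.0 if lg <= _LOG_GAMMA_MIN + 1e-9 else g * s2)
              for t, g, lg in zip(terms, gam, np.clip(res.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))}

    beta = sol[: ws.p]
    fe = pd.Series(beta, index=["intercept"] + [f"env[{e}]" for e in env_levels[1:]])
    blups = {}
    for t, sl in zip(terms, ws.slices):
        blups[t] = pd.Series(sol[sl], index=levels[t])
    Z = np.hstack(Zs)
    fitted = X @ beta + Z @ sol[ws.p:]
    residuals = y - fitted

    vc = VarianceComponents(
        sigma2_g=sigma2["genotype"],
        sigma2_b=sigma2["block"],
        sigma2_e=s2,
        sigma2_ga=sigma2.get("gxe") if spec.include_gxe else None,
    )
    return MixedModelFit(
        spec=spec, vc=vc, fixed_estimates=fe, blups=blups, residuals=residuals,
        fitted=fitted, reml_loglik=-0.5 * neg2, n_obs=n, n_fixed=p,
        converged=bool(res.success), n_iter=int(res.nit),
        data_fingerprint=fingerprint, levels=levels, row_index=row_index,
    )


def information_criteria(fit: MixedModelFit):
    """REML AIC/BIC with q = number of variance parameters."""
    q = fit.n_vc
    aic = -2.0 * fit.reml_loglik + 2.0 * q
    bic = -2.0 * fit.reml_loglik + q * np.log(fit.n_obs)
    return float(aic), float(bic)


def lr_test(full: MixedModelFit, reduced: MixedModelFit, boundary_mixture: bool = False) -> ModelComparison:
    """Likelihood-ratio test of the G-by-E component (full vs reduced).

    Both fits must come from the same data; the statistic is clipped at
    zero. The default reference distribution is chi-square with 1 df; the
    0.5*chi2_0 + 0.5*chi2_1 boundary mixture halves the p-value when
    requested.
    """
    if full.data_fingerprint != reduced.data_fingerprint:
        raise ValueError("full and reduced fits were not computed on the same data")
    if not full.spec.include_gxe or reduced.spec.include_gxe:
        raise ValueError("expected full (with GxE) vs reduced (without GxE)")
    stat = max(0.0, 2.0 * (full.reml_loglik - reduced.reml_loglik))
    if boundary_mixture:
        p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    else:
        p = stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    aic_f, bic_f = information_criteria(full)
    aic_r, bic_r = information_criteria(reduced)
    return ModelComparison(aic_f, bic_f, aic_r, bic_r, float(stat), float(p))


def heritability(vc: VarianceComponents, n_env: int, n_rep: int) -> float:
    """Entry-mean heritability h2 = s2_g / (s2_g + s2_ga/J + s2_e/(J*K))."""
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    s2_ga = vc.sigma2_ga or 0.0
    denom = vc.sigma2_g + s2_ga / n_env + vc.sigma2_e / (n_env * n_rep)
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return float(vc.sigma2_g / denom)


def adjusted_phenotypes(fit: MixedModelFit, mode: str = "genotype_blup") -> AdjustedPhenotypes:
    """Adjusted phenotype Y* per genotype.

    ``genotype_blup`` (default) returns the genotype BLUP g_hat_i — one
    value per genotype, free of environment, block and residual noise.
    ``plot_sum`` sums all random-effect predictions plus the residual per
    plot and averages within genotype, i.e. the observation minus the
    fixed-effect fit.
    """
    g_blup = fit.blups["genotype"]
    if mode == "genotype_blup":
        vals = g_blup.copy()
    elif mode == "plot_sum":
        df = fit.row_index.copy()
        total = g_blup.loc[df["genotype"]].to_numpy()
        if "gxe" in fit.blups:
            total = total + fit.blups["gxe"].loc[
                (df["genotype"] + ":" + df["environment"])
            ].to_numpy()
        total = total + fit.blups["block"].loc[
            (df["environment"] + ":" + df["block"])
        ].to_numpy()
        total = total + fit.residuals
        vals = pd.Series(total).groupby(df["genotype"].to_numpy()).mean()
        vals = vals.reindex(g_blup.index)
    else:
        raise ValueError(f"unknown adjusted-phenotype mode {mode!r}")
    if not np.isfinite(vals.to_numpy()).all():
        raise RuntimeError("non-finite adjusted phenotype")
    return AdjustedPhenotypes(trait=fit.spec.trait, mode=mode, values=vals)


def genetic_parameters(
    fits: Dict[str, MixedModelFit],
    records: PhenotypeRecords,
    method: str = "blup_pearson",
    n_env: Optional[int] = None,
    n_rep: Optional[int] = None,
) -> GeneticParameters:
    """Heritabilities plus genetic and phenotypic correlation matrices.

    Genetic correlations are Pearson correlations of per-genotype BLUPs
    (an approximation to bivariate REML); phenotypic correlations are
    Pearson correlations of plot-level observations paired by plot.
    """
    if method != "blup_pearson":
        raise ValueError(f"unknown method {method!r}")
    traits = tuple(sorted(fits))
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    df = records.data
    if n_env is None:
        n_env = df["environment"].nunique()
    if n_rep is None:
        n_rep = df.groupby("environment")["block"].nunique().max()

    blup_mat = pd.DataFrame({t: fits[t].blups["genotype"] for t in traits})
    for t in traits:
        if float(blup_mat[t].std(ddof=0)) == 0.0:
            raise ValueError(f"zero-variance genotype BLUPs for trait {t!r}")
    gcor = blup_mat.corr()

    plots = df.pivot_table(index=["genotype", "environment", "block"],
                           columns="trait", values="value", aggfunc="first")[list(traits)]
    pcor = plots.corr()

    h2 = pd.Series({t: heritability(fits[t].vc, n_env, n_rep) for t in traits})
    return GeneticParameters(
        traits=traits,
        heritability=h2,
        genetic_correlations=gcor,
        phenotypic_correlations=pcor,
    )
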