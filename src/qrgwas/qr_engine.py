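"""Check-loss quantile regression: estimator, inference and goodness of fit.

The tau-th conditional quantile of a response y given a design X is
estimated by minimizing the asymmetric check loss

    rho_tau(e) = tau * e        if e >= 0
               = (tau - 1) * e  if e < 0

over coefficients beta. The minimization is the linear program

    min  tau * 1'u + (1 - tau) * 1'v
    s.t. X beta + u - v = y,  u >= 0,  v >= 0,

solved here through its bounded dual (max y'a s.t. X'a = (1-tau) X'1,
0 <= a <= 1), whose equality multipliers are the primal coefficients; the
dual has p constraints instead of n and is much faster at genome-scan
scale. HiGHS returns a vertex (basic) solution; when the minimizer is an
interval (even n, intercept-only), the returned vertex is reported as-is.

Inference on a coefficient uses either a Wald test with the
Koenker non-iid sandwich (local conditional density estimated by a
difference quotient of fitted quantiles at tau +/- the Hall–Sheather
bandwidth) or an (x, y)-pair bootstrap. Both are asymptotic; at extreme
quantiles in small panels their far-tail calibration degrades, so the
genome scan's significance calls instead use the exact conditional
tail-enrichment test (:func:`tail_enrichment_test`), which conditions on
the below-quantile set of the null-model fit and is family-wise valid at
any sample size.
"""

from __future__ import annotations

import dataclasses
import warnings
from functools import lru_cache
from math import comb
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "QRDesign",
    "QRFit",
    "QRInference",
    "check_loss",
    "fit_quantile",
    "qr_test",
    "pseudo_r1",
    "hall_sheather_bandwidth",
    "tail_membership",
    "tail_enrichment_test",
]


def check_loss(eps, tau: float):
    """Check function rho_tau applied elementwise.

    rho_tau(e) = tau*e for e >= 0 and (1-tau)*|e| for e < 0; continuous,
    zero only at zero.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    e = np.asarray(eps, dtype=float)
    out = np.where(e >= 0, tau * e, (tau - 1) * e)
    return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class QRDesign:
    """Design matrix, response and quantile for one QR fit.

    X must contain the intercept column explicitly; for a GWA fit the
    columns are [intercept, SNP dosage, PC covariates].
    """

    X: np.ndarray
    y: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible lengths")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need n > p")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)


@dataclasses.dataclass(frozen=True)
class QRFit:
    tau: float
    beta: np.ndarray
    objective: float     # sum of check losses at beta
    residuals: np.ndarray


@dataclasses.dataclass(frozen=True)
class QRInference:
    method: str
    se: np.ndarray
    p_value: np.ndarray
    zstat: np.ndarray


def _solve_lp_full(X: np.ndarray, y: np.ndarray, tau: float):
    """Coefficients and dual variables of the QR linear program.

    The dual solution ``a`` lies in [0, 1]^n with a_i = 1 above the fitted
    quantile plane, 0 below, fractional at basis (interpolated) points;
    ``1 - a`` is the (fractional) below-quantile membership and sums to
    tau * n exactly.
    """
    res = optimize.linprog(
        -y,
        A_eq=X.T,
        b_eq=(1.0 - tau) * X.sum(axis=0),
        bounds=(0.0, 1.0),
        method="highs",
    )
    if res.status != 0 or res.eqlin is None:
        return None
    return -np.asarray(res.eqlin.marginals, dtype=float), np.asarray(res.x, dtype=float)


def _solve_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Return the QR coefficient vector via the dual LP (primal fallback)."""
    n, p = X.shape
    full = _solve_lp_full(X, y, tau)
    if full is not None:
        return full[0]
    # fall back to the primal formulation
    from scipy import sparse

    c = np.concatenate([np.zeros(p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A = sparse.hstack(
        [sparse.csc_matrix(X), sparse.eye(n, format="csc"), -sparse.eye(n, format="csc")],
        format="csc",
    )
    res = optimize.linprog(
        c, A_eq=A, b_eq=y, bounds=[(None, None)] * p + [(0, None)] * (2 * n), method="highs"
    )
    if res.status != 0:
        raise RuntimeError(f"quantile-regression LP failed (status {res.status}): {res.message}")
    return np.asarray(res.x[:p], dtype=float)


def fit_quantile(d: QRDesign) -> QRFit:
    """Minimize the check loss; returns a vertex solution of the QR linear program."""
    X, y, tau = d.X, d.y, d.tau
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta = _solve_lp(X, y, tau)
    resid = y - X @ beta
    obj = float(np.sum(check_loss(resid, tau)))
    return QRFit(tau=tau, beta=beta, objective=obj, residuals=resid)


def hall_sheather_bandwidth(n: int, tau: float, alpha: float = 0.05) -> float:
    """Hall–Sheather bandwidth for sparsity estimation at quantile tau."""
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_t = stats.norm.ppf(tau)
    num = 1.5 * stats.norm.pdf(z_t) ** 2
    den = 2 * z_t ** 2 + 1
    return float(n ** (-1 / 3) * z_a ** (2 / 3) * (num / den) ** (1 / 3))


def _wald_nid(d: QRDesign, fit: QRFit) -> QRInference:
    X, y, tau = d.X, d.y, d.tau
    n, p = X.shape
    h = hall_sheather_bandwidth(n, tau)
    lo, hi = tau - h, tau + h
    eps_b = 1e-3
    if lo <= 0 or hi >= 1:
        warnings.warn(
            f"Hall–Sheather band tau +/- {h:.3f} leaves (0,1) at tau={tau}; clamping"
        )
        lo, hi = max(lo, eps_b), min(hi, 1 - eps_b)
    beta_hi = _solve_lp(X, y, hi)
    beta_lo = _solve_lp(X, y, lo)
    dyhat = X @ (beta_hi - beta_lo)
    eps = np.finfo(float).eps ** (2 / 3)
    # local density (inverse sparsity) per observation; negative quotients -> 0
    f = np.maximum(0.0, (hi - lo) / (dyhat - eps))
    XFX = (X * f[:, None]).T @ X
    XtX = X.T @ X
    w, V = np.linalg.eigh(XFX)
    tol = max(np.max(w), 1.0) * n * np.finfo(float).eps
    null_dirs = w < tol
    if null_dirs.any():
        # a coefficient direction with zero density weight carries no
        # information at this quantile: se = inf, p = 1 (never p = 0)
        XFX_inv = (V[:, ~null_dirs] / w[~null_dirs]) @ V[:, ~null_dirs].T
        uninformative = np.abs(V[:, null_dirs]).max(axis=1) > 1e-8
    else:
        XFX_inv = (V / w) @ V.T
        uninformative = np.zeros(p, dtype=bool)
    cov = tau * (1 - tau) * XFX_inv @ XtX @ XFX_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se[uninformative] = np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.beta / se, np.inf * np.sign(fit.beta))
    z[uninformative] = 0.0
    pval = 2 * stats.norm.sf(np.abs(z))
    return QRInference(method="wald_nid", se=se, p_value=pval, zstat=z)


def _bootstrap_xy(d: QRDesign, fit: QRFit, B: int, seed: Optional[int]) -> QRInference:
    if B < 200:
        raise ValueError("bootstrap needs B >= 200")
    rng = np.random.default_rng(seed)
    n, p = d.X.shape
    betas = np.empty((B, p))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb, yb = d.X[idx], d.y[idx]
        if np.linalg.matrix_rank(Xb) < p:
            idx = rng.integers(0, n, size=n)
            Xb, yb = d.X[idx], d.y[idx]
        betas[b] = _solve_lp(Xb, yb, d.tau)
    se = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.beta / se, np.inf * np.sign(fit.beta))
    pval = 2 * stats.norm.sf(np.abs(z))
    return QRInference(method="bootstrap_xy", se=se, p_value=pval, zstat=z)


def qr_test(
    d: QRDesign,
    fit: QRFit,
    method: str = "wald_nid",
    B: int = 500,
    seed: Optional[int] = None,
) -> QRInference:
    """Per-coefficient standard errors and two-sided p-values.

    ``wald_nid`` is the default (sandwich with locally estimated
    conditional density); ``bootstrap_xy`` resamples (x, y) pairs and uses
    the normal approximation to the bootstrap coefficient distribution.
    """
    if method == "wald_nid":
        return _wald_nid(d, fit)
    if method == "bootstrap_xy":
        return _bootstrap_xy(d, fit, B, seed)
    raise ValueError(f"unknown inference method {method!r}")


def tail_membership(X0: np.ndarray, y: np.ndarray, tau: float):
    """Fractional below-quantile membership from the null-model QR fit.

    Fits y on the nuisance design X0 (intercept + structure covariates)
    at quantile tau and returns ``(w, k)``: w = 1 - a with a the LP dual
    solution, so w_i = 1 strictly below the fitted tau-quantile plane,
    0 above, fractional at basis points; sum(w) = tau * n and k =
    round(tau * n) is the integer below-quantile mass.
    """
    full = _solve_lp_full(X0, y, tau)
    if full is None:
        raise RuntimeError("null-model quantile fit failed")
    _, a = full
    w = 1.0 - a
    return w, int(round(w.sum()))


@lru_cache(maxsize=4096)
def _tail_pmf(n0: int, n1: int, n2: int, k: int):
    """Exact pmf of the dosage sum over a uniform k-subset of a panel
    with n0/n1/n2 individuals of dosage 0/1/2 (trinomial hypergeometric)."""
    tot = comb(n0 + n1 + n2, k)
    pmf: dict = {}
    for j in range(0, min(k, n1) + 1):
        for l in range(0, min(k - j, n2) + 1):
            m = k - j - l
            if m < 0 or m > n0:
                continue
            pmf[j + 2 * l] = pmf.get(j + 2 * l, 0) + comb(n1, j) * comb(n2, l) * comb(n0, m)
    vals = np.array(sorted(pmf))
    pr = np.array([pmf[v] for v in vals], dtype=float) / tot
    return vals, pr


def tail_enrichment_test(dosage, w: np.ndarray, k: int) -> float:
    """Exact two-sided test of allele enrichment in the lower quantile tail.

    Conditions on the below-quantile mass k of the null quantile fit and
    asks whether the observed below-tail dosage weight s = dosage' w is
    extreme relative to a uniformly drawn k-subset of the panel — the
    exact trinomial-hypergeometric distribution of a dosage sum. Discrete
    and family-wise valid in small samples where asymptotic Wald
    inference at extreme quantiles is not; this is the default p-value
    source of the genome scan. Dosages are rounded to {0, 1, 2} (mean
    imputation can leave fractional entries).
    """
    x = np.clip(np.rint(np.asarray(dosage, dtype=float)), 0, 2).astype(int)
    if k <= 0 or k >= len(x):
        raise ValueError(f"below-tail mass k={k} outside (0, n)")
    n0 = int((x == 0).sum()); n1 = int((x == 1).sum()); n2 = int((x == 2).sum())
    s = float(x @ w)
    vals, pr = _tail_pmf(n0, n1, n2, k)
    p_hi = float(pr[vals >= s - 1e-9].sum())
    p_lo = float(pr[vals <= s + 1e-9].sum())
    return min(1.0, 2.0 * min(p_hi, p_lo))


def pseudo_r1(objective_full: float, objective_null: float) -> float:
    """Koenker–Machado goodness of fit R1 = 1 - V_full / V_null.

    ``objective_null`` is the check-loss optimum of the reduced model
    (here: intercept + structure covariates, no SNP) at the same tau.
    """
    if objective_null <= 0:
        raise ValueError("null objective must be positive (degenerate response)")
    # allow LP solver slack: nesting guarantees full <= null only up to
    # the optimizer's tolerance
    tol = 1e-7 * max(1.0, objective_null)
    if objective_full < -tol or objective_full > objective_null + tol:
        raise ValueError("need 0 <= objective_full <= objective_null")
    return float(max(0.0, 1.0 - objective_full / objective_null))
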