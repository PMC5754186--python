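"""Principal components of the dosage matrix as population-structure covariates.

Covariance PCA (columns centered, unscaled) is the default, matching the
usual treatment of raw 0/1/2 genotype data; correlation PCA (unit-scaled
columns) is available by flag. Component signs are fixed by making the
largest-magnitude loading of each component positive, so results are
reproducible across linear-algebra backends.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import GenotypeMatrix

__all__ = ["PCResult", "genotype_pca", "select_pcs"]


@dataclasses.dataclass(frozen=True)
class PCResult:
    scores: np.ndarray      # n x k genotype coordinates (k = min(n-1, m))
    loadings: np.ndarray    # m x k SNP loadings (orthonormal columns)
    explained: np.ndarray   # variance proportions, non-increasing, sums to 1
    eigenvalues: np.ndarray
    k_selected: int
    scaled: bool

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def covariates(self, k: int = None) -> np.ndarray:
        """First k score columns, for use as fixed covariates in a scan."""
        k = self.k_selected if k is None else k
        if k > self.n_components:
            raise ValueError(f"requested {k} components, only {self.n_components} available")
        return self.scores[:, :k]


def genotype_pca(g: GenotypeMatrix, scale: bool = False, k_default: int = 7) -> PCResult:
    """PCA of the genotype dosage matrix via SVD of the centered data.

    ``explained`` holds eigenvalues of the sample covariance divided by
    their sum, over the min(n-1, m) possibly nonzero components.
    ``k_default`` seeds :attr:`PCResult.k_selected` (capped at the number
    of available components); it mirrors the common practice of carrying
    a handful of leading PCs as scan covariates.
    """
    X = np.asarray(g.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a fully observed matrix; run impute_missing first")
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 genotypes and 2 SNPs")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = list(g.snp_map.snp_id[zero][:5])
            raise ValueError(f"constant SNP column(s) with scale=True: {bad}")
        Xc = Xc / sd

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, m)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    eig = s**2 / (n - 1)
    total = eig.sum()
    explained = eig / total if total > 0 else np.zeros_like(eig)
    scores = U * s
    return PCResult(
        scores=scores,
        loadings=Vt.T,
        explained=explained,
        eigenvalues=eig,
        k_selected=min(k_default, k),
        scaled=scale,
    )


def select_pcs(pc: PCResult, rule) -> np.ndarray:
    """Indices of the retained components.

    ``rule`` is either ``{"fixed_k": k}`` (first k components) or
    ``{"cum_var": t}`` (smallest prefix whose cumulative explained
    variance reaches t).
    """
    if not isinstance(rule, dict) or len(rule) != 1:
        raise ValueError("rule must be {'fixed_k': int} or {'cum_var': float}")
    (kind, val), = rule.items()
    if kind == "fixed_k":
        k = int(val)
        if not 1 <= k <= pc.n_components:
            raise ValueError(f"fixed_k={k} outside 1..{pc.n_components}")
        return np.arange(k)
    if kind == "cum_var":
        t = float(val)
        if not 0 < t <= 1:
            raise ValueError("cum_var threshold must be in (0, 1]")
        csum = np.cumsum(pc.explained)
        k = int(np.searchsorted(csum, t - 1e-12) + 1)
        return np.arange(min(k, pc.n_components))
    raise ValueError(f"unknown selection rule {kind!r}")
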