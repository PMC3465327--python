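"""LD pruning, frequency-weighted PCA and cross-category PC comparison.

PCA follows the EIGENSTRAT normalization: each variant column is mean
centered, missing dosages are imputed to the column mean, and (with
``weighting='af'``) the column is divided by sqrt(p*(1-p)) where p is a
posterior-mean allele-frequency estimate (1 + sum g) / (2 + 2n). The
frequency weighting up-weights rare variants, which is what lets a
rare-variant PCA express a stratification axis invisible to common
variants. Scores and eigenvalues come from the singular value
decomposition of the normalized matrix; component signs are fixed by
making each component's largest-magnitude loading positive, so results are
comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from strat_spectrum.plinkio import MISSING, GenotypeMatrix


@dataclass
class PCResult:
    """Principal-component decomposition of one (pruned) variant set."""

    scores: np.ndarray            # (n_samples, k)
    eigenvalues: np.ndarray       # length k, non-increasing
    pve: np.ndarray               # proportion of variance explained, length k
    variant_index: np.ndarray     # columns used (positions into the input)
    weighting: str                # 'af' or 'none'

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(self.pve < -1e-12) or self.pve.sum() > 1 + 1e-9:
            raise ValueError("PVE must lie in [0, 1] and sum to <= 1")

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _dosage_matrix(gm) -> np.ndarray:
    return gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)


def _normalize(d: np.ndarray, weighting: str):
    """Center, mean-impute and (optionally) frequency-weight dosages.

    Returns (normalized float matrix, kept-column index); columns with no
    variance after imputation (monomorphic) are dropped.
    """
    called = d != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise ValueError("variant with no called genotypes")
    sums = np.where(called, d, 0).sum(axis=0)
    mean = sums / n_called
    x = np.where(called, d, mean[None, :]).astype(float)
    x -= mean[None, :]
    keep = (x != 0).any(axis=0)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic variants from PCA")
    x = x[:, keep]
    if weighting == "af":
        # posterior-mean frequency keeps rare-variant weights finite
        p_hat = (1 + sums[keep]) / (2 + 2 * n_called[keep])
        x /= np.sqrt(p_hat * (1 - p_hat))[None, :]
    elif weighting != "none":
        raise ValueError(f"unknown weighting {weighting!r}")
    return x, np.flatnonzero(keep)


def ld_prune(gm, maf: np.ndarray, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained column positions.

    Within each ``window``-variant window (slid by ``step``), while any
    pair of retained variants has squared dosage correlation above
    ``r2_max``, the member with lower MAF is removed (ties remove the later
    position). Variants must be ordered by chromosome and position.
    Matches the common "indep-pairwise 50 5 0.2" protocol.
    """
    d = _dosage_matrix(gm)
    m = d.shape[1]
    maf = np.asarray(maf, dtype=float)
    called = d != MISSING
    n_called = called.sum(axis=0)
    mean = np.where(called, d, 0).sum(axis=0) / np.maximum(n_called, 1)
    x = np.where(called, d, mean[None, :]).astype(float) - mean[None, :]
    sd = x.std(axis=0)
    retained = np.ones(m, dtype=bool)
    retained[sd == 0] = False  # monomorphic: uninformative, drop up front
    starts = range(0, max(m - 1, 1), step)
    for start in starts:
        idx = np.flatnonzero(retained[start:start + window]) + start
        if len(idx) < 2:
            continue
        xw = x[:, idx]
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(xw, rowvar=False)
        r2 = c ** 2
        np.fill_diagonal(r2, 0.0)
        alive = np.ones(len(idx), dtype=bool)
        while True:
            r2a = np.where(np.outer(alive, alive), r2, 0.0)
            i, j = np.unravel_index(np.argmax(r2a), r2a.shape)
            if r2a[i, j] <= r2_max:
                break
            # remove the lower-MAF member; tie -> later position
            gi, gj = idx[i], idx[j]
            if maf[gi] < maf[gj] or (maf[gi] == maf[gj] and gi > gj):
                victim = i
            else:
                victim = j
            alive[victim] = False
            retained[idx[victim]] = False
        if start + window >= m:
            break
    return np.flatnonzero(retained)


def eigen_pca(gm, k: int, weighting: str = "af") -> PCResult:
    """Principal components of a genotype matrix (see module docstring).

    ``k`` top components are returned; eigenvalues derive from the sample
    covariance of the normalized matrix and PVE is each eigenvalue over the
    sum of all eigenvalues.
    """
    d = _dosage_matrix(gm)
    n, m = d.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= k < min(n, max(m, 2)) + 1:
        raise ValueError(f"k={k} out of range for {n} samples x {m} variants")
    x, kept = _normalize(d, weighting)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    k = min(k, len(s))
    # sign convention: the largest-magnitude loading of each PC is positive
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :k] * s[:k][None, :]
    total = eigvals.sum()
    return PCResult(
        scores=scores,
        eigenvalues=eigvals[:k],
        pve=eigvals[:k] / total if total > 0 else np.zeros(k),
        variant_index=kept,
        weighting=weighting,
    )


def pc_region_anova(scores: np.ndarray, regions: np.ndarray):
    """One-way fixed-effects ANOVA of one PC's scores across regions.

    Regions with fewer than 2 samples are excluded with a warning.
    Returns (F, p).
    """
    scores = np.asarray(scores, dtype=float)
    groups = []
    for r in np.unique(regions):
        g = scores[regions == r]
        if len(g) < 2:
            warnings.warn(f"region {r!r} has <2 samples; excluded from ANOVA")
            continue
        groups.append(g)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >=2 regions with >=2 samples")
    f, p = f_oneway(*groups)
    return float(f), float(p)


def pc_cross_correlation(pcs_a: PCResult, pcs_b: PCResult,
                         top_k: int = 10) -> pd.DataFrame:
    """R-squared of each A component against B's components.

    Rows are A's PCs; columns ``PC1`` .. of B hold the squared Pearson
    correlation with that single B component, and ``TopK`` holds the
    coefficient of determination of the least-squares projection of the A
    component onto the span of B's top ``top_k`` PCs plus an intercept
    (so TopK >= every single-PC entry).
    """
    if pcs_a.scores.shape[0] != pcs_b.scores.shape[0]:
        raise ValueError("PC results must share the same samples in order")
    a = pcs_a.scores
    b = pcs_b.scores
    top_k = min(top_k, b.shape[1])
    out = {}
    for jb in range(b.shape[1]):
        r = _safe_corr(a, b[:, jb])
        out[f"PC{jb + 1}"] = r ** 2
    design = np.column_stack([np.ones(b.shape[0]), b[:, :top_k]])
    cum = np.empty(a.shape[1])
    for ja in range(a.shape[1]):
        y = a[:, ja]
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        tss = ((y - y.mean()) ** 2).sum()
        cum[ja] = 1.0 - resid @ resid / tss if tss > 0 else 0.0
    out[f"Top{top_k}"] = cum
    return pd.DataFrame(out, index=[f"PC{i + 1}" for i in range(a.shape[1])])


def _safe_corr(a: np.ndarray, y: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((ac ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, ac.T @ yc / denom, 0.0)
    return r


def disjoint_subset_stability(gm, maf: np.ndarray, n_subsets: int,
                              subset_size: int, k: int = 10,
                              weighting: str = "af",
                              seed: int | None = None):
    """PC reproducibility across random disjoint variant subsets.

    Draws ``n_subsets`` disjoint subsets of ``subset_size`` variants,
    runs :func:`eigen_pca` on each, and cross-correlates every subset pair.
    Returns (subsets, results, {(i, j): R-squared table}). Quantifies how
    much of a structure axis survives with a reduced marker panel.
    """
    d = _dosage_matrix(gm)
    m = d.shape[1]
    if n_subsets * subset_size > m:
        raise ValueError("not enough variants for the requested partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    subsets = [np.sort(perm[i * subset_size:(i + 1) * subset_size])
               for i in range(n_subsets)]
    results = [eigen_pca(d[:, s], k=k, weighting=weighting) for s in subsets]
    tables = {}
    for i in range(n_subsets):
        for j in range(i + 1, n_subsets):
            tables[(i, j)] = pc_cross_correlation(results[i], results[j], top_k=k)
    return subsets, results, tables
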