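"""Supervised ancestry assignment by admixture-proportion maximum likelihood.

Per-region allele frequencies are fixed from a labelled reference panel
(with a pseudocount of 0.5 per allele, so no frequency is exactly 0 or 1).
For each target individual the admixture proportions q over the K regions
maximize the binomial log-likelihood

    sum_j [ g_j * ln(sum_r q_r p_rj) + (2 - g_j) * ln(1 - sum_r q_r p_rj) ]

over the simplex, fitted by EM. The EM update is the standard
allele-responsibility step, so the log-likelihood is non-decreasing at
every iteration (asserted). An individual is "confidently assigned" when
its proportion for the argmax region exceeds a threshold (default 0.5).
With no differentiation between regions the likelihood is flat and the
proportions stay near uniform 1/K, so confident assignment collapses -- a
useful negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from strat_spectrum.plinkio import MISSING, GenotypeMatrix


@dataclass
class AncestryResult:
    """Admixture proportions and derived assignments for target samples."""

    Q: pd.DataFrame               # samples x regions, rows on the simplex
    log_likelihood: np.ndarray    # per sample
    assignment: np.ndarray        # argmax region label per sample
    confident: np.ndarray         # bool, max proportion > threshold
    threshold: float
    converged: bool

    def __post_init__(self) -> None:
        q = self.Q.to_numpy()
        if (q < -1e-9).any() or np.abs(q.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("each Q row must lie on the simplex")


def _reference_frequencies(ref: GenotypeMatrix | np.ndarray,
                           ref_regions: np.ndarray,
                           pseudocount: float = 0.5):
    d = ref.dosages if isinstance(ref, GenotypeMatrix) else np.asarray(ref)
    labels = np.unique(ref_regions)
    freqs = np.empty((len(labels), d.shape[1]))
    for k, r in enumerate(labels):
        block = d[ref_regions == r]
        called = block != MISSING
        copies = np.where(called, block, 0).sum(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        freqs[k] = (copies + pseudocount) / (n_alleles + 2 * pseudocount)
    return labels, np.clip(freqs, 1e-9, 1 - 1e-9)


def supervised_ancestry(ref: GenotypeMatrix | np.ndarray,
                        ref_regions: np.ndarray,
                        targets: GenotypeMatrix | np.ndarray,
                        tol: float = 1e-6,
                        max_iter: int = 2000,
                        threshold: float = 0.5,
                        pseudocount: float = 0.5) -> AncestryResult:
    """Estimate admixture proportions of targets over reference regions.

    ``ref`` and ``targets`` must share the same variant space. Returns an
    :class:`AncestryResult`; ``converged`` is False when any individual
    exhausts ``max_iter`` before the total log-likelihood gain drops below
    ``tol`` (a warning is emitted, results are still returned).
    """
    labels, p = _reference_frequencies(ref, ref_regions, pseudocount)
    k = len(labels)
    t = targets.dosages if isinstance(targets, GenotypeMatrix) else np.asarray(targets)
    sample_ids = (targets.sample_ids if isinstance(targets, GenotypeMatrix)
                  else np.array([f"T{i}" for i in range(t.shape[0])], dtype=object))
    if t.shape[1] != p.shape[1]:
        raise ValueError("reference and targets must share the variant space")
    n = t.shape[0]
    called = t != MISSING
    g = np.where(called, t, 0).astype(float)
    h = np.where(called, 2 - t, 0).astype(float)  # copies of the other allele
    denom = (g + h).sum(axis=1)  # 2 * called variants per individual

    q = np.full((n, k), 1.0 / k)
    if k == 1:
        ll = _loglik(q, p, g, h)
        return _result(q, ll, labels, sample_ids, threshold, True)

    ll_old = _loglik(q, p, g, h)
    converged = False
    for _ in range(max_iter):
        x = q @ p                      # (n, m) mixture frequency per genotype
        np.clip(x, 1e-12, 1 - 1e-12, out=x)
        # responsibilities: share of each allele copy attributed to region r
        a = (g / x) @ p.T              # (n, k)
        b = (h / (1 - x)) @ (1 - p).T
        q = q * (a + b) / denom[:, None]
        q /= q.sum(axis=1, keepdims=True)  # guard against roundoff drift
        ll = _loglik(q, p, g, h)
        gain = ll.sum() - ll_old.sum()
        assert gain > -1e-6 * max(1.0, abs(ll.sum())), \
            "EM log-likelihood decreased"
        if gain < tol:
            converged = True
            break
        ll_old = ll
    else:
        ll = ll_old
    if not converged:
        warnings.warn("supervised ancestry EM hit max_iter before tol")
    return _result(q, ll, labels, sample_ids, threshold, converged)


def _loglik(q, p, g, h) -> np.ndarray:
    x = np.clip(q @ p, 1e-12, 1 - 1e-12)
    return (g * np.log(x) + h * np.log1p(-x)).sum(axis=1)


def _result(q, ll, labels, sample_ids, threshold, converged) -> AncestryResult:
    qdf = pd.DataFrame(q, columns=list(labels), index=list(sample_ids))
    amax = q.argmax(axis=1)
    return AncestryResult(
        Q=qdf,
        log_likelihood=ll,
        assignment=labels[amax],
        confident=q[np.arange(len(q)), amax] > threshold,
        threshold=threshold,
        converged=converged,
    )


def summarize_assignment(result: AncestryResult, true_regions: np.ndarray,
                         threshold: float = 0.5):
    """Count individuals assigned to their true region with proportion above
    ``threshold``. Returns (count, fraction)."""
    true_regions = np.asarray(true_regions)
    q = result.Q
    cols = {c: i for i, c in enumerate(q.columns)}
    vals = q.to_numpy()
    ok = 0
    for i, region in enumerate(true_regions):
        j = cols.get(region)
        if j is not None and vals[i, j] > threshold:
            ok += 1
    return ok, ok / len(true_regions)
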