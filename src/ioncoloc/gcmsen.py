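"""Bulk GC-MS isotopologue correction and enrichment.

A metabolite with ``i`` carbons yields isotopologue intensities
C(m+0) ... C(m+i).  Natural ¹³C abundance smears the true labeling
distribution forward: a molecule with k labeled carbons contributes to
channel j >= k with probability Binom(j-k; i-k, p).  Correction inverts that
convolution under a non-negativity constraint; enrichment statistics are
then simple fractions of the corrected pool.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

NATURAL_13C = 0.01109  # probability of a natural 13C per carbon

__all__ = [
    "NATURAL_13C",
    "natural_abundance_matrix",
    "correct_natural_abundance",
    "isotopologue_enrichment",
    "total_carbon_enrichment",
]


def natural_abundance_matrix(n_carbons: int, natural_p: float = NATURAL_13C) -> np.ndarray:
    """Forward convolution matrix M with M[j, k] = Binom(j-k; n-k, p).

    ``M @ x`` maps a true labeling distribution x (length n+1) to the
    observed isotopologue distribution.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        M[k:, k] = stats.binom.pmf(np.arange(n - k + 1), n - k, natural_p)
    return M


def correct_natural_abundance(
    observed: np.ndarray,
    n_carbons: int,
    natural_p: float = NATURAL_13C,
    return_residual: bool = False,
):
    """Strip natural ¹³C abundance from an observed isotopologue vector.

    Solves M @ x = observed for x >= 0 by non-negative least squares, where
    M is the carbon natural-abundance convolution matrix.  Measurement noise
    can make the unconstrained solution negative; the constrained solution
    is returned and, with ``return_residual=True``, the residual norm too.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size != n_carbons + 1:
        raise ValueError(
            f"expected {n_carbons + 1} isotopologue intensities, got {obs.size}"
        )
    if np.any(obs < 0):
        raise ValueError("isotopologue intensities must be non-negative")
    M = natural_abundance_matrix(n_carbons, natural_p)
    x, residual = optimize.nnls(M, obs)
    if return_residual:
        return x, float(residual)
    return x


def isotopologue_enrichment(corrected: np.ndarray) -> np.ndarray:
    """Per-isotopologue enrichment: percent of the metabolite pool holding
    exactly x labeled carbons, Enrichment(m+x) = C(m+x) / sum_j C(m+j) * 100.
    """
    c = np.asarray(corrected, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("corrected vector sums to zero; enrichment undefined")
    return c / total * 100.0


def total_carbon_enrichment(corrected: np.ndarray, n_carbons: int | None = None) -> float:
    """Percent of the metabolite's carbons that are labeled.

    Weighted sum of the isotopologue fractions,
    sum_{k=1..i} k * Enrichment(m+k) / i, bounded in [0, 100].
    """
    c = np.asarray(corrected, dtype=float)
    if n_carbons is None:
        n_carbons = c.size - 1
    if c.size != n_carbons + 1:
        raise ValueError("vector length must be n_carbons + 1")
    enr = isotopologue_enrichment(c)
    k = np.arange(n_carbons + 1)
    return float(np.sum(k * enr) / n_carbons)
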