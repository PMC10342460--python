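"""Exact conditional test of Hardy-Weinberg equilibrium.

Given observed genotype counts, the test conditions on the allele counts and
sums the probabilities of all heterozygote counts whose conditional
probability does not exceed that of the observed count. The conditional
distribution is built by full enumeration over attainable heterozygote
counts using the stable ratio recurrence

    P(k+2) / P(k) = 4 * n_rare_hom(k) * n_common_hom(k) / ((k+1)(k+2))

which avoids large factorials.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

# Relative slack when comparing term probabilities to the observed one, so
# that exact ties (e.g. symmetric distributions) are included regardless of
# floating-point rounding.
_TIE_EPS = 1e-12


def hwe_het_distribution(n_total: int, n_alt_alleles: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Returns ``(het_counts, probabilities)`` for a sample of ``n_total``
    diploid individuals carrying ``n_alt_alleles`` alternate alleles.
    """
    if n_total < 1:
        raise InvalidArgumentError("total genotype count must be >= 1")
    if not 0 <= n_alt_alleles <= 2 * n_total:
        raise InvalidArgumentError("allele count out of range")
    rare = min(n_alt_alleles, 2 * n_total - n_alt_alleles)
    k0 = rare % 2
    ks = np.arange(k0, rare + 1, 2)
    probs = np.empty(len(ks), dtype=float)
    probs[0] = 1.0
    for i in range(len(ks) - 1):
        k = ks[i]
        n_rare_hom = (rare - k) // 2
        n_common_hom = (2 * n_total - rare - k) // 2
        probs[i + 1] = probs[i] * 4.0 * n_rare_hom * n_common_hom / ((k + 1.0) * (k + 2.0))
        if probs[i + 1] > 1e250:  # rescale guard for very large samples
            probs[: i + 2] /= probs[i + 1]
    probs /= probs.sum()
    return ks, probs


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact Hardy-Weinberg test p-value for observed genotype counts.

    Parameters
    ----------
    n_ref_hom, n_het, n_alt_hom
        Non-negative genotype counts (reference homozygote, heterozygote,
        alternate homozygote); their sum must be at least 1.

    Returns
    -------
    The two-sided exact p-value: the total conditional probability of
    heterozygote counts no more probable than the observed one.
    """
    counts = (n_ref_hom, n_het, n_alt_hom)
    if any(int(c) != c for c in counts):
        raise InvalidArgumentError(f"genotype counts must be integers, got {counts}")
    if any(c < 0 for c in counts):
        raise InvalidArgumentError(f"genotype counts must be non-negative, got {counts}")
    n = n_ref_hom + n_het + n_alt_hom
    if n < 1:
        raise InvalidArgumentError("at least one genotyped individual is required")
    n_alt = n_het + 2 * n_alt_hom
    ks, probs = hwe_het_distribution(n, n_alt)
    obs_idx = int(np.searchsorted(ks, n_het))
    p_obs = probs[obs_idx]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_EPS)].sum())
    return min(1.0, p)
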