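"""Shared exact tests and resampling conventions.

Every cohort contrast in the package funnels through this module so that the
germline carrier comparison, the signature-presence contrast and the per-gene
somatic frequency comparison all use one two-sided Fisher definition, one
Wilcoxon-Mann-Whitney definition, one Bonferroni rule and one empirical
p-value convention.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import scipy.stats as sps

__all__ = [
    "fisher_exact_two_sided",
    "mann_whitney_two_sided",
    "bonferroni",
    "empirical_pvalue",
]

# Exact enumeration is used for the rank test up to this pooled sample size;
# beyond it the normal approximation with tie and continuity corrections.
EXACT_MWW_MAX_N = 20


def fisher_exact_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for carriers k1/n1 vs k2/n2.

    Probability-mass rule: sum hypergeometric probabilities, over all 2x2
    tables with the observed margins, of every table whose probability does
    not exceed the observed table's (relative tolerance 1e-7 on the
    comparison). This is the convention of mainstream exact-test
    implementations.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError(f"inconsistent counts: {k1}/{n1} vs {k2}/{n2}")
    if n1 == 0 and n2 == 0:
        raise ValueError("degenerate margins: both cohorts empty")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def _exact_mww_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Handles ties through midranks: the null distribution of the rank sum is
    built from all C(n, nx) assignments of the pooled midranks, which is the
    exact permutation distribution conditional on the observed values.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    mean = nx * (len(pooled) + 1) / 2.0
    # two-sided by symmetry of the permutation distribution around its mean
    dev = abs(obs - mean) - 1e-9
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        s = ranks[list(idx)].sum()
        if abs(s - mean) >= dev:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact permutation enumeration when the pooled sample size is at most
    ``EXACT_MWW_MAX_N`` (ties handled through midranks); otherwise the normal
    approximation with tie correction and continuity correction. Degenerate
    input in which every pooled value is identical returns 1.0 (all ranks
    tied).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("each cohort needs at least one observation")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if len(pooled) <= EXACT_MWW_MAX_N:
        return _exact_mww_pvalue(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def bonferroni(p: float, m_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, m_tests * p)


def empirical_pvalue(observed: float, null_stats: np.ndarray) -> float:
    """Add-one empirical p: (1 + #{null >= observed}) / (B + 1).

    Never returns 0; attains its floor 1/(B+1) exactly when no null value
    reaches the observed statistic.
    """
    null_stats = np.asarray(null_stats)
    b = len(null_stats)
    if b == 0:
        raise ValueError("empty null distribution")
    return (1 + int(np.sum(null_stats >= observed))) / (b + 1)
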