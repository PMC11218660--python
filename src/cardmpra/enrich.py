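"""Rank enrichment of a region subset within the activity-ranked library.

For a library L of N designs ranked by activity and a subset R of n
members, the enrichment score at rank i is the cumulative membership
fraction minus the cumulative library fraction,

    ES_i = (1/n) * sum_{t<=i} 1[r_t in R] - i/N,

so ES_N = 0 identically; positive scores mean R concentrates toward the
top of the ranking.  Significance of the mean enrichment score comes from a
one-sided permutation test over random same-size subsets (the tail is
chosen by the sign of the observed mean score), with an optional Bonferroni
multiplier when several subsets are tested in a batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_PERMUTATIONS = 2000


@dataclass
class EnrichmentResult:
    es_curve: np.ndarray
    mean_es: float
    p_perm: float | None = None
    p_bonferroni: float | None = None


def enrichment_curve(ranked_ids: list, subset: set) -> EnrichmentResult:
    """Running enrichment score along a ranked list.

    ``ranked_ids`` must have unique entries and ``subset`` must be a
    non-empty subset of them.
    """
    N = len(ranked_ids)
    if len(set(ranked_ids)) != N:
        raise ValueError("ranked list contains duplicate ids")
    subset = set(subset)
    if not subset:
        raise ValueError("subset R is empty")
    if not subset <= set(ranked_ids):
        raise ValueError("R must be a subset of the ranked library")
    member = np.fromiter((x in subset for x in ranked_ids), dtype=float, count=N)
    n = member.sum()
    es = np.cumsum(member) / n - np.arange(1, N + 1) / N
    return EnrichmentResult(es_curve=es, mean_es=float(es.mean()))


def _mean_es_from_ranks(ranks: np.ndarray, n: int, N: int) -> np.ndarray:
    """Mean of the ES curve from the (1-based) ranks of subset members.

    mean ES = (1/(n*N)) * sum_t (N - rank_t + 1) - (N+1)/(2N); identical to
    averaging the full curve, since each member at rank t contributes 1/n to
    every ES_i with i >= t.
    """
    contrib = (N - ranks + 1).sum(axis=-1) / (n * N)
    return contrib - (N + 1) / (2 * N)


def permutation_p(ranked_ids: list, subset: set, B: int = N_PERMUTATIONS,
                  seed: int = 0, n_subsets_tested: int = 1
                  ) -> EnrichmentResult:
    """Permutation p-value for the mean enrichment score of ``subset``.

    Draws ``B`` random same-size subsets; p is the proportion with mean ES
    >= the observed value when the observed mean is positive, or <= when
    negative (one-sided, no smoothing).  ``p_bonferroni`` multiplies by the
    number of subsets tested in the batch, capped at 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    res = enrichment_curve(ranked_ids, subset)
    N, n = len(ranked_ids), len(set(subset))
    rng = np.random.default_rng(seed)
    # sample n ranks without replacement, B times
    perm_ranks = np.argsort(rng.random((B, N)), axis=1)[:, :n] + 1
    null = _mean_es_from_ranks(perm_ranks, n, N)
    if res.mean_es > 0:
        p = float((null >= res.mean_es).mean())
    elif res.mean_es < 0:
        p = float((null <= res.mean_es).mean())
    else:
        p = 1.0
    res.p_perm = p
    res.p_bonferroni = min(1.0, p * n_subsets_tested)
    return res
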