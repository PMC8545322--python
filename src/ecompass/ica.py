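"""Initial Cluster Analysis: significance of contact enrichment at the top
of a ranked DC-score array.

Given an array of L elements ordered by DC score, D of which are
*distinguished* (structural contacts, themselves ranked by closeness), the
statistic scans initial segments ending at each distinguished element and,
for each candidate length X, combines

* an enrichment component: the hypergeometric tail probability of seeing
  at least d distinguished elements among the first X; and
* an ordering component: the probability that the closer-ranked contacts
  appear as early within those d as observed (exact permutation null of
  the Spearman D-statistic for d <= 8, normal approximation beyond).

The two components are combined through the exact joint tail of their
product under the null — Pr{ p_enrich * p_order <= observed product } —
enumerated over the hypergeometric distribution of d and the discrete
ordering atoms.  (A chi-square/Fisher combination treats both p-values as
continuous uniforms and, because both components are strongly discrete at
small d, can overstate the combined p by orders of magnitude at extreme
configurations.)  The minimum over candidate X is Bonferroni-corrected by
the number of possible segment lengths L — the scan's minimum over all
initial segments is always attained at a segment ending in a distinguished
element, so only those ends are evaluated, but the selection ranges over
every length.  The S-score is -log10 of the final P; all arithmetic is
done in log space so S up to several hundred is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, norm

from .errors import DataError
from .pair_mapping import PairArray

LN10 = np.log(10.0)

#: largest d for which the ordering null is enumerated exactly
EXACT_ORDER_MAX = 8


@dataclass
class IcaResult:
    """S-score and diagnostics for one ranked array."""

    s_score: float
    log10_p: float
    best_cutoff: int  # segment length X at the optimum
    d_at_cutoff: int
    L: int
    D: int
    components: tuple[float, float]  # (enrichment p, ordering p) at optimum

    @property
    def p_value(self) -> float:
        return float(10.0**self.log10_p)


@lru_cache(maxsize=32)
def _exact_order_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null atoms of the Spearman D-statistic sum((i - sigma(i))^2).

    Returns (sorted unique statistic values, log tail Pr(D2 <= value)).
    """
    base = np.arange(n)
    stats = np.fromiter(
        (int(((base - np.array(p)) ** 2).sum())
         for p in itertools.permutations(base)),
        dtype=np.int64,
    )
    values, counts = np.unique(stats, return_counts=True)
    tail = np.cumsum(counts) / len(stats)
    return values, np.log(tail)


def _log_p_order(ranks: np.ndarray) -> float:
    """One-sided p that concordance of ranks with array order is as large
    as observed.  ``ranks`` are the global closeness ranks of the first d
    distinguished elements, in array order."""
    d = len(ranks)
    if d < 3:
        return 0.0  # log(1)
    rel = np.argsort(np.argsort(ranks))  # relative ranks 0..d-1
    d2 = int(((np.arange(d) - rel) ** 2).sum())
    if d <= EXACT_ORDER_MAX:
        values, log_tail = _exact_order_null(d)
        idx = np.searchsorted(values, d2, side="right") - 1
        return float(log_tail[idx])
    rho = 1.0 - 6.0 * d2 / (d * (d * d - 1.0))
    z = rho * np.sqrt(d - 1.0)
    return float(norm.logsf(z))


def _log_pr_order_le(d: int, log_c: float) -> float:
    """log Pr(ordering p of a random d-permutation <= c)."""
    if log_c >= 0.0:
        return 0.0
    if d < 3:
        return -np.inf  # the ordering p is identically 1
    if d <= EXACT_ORDER_MAX:
        _, log_tail = _exact_order_null(d)
        idx = np.searchsorted(log_tail, log_c, side="right") - 1
        return float(log_tail[idx]) if idx >= 0 else -np.inf
    return log_c  # continuous-uniform tail


@lru_cache(maxsize=4096)
def _hyper_row(L: int, D: int, X: int) -> tuple[np.ndarray, np.ndarray]:
    """log sf and log pmf of Hypergeom(L, D, X) over d = 0..D."""
    d = np.arange(D + 1)
    logsf = hypergeom.logsf(d - 1, L, D, X)
    logpmf = hypergeom.logpmf(d, L, D, X)
    return logsf, logpmf


def _log_p_joint(L: int, D: int, X: int, log_u: float) -> float:
    """log Pr{ p_enrich(X, d') * p_order(d', sigma) <= u } under the null."""
    logsf, logpmf = _hyper_row(L, D, X)
    d_max = min(X, D)
    lp = logpmf[: d_max + 1]
    # the 1e-9 slack keeps the observed configuration's own atom in its
    # tail despite roundoff in the log subtraction
    log_c = log_u - logsf[: d_max + 1] + 1e-9
    contrib = np.where(log_c >= 0.0, 0.0, -np.inf)
    # d' < 3: ordering p identically 1, handled by the line above;
    # 3 <= d' <= 8: exact ordering atoms; d' > 8: continuous-uniform tail
    for dp in range(3, min(d_max, EXACT_ORDER_MAX) + 1):
        if log_c[dp] < 0.0:
            contrib[dp] = _log_pr_order_le(dp, log_c[dp])
    if d_max > EXACT_ORDER_MAX:
        sl = slice(EXACT_ORDER_MAX + 1, d_max + 1)
        contrib[sl] = np.minimum(0.0, log_c[sl])
    terms = lp + contrib
    terms = terms[np.isfinite(terms)]
    if terms.size == 0:
        return -np.inf
    return float(logsumexp(terms))


def ica_s_score(array: PairArray) -> IcaResult:
    """Compute the ICA S-score of one ranked pair array.

    Distinguished elements are ranked by ascending structural distance
    (rank 1 = closest; ties broken by residue-pair order).  Candidate
    segment ends are the array positions of the distinguished elements.
    """
    L = array.L
    if L == 0:
        raise DataError("empty pair array")
    D = array.D
    if D > L:
        raise DataError("more distinguished elements than array entries")
    if D == 0:
        return IcaResult(0.0, 0.0, 0, 0, L, 0, (1.0, 1.0))

    idx = np.flatnonzero(array.distinguished)
    # global closeness ranks of the distinguished elements, in array order
    sub_pairs = array.pairs[idx]
    sub_dist = array.distances[idx]
    order = np.lexsort((sub_pairs[:, 1], sub_pairs[:, 0], sub_dist))
    ranks = np.empty(D, dtype=np.int64)
    ranks[order] = np.arange(1, D + 1)

    best = (np.inf, 0, 0, 0.0, 0.0)  # (log_pjoint, X, d, log_ph, log_po)
    for k in range(D):
        X = int(idx[k]) + 1  # 1-based segment length
        d = k + 1
        log_ph = float(_hyper_row(L, D, X)[0][d])
        log_po = _log_p_order(ranks[:d])
        log_pj = _log_p_joint(L, D, X, log_ph + log_po)
        if log_pj < best[0]:
            best = (log_pj, X, d, log_ph, log_po)

    log_praw, X, d, log_ph, log_po = best
    # the scan optimises over every initial segment length 1..L (its minimum
    # is always attained at a distinguished end, which is all we evaluate),
    # so the union bound runs over L candidate lengths
    log_p = min(0.0, log_praw + np.log(L))
    log10_p = log_p / LN10
    return IcaResult(
        s_score=-log10_p,
        log10_p=log10_p,
        best_cutoff=X,
        d_at_cutoff=d,
        L=L,
        D=D,
        components=(float(np.exp(log_ph)), float(np.exp(log_po))),
    )


def delta_s(s1: IcaResult, s2: IcaResult) -> float:
    """S1 - S2; positive favours the first MSA.

    Arrays built from the same structure share L and D by construction, and
    only such arrays are comparable; mismatched L or D is a hard error.
    """
    if s1.L != s2.L or s1.D != s2.D:
        raise DataError(
            f"S-scores are only comparable at equal L and D "
            f"(got L={s1.L}/{s2.L}, D={s1.D}/{s2.D})"
        )
    return s1.s_score - s2.s_score


def diagnostics_frame(array: PairArray):
    """Per-candidate diagnostics as a pandas DataFrame (optional dump)."""
    import pandas as pd

    L, D = array.L, array.D
    rows = []
    if D:
        idx = np.flatnonzero(array.distinguished)
        sub_pairs = array.pairs[idx]
        sub_dist = array.distances[idx]
        order = np.lexsort((sub_pairs[:, 1], sub_pairs[:, 0], sub_dist))
        ranks = np.empty(D, dtype=np.int64)
        ranks[order] = np.arange(1, D + 1)
        for k in range(D):
            X = int(idx[k]) + 1
            d = k + 1
            log_ph = float(_hyper_row(L, D, X)[0][d])
            log_po = _log_p_order(ranks[:d])
            log_pj = _log_p_joint(L, D, X, log_ph + log_po)
            rows.append(
                dict(X=X, d=d, p_enrich=np.exp(log_ph),
                     p_order=np.exp(log_po), log10_p_joint=log_pj / LN10)
            )
    return pd.DataFrame(rows)
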