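"""Exact minimum-hypergeometric (mHG) test on a ranked binary list.

Given a ranking of N genes of which B belong to a gene set, write the
ranking as a 0/1 indicator series.  For every prefix length n the
hypergeometric tail HGT(n) = P[X >= b_n] (X ~ Hypergeom(N, B, n), b_n ones
among the top n) measures enrichment at that cutoff; the mHG statistic is
the minimum tail over all cutoffs, i.e. the best achievable enrichment with
the cutoff chosen a posteriori.  Because the cutoff is optimised, the
statistic itself is not a p-value; the exact p-value is the probability,
under uniform random placement of the B ones among N positions, that the
minimum tail is at most the observed one.

The p-value is computed by the standard dynamic program over the (n, b)
lattice: a random arrangement is a monotone path from (0, 0) to (N, B), and
the DP propagates path probability while zeroing every cell whose tail
probability falls at or below the observed statistic, accumulating the
zeroed mass as the p-value.  Accumulating rejected mass directly (rather
than 1 minus the surviving mass) keeps small p-values accurate to near
machine relative precision.  Cost is O(N*B) per term.

Numerical safety: tail probabilities for the lattice are computed from
log-factorials (scipy.special.gammaln) and exponentiated per prefix row;
tails below ~1e-300 underflow to 0 and are then necessarily inside the
rejection region, which only affects p-values far below any reporting
threshold.  Returned p-values are clamped into (0, 1].
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

#: relative slack in the rejection comparison tail <= stat, so the boundary
#: cell defining the statistic is always rejected despite float jitter
#: between the two tail computations.
_REL_EPS = 1e-9

_P_FLOOR = 1e-300


def mhg_statistic(indicator: Sequence[int]) -> Tuple[float, int, int]:
    """Minimum hypergeometric tail over all prefix cutoffs.

    Returns ``(mhg_stat, n_star, b_at_cutoff)`` where ``n_star`` is the
    smallest cutoff attaining the minimum.  Degenerate series (B = 0 or
    B = N) have statistic 1.0 at cutoff N.
    """
    ind = np.asarray(indicator, dtype=np.int64)
    if ind.ndim != 1 or len(ind) == 0:
        raise ValueError("indicator must be a non-empty 1-D series")
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("indicator must be binary")
    N = len(ind)
    B = int(ind.sum())
    if B == 0 or B == N:
        return 1.0, N, B
    b = np.cumsum(ind)
    n = np.arange(1, N + 1)
    tails = hypergeom.sf(b - 1, N, B, n)
    i = int(np.argmin(tails))  # first index attaining the min
    return float(tails[i]), int(n[i]), int(b[i])


def _log_binom(lnfact: np.ndarray, n, k):
    return lnfact[n] - lnfact[k] - lnfact[n - k]


def _tail_lattice(N: int, B: int) -> np.ndarray:
    """Tail matrix T of shape (N+1, B+1): T[n, b] = P[X >= b] for
    X ~ Hypergeom(N, B, n); 0 for infeasible (n, b).

    log pmf(n, b) = ln C(B,b) + ln C(N-B, n-b) - ln C(N,n) separates into a
    b-only, an (n-b)-only and an n-only vector, so the lattice is built from
    three 1-D precomputes and a single gather.
    """
    lnfact = gammaln(np.arange(N + 1, dtype=float) + 1.0)  # lnfact[k] = ln k!
    b = np.arange(B + 1)
    k = np.arange(N - B + 1)
    n = np.arange(N + 1)
    vb = lnfact[B] - lnfact[b] - lnfact[B - b]
    vk = lnfact[N - B] - lnfact[k] - lnfact[N - B - k]
    vn = -(lnfact[N] - lnfact[n] - lnfact[N - n])
    diff = n[:, None] - b[None, :]  # n - b; feasible iff 0 <= diff <= N-B
    feasible = (diff >= 0) & (diff <= N - B)
    logpmf = vk[np.clip(diff, 0, N - B)]
    logpmf += vb[None, :]
    logpmf += vn[:, None]
    logpmf[~feasible] = -np.inf
    pmf = np.exp(logpmf, out=logpmf)
    # reverse cumulative sum along b: tail[n, b] = sum_{k>=b} pmf[n, k]
    tail = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(tail, 1.0, out=tail)


def _dp_numpy(P, b_thr, N, B, n_start, n_end):
    p_rej = 0.0
    pr_one_num = B - np.arange(B + 1, dtype=float)
    for n in range(n_start, n_end + 1):
        pr_one = pr_one_num / (N - n + 1)
        newP = P * (1.0 - pr_one)
        newP[1:] += P[:-1] * pr_one[:-1]
        t = int(b_thr[n])
        if t <= B:
            rej_mass = float(newP[t:].sum())
            if rej_mass:
                p_rej += rej_mass
                newP[t:] = 0.0
                if not newP.any():
                    return p_rej
        P = newP
    return p_rej


try:  # compiled DP kernel; the numpy path is the (identical) fallback
    from numba import njit

    @njit(cache=True)
    def _dp_numba(P, b_thr, N, B, n_start, n_end):  # pragma: no cover
        p_rej = 0.0
        for n in range(n_start, n_end + 1):
            rem = float(N - n + 1)
            bmax = min(n, B)
            for b in range(bmax, 0, -1):  # descending: P[b-1] still old value
                P[b] = P[b] * (1.0 - (B - b) / rem) + P[b - 1] * ((B - b + 1.0) / rem)
            P[0] = P[0] * (1.0 - B / rem)
            t = b_thr[n]
            if t <= B:
                rej = 0.0
                for b in range(t, bmax + 1):
                    rej += P[b]
                    P[b] = 0.0
                if rej > 0.0:
                    p_rej += rej
                    alive = False
                    for b in range(bmax + 1):
                        if P[b] > 0.0:
                            alive = True
                            break
                    if not alive:
                        return p_rej
        return p_rej

    _DP_KERNEL = _dp_numba
except Exception:  # pragma: no cover
    _DP_KERNEL = _dp_numpy


def _pmf_row(N: int, B: int, n: int) -> np.ndarray:
    """Unconstrained hypergeometric pmf over b for prefix length n."""
    lnfact = gammaln(np.arange(N + 2, dtype=float) + 1.0)
    b = np.arange(B + 1)
    feasible = (b <= n) & (n - b <= N - B)
    bc = np.where(feasible, b, 0)
    nb = np.where(feasible, n - bc, 0)
    logpmf = (
        _log_binom(lnfact, B, bc)
        + _log_binom(lnfact, N - B, nb)
        - _log_binom(lnfact, N, n)
    )
    return np.where(feasible, np.exp(logpmf), 0.0)


def _pvalue_from_lattice(mhg_stat: float, N: int, B: int, tail: np.ndarray) -> float:
    threshold = mhg_stat * (1.0 + _REL_EPS)
    reject = tail <= threshold  # (N+1, B+1); an upper-b region per row
    # first rejected b per prefix length (B+1 when the row rejects nothing);
    # tails decrease in b, so rejection is the slice [b_thr[n]:].
    b_thr = np.where(reject.any(axis=1), reject.argmax(axis=1), B + 1).astype(np.int64)

    # DP over prefix length n; P[b] = prob. of reaching (n, b) having never
    # entered the rejection region.  States infeasible for (N, B) carry zero
    # mass by induction, so the transition probabilities need no clipping.
    # Rows before the first rejecting prefix leave the distribution
    # unconstrained (it is the plain hypergeometric pmf), and rows after the
    # last rejecting prefix cannot add rejected mass, so the DP only walks
    # the [first, last] rejecting window.
    rejecting_rows = np.nonzero(b_thr[1:] <= B)[0] + 1
    if rejecting_rows.size == 0:
        return 1.0
    n_start = int(rejecting_rows[0])
    n_end = int(rejecting_rows[-1])
    P = _pmf_row(N, B, n_start - 1) if n_start > 1 else None
    if P is None:
        P = np.zeros(B + 1)
        P[0] = 1.0
    p_rej = _DP_KERNEL(P, b_thr, N, B, n_start, n_end)
    return float(min(1.0, max(p_rej, _P_FLOOR)))


def mhg_pvalue(mhg_stat: float, N: int, B: int) -> float:
    """Exact p-value of the observed mHG statistic.

    Probability, under uniform random placement of B ones among N positions,
    that the minimum prefix tail is <= ``mhg_stat``.
    """
    if not (0 <= B <= N) or N < 1:
        raise ValueError("need 0 <= B <= N, N >= 1")
    if B == 0 or B == N or mhg_stat >= 1.0:
        return 1.0
    return _pvalue_from_lattice(mhg_stat, N, B, _tail_lattice(N, B))


def mhg_test(indicator: Sequence[int]) -> Tuple[float, int, int, float]:
    """Statistic, optimal cutoff, ones at cutoff, exact p-value.

    Builds the tail lattice once and reads both the prefix-path minimum and
    the DP rejection boundary from it, so the two stages see identical
    floats.
    """
    ind = np.asarray(indicator, dtype=np.int64)
    N = len(ind)
    B = int(ind.sum())
    if B == 0 or B == N:
        return 1.0, N, B, 1.0
    tail = _tail_lattice(N, B)
    b = np.cumsum(ind)
    path = tail[np.arange(1, N + 1), b]
    i = int(np.argmin(path))
    stat, n_star, b_at = float(path[i]), i + 1, int(b[i])
    return stat, n_star, b_at, _pvalue_from_lattice(stat, N, B, tail)
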