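"""Paired nonparametric tests: Friedman across k matched conditions, Wilcoxon
signed-rank between two.

Both are rank-based, so every p-value is invariant under strictly monotone
transforms of the underlying values.  Small samples use exact permutation
distributions (within-row permutations for Friedman, sign assignments for
Wilcoxon, both with midranks so ties are handled exactly); larger samples use
the tie-corrected chi-square / normal approximations.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats as sps

FRIEDMAN_EXACT_MAX_N = 6
WILCOXON_EXACT_MAX_N = 12


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic for an (n blocks x k) matrix."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.apply_along_axis(_midranks, 1, matrix)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * (np.sum(col_sums**2) - n**2 * k * (k + 1) ** 2 / 4.0)
    den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if den == 0:  # every row completely tied
        return 0.0
    return float(num / den)


def _friedman_exact_p(ranks: np.ndarray) -> float:
    """Exact P(sum_j R_j^2 >= observed) under within-row rank permutations.

    Dynamic programme over column rank-sum states; each row contributes the
    k! orderings of its own midrank vector (duplicates kept, so tied rows are
    weighted correctly).
    """
    n, k = ranks.shape
    observed = float(np.sum(ranks.sum(axis=0) ** 2))
    states: dict[tuple, float] = {tuple([0.0] * k): 1.0}
    for row in ranks:
        perms = list(itertools.permutations(row))
        nxt: dict[tuple, float] = {}
        for state, cnt in states.items():
            for perm in perms:
                key = tuple(s + p for s, p in zip(state, perm))
                nxt[key] = nxt.get(key, 0.0) + cnt
        states = nxt
    total = sum(states.values())
    hits = sum(
        cnt
        for state, cnt in states.items()
        if sum(s * s for s in state) >= observed - 1e-9
    )
    return hits / total


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman test across k matched columns.

    Returns the tie-corrected chi-square statistic and a p-value: the exact
    within-row permutation p for n <= 6 blocks, the chi-square (k-1 df) tail
    otherwise.  Rows with missing values are an error.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains missing/non-finite values")
    n, k = matrix.shape
    q = friedman_statistic(matrix)
    ranks = np.apply_along_axis(_midranks, 1, matrix)
    if np.allclose(ranks, ranks[:, :1]):  # all columns identical within rows
        return 0.0, 1.0
    if n <= FRIEDMAN_EXACT_MAX_N:
        return q, _friedman_exact_p(ranks)
    return q, float(sps.chi2.sf(q, k - 1))


def _wilcoxon_exact_p(abs_ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments, midranks allowed."""
    n = abs_ranks.size
    w_all = np.zeros(1)
    for r in abs_ranks:  # distribution of W+ by convolution over signs
        w_all = np.concatenate([w_all, w_all + r])
    total = w_all.size
    p_le = np.sum(w_all <= w_plus + 1e-9) / total
    p_ge = np.sum(w_all >= w_plus - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic convention) with a warning; if all
    are zero the defined result is (0, 1) with a warning.  Midranks on |d|;
    exact enumeration of the 2^n sign assignments for effective n <= 12,
    tie-corrected normal approximation above.  Returns (W+, p).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1 or diffs.size < 1:
        raise ValueError("need a 1-D array of at least one difference")
    nonzero = diffs[diffs != 0]
    if nonzero.size < diffs.size:
        warnings.warn(
            f"dropping {diffs.size - nonzero.size} zero difference(s) "
            "(Wilcoxon convention)"
        )
    if nonzero.size == 0:
        return 0.0, 1.0
    ranks = _midranks(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if nonzero.size <= WILCOXON_EXACT_MAX_N:
        return w_plus, _wilcoxon_exact_p(ranks, w_plus)
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", correction=False, alternative="two-sided",
        method="approx",
    )
    return w_plus, float(res.pvalue)
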