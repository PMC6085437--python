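"""Probabilistic pairwise co-occurrence of complexes across genomes.

The null model is the standard hypergeometric ("probabilistic species
co-occurrence") model: given that complex 1 is present at *n1* of *N*
genomes and complex 2 at *n2*, the joint presence count *j* under
independence follows

    P(j) = C(n2, j) * C(N - n2, n1 - j) / C(N, n1).

A pair is scored *positive* when the probability of observing a joint
count at least as large as the observed one is below alpha, *negative*
when the probability of one at most as large is below alpha, and
*random* otherwise (two one-sided tests at the 95% significance
threshold by default, no multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import BfscanError


def support(N: int, n1: int, n2: int) -> range:
    """Admissible joint counts."""
    return range(max(0, n1 + n2 - N), min(n1, n2) + 1)


def pair_probability(N: int, n1: int, n2: int, j: int) -> float:
    """P(exactly *j* joint presences) under the hypergeometric null."""
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise BfscanError(f"marginals out of range: N={N}, n1={n1}, n2={n2}")
    if j not in support(N, n1, n2):
        raise BfscanError(
            f"joint count {j} outside support {list(support(N, n1, n2))!r}"
        )
    return float(hypergeom.pmf(j, N, n2, n1))


def pair_tails(N: int, n1: int, n2: int, j: int) -> tuple[float, float]:
    """(P(J <= j), P(J >= j)); both tails include the observed count."""
    if j not in support(N, n1, n2):
        raise BfscanError(f"joint count {j} outside support")
    rv = hypergeom(N, n2, n1)
    p_lt = float(rv.cdf(j))
    p_gt = float(rv.sf(j - 1))
    return min(p_lt, 1.0), min(p_gt, 1.0)


@dataclass(frozen=True)
class PairResult:
    complex_1: str
    complex_2: str
    N: int
    n1: int
    n2: int
    observed: int
    expected: float
    p_lt: float
    p_gt: float
    verdict: str  # positive / negative / random
    note: str = ""


def cooccur_analysis(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_presence: int = 0,
) -> list[PairResult]:
    """Score every unordered column pair of a binary presence matrix.

    Rows are genomes (sites), columns complexes.  Rows with all-zero
    presence still inform *N*; optionally require each column of a pair
    to have at least *min_presence* ones.  Verdicts are invariant to row
    and column order.
    """
    if matrix.shape[1] < 2:
        raise BfscanError("co-occurrence needs at least two complexes")
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise BfscanError("presence matrix must be binary")
    N = matrix.shape[0]
    counts = {c: int(matrix[c].sum()) for c in matrix.columns}

    results = []
    for c1, c2 in combinations(sorted(matrix.columns), 2):
        n1, n2 = counts[c1], counts[c2]
        j = int((matrix[c1] & matrix[c2]).sum())
        note = ""
        if min(n1, n2) < min_presence:
            note = "below min_presence"
        if n1 == 0 or n2 == 0:
            note = (note + "; " if note else "") + "constant all-zero column"
        p_lt, p_gt = pair_tails(N, n1, n2, j)
        sup = support(N, n1, n2)
        if len(sup) == 1:
            verdict = "random"  # single-point support: no test possible
        elif p_gt < alpha:
            verdict = "positive"
        elif p_lt < alpha:
            verdict = "negative"
        else:
            verdict = "random"
        results.append(
            PairResult(
                complex_1=c1,
                complex_2=c2,
                N=N,
                n1=n1,
                n2=n2,
                observed=j,
                expected=n1 * n2 / N if N else float("nan"),
                p_lt=p_lt,
                p_gt=p_gt,
                verdict=verdict,
                note=note,
            )
        )
    return results


def results_to_dataframe(results: list[PairResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def verdict_matrix(results: list[PairResult]) -> pd.DataFrame:
    """Symmetric complex x complex verdict table (heatmap-ready)."""
    names = sorted({r.complex_1 for r in results} | {r.complex_2 for r in results})
    mat = pd.DataFrame("", index=names, columns=names)
    for n in names:
        mat.loc[n, n] = "self"
    for r in results:
        mat.loc[r.complex_1, r.complex_2] = r.verdict
        mat.loc[r.complex_2, r.complex_1] = r.verdict
    return mat
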