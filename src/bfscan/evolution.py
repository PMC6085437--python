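"""Subunit co-evolution statistics: p-distances, Mantel tests, identity binning.

Whether the subunits of a complex co-evolved is assessed by correlating
their pairwise p-distance matrices (computed per subunit over the same
set of genomes) with a one-sided Mantel permutation test.  Homolog sets
too large for tree building are reduced by greedy incremental clustering
at a global-identity threshold (the classic longest-first heuristic of
CD-HIT-style tools), and representatives are exported for external
phylogenetics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from Bio import Align

from .core_io import BfscanError


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise BfscanError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise BfscanError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise BfscanError("distance matrix is not symmetric")
        if not np.all(np.diag(self.values) == 0):
            raise BfscanError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reordered(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def p_distance_matrix(
    sequences: dict[str, str] | list[tuple[str, str]],
    gap_policy: str = "pairwise_deletion",
) -> DistanceMatrix:
    """p-distances (mismatch fraction) from an alignment.

    Columns holding a gap (``-`` or ``.``) in either sequence of a pair
    are excluded under ``pairwise_deletion``; ``complete_deletion``
    drops columns gapped in any sequence before comparing.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise BfscanError("p-distance needs at least two sequences")
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise BfscanError("duplicate sequence labels")
    length = len(items[0][1])
    if length < 1 or any(len(s) != length for _, s in items):
        raise BfscanError("sequences must share one aligned length >= 1")
    arr = np.array([list(s.upper()) for _, s in items])
    gap = (arr == "-") | (arr == ".")
    if gap_policy == "complete_deletion":
        keep = ~gap.any(axis=0)
        arr, gap = arr[:, keep], gap[:, keep]
    elif gap_policy != "pairwise_deletion":
        raise BfscanError(f"unknown gap policy {gap_policy!r}")
    n = len(items)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gap[i] | gap[j])
            m = int(comparable.sum())
            if m == 0:
                raise BfscanError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d = float((arr[i, comparable] != arr[j, comparable]).sum()) / m
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    seed: int | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise BfscanError("Mantel: zero variance in off-diagonal distances")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "auto",
) -> MantelResult:
    """One-sided Mantel test of correlation between two distance matrices.

    *B*'s rows and columns are permuted jointly; the one-sided p-value
    (positive association) is ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    ``method='exact'`` (automatic for n <= 6) enumerates all n!
    relabelings and reports the exact fraction with ``r >= r_obs``.
    """
    if set(A.labels) != set(B.labels):
        diff = set(A.labels) ^ set(B.labels)
        raise BfscanError(f"Mantel: label sets differ by {sorted(diff)}")
    n = A.n
    if n < 3:
        raise BfscanError("Mantel needs at least 3 labels")
    B = B.reordered(A.labels)
    x = A.condensed()
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(x, B.values[iu])

    if method == "auto":
        method = "exact" if n <= 6 else "permutation"
    if method == "exact":
        total = math.factorial(n)
        count = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            r = _pearson(x, B.values[np.ix_(idx, idx)][iu])
            if r >= r_obs - 1e-12:
                count += 1
        return MantelResult(r=r_obs, p=count / total, n_perm=total, method="exact")
    if method != "permutation":
        raise BfscanError(f"unknown Mantel method {method!r}")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r = _pearson(x, B.values[np.ix_(idx, idx)][iu])
        if r >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method="permutation", seed=seed)


# ---------------------------------------------------------------------------
# greedy identity binning
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    representative_id: str
    representative_seq: str
    member_ids: list[str]
    identities: list[float]  # member identity to representative


def global_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Global alignment identity = matches / alignment columns."""
    if not a or not b:
        raise BfscanError("empty sequence in identity computation")
    if aligner is None:
        aligner = _identity_aligner()
    aln = next(iter(aligner.align(a.upper(), b.upper())))
    counts = aln.counts()
    columns = counts.aligned + counts.gaps
    return counts.identities / columns if columns else 0.0


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    return aligner


def greedy_cluster(
    sequences: dict[str, str] | list[tuple[str, str]],
    identity_threshold: float = 0.60,
) -> list[Cluster]:
    """Greedy incremental clustering at a global-identity threshold.

    Sequences are sorted longest-first (ties broken lexically by
    sequence, then id) and each joins the first existing cluster whose
    *representative* it matches at or above the threshold, otherwise
    founds a new cluster.  Deterministic; every member's identity to its
    representative is >= the threshold.
    """
    if not (0 < identity_threshold <= 1):
        raise BfscanError("identity threshold must be in (0, 1]")
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if not items:
        return []
    items.sort(key=lambda kv: (-len(kv[1]), kv[1], kv[0]))
    aligner = _identity_aligner()
    clusters: list[Cluster] = []
    for sid, seq in items:
        placed = False
        for cl in clusters:
            ident = global_identity(seq, cl.representative_seq, aligner)
            if ident >= identity_threshold:
                cl.member_ids.append(sid)
                cl.identities.append(ident)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sid, seq, [sid], [1.0]))
    return clusters


def write_representatives(clusters: list[Cluster], path) -> None:
    """Aligned-FASTA-ready export of cluster representatives."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">{cl.representative_id} n={len(cl.member_ids)}\n")
            fh.write(cl.representative_seq + "\n")
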