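"""Dendrogram construction and co-evolution testing.

Per patient, the tumour samples (primary and metastatic; blood and normal
excluded) are hierarchically clustered with complete linkage from three
feature spaces: neoantigen sets (Jaccard distance), TCR clonotype sets
(Jaccard distance on presence/absence keys, mirroring the heterogeneity
metric) and immune-cell infiltration vectors (Euclidean distance).

Two dendrograms over the same leaves are compared with the cophenetic
correlation: the Pearson correlation, over all unordered leaf pairs
matched by label, of the merge heights of each pair's lowest common
cluster.  Significance comes from a leaf-label permutation null with the
add-one estimator; for up to 7 leaves all ``n!`` permutations are
enumerated and the p-value is exact.  The test is one-sided (large
positive correlation = co-evolution) unless ``two_sided`` is requested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "Dendrogram",
    "CoevolutionTest",
    "jaccard_distance_matrix",
    "euclidean_distance_matrix",
    "complete_linkage",
    "cophenetic_correlation",
    "permutation_pvalue",
    "coevolution_test",
]

EXHAUSTIVE_MAX_LEAVES = 7


@dataclass
class Dendrogram:
    """Ultrametric merge tree over labelled leaves.

    ``merges`` follows the linkage convention: leaves are clusters
    ``0..n-1`` (in ``labels`` order) and merge ``i`` creates cluster
    ``n+i`` from its two children at the recorded height.  Complete
    linkage is monotone, so heights are non-decreasing.
    """

    labels: Tuple[str, ...]
    merges: List[Tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValidationError(f"{n} leaves require {n - 1} merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _members(self) -> Dict[int, Set[int]]:
        n = len(self.labels)
        members: Dict[int, Set[int]] = {i: {i} for i in range(n)}
        for i, (a, b, _) in enumerate(self.merges):
            members[n + i] = members[a] | members[b]
        return members

    def cophenetic(self) -> Dict[FrozenSet[str], float]:
        """Map each unordered leaf pair to the height of its lowest common
        merge."""
        n = len(self.labels)
        members = self._members()
        out: Dict[FrozenSet[str], float] = {}
        for i, (a, b, h) in enumerate(self.merges):
            for x in members[a]:
                for y in members[b]:
                    out[frozenset((self.labels[x], self.labels[y]))] = h
        return out

    def cophenetic_vector(
        self, pair_order: Optional[Sequence[Tuple[str, str]]] = None
    ) -> Tuple[List[Tuple[str, str]], np.ndarray]:
        """Cophenetic distances over sorted unordered label pairs."""
        coph = self.cophenetic()
        if pair_order is None:
            pair_order = list(itertools.combinations(sorted(self.labels), 2))
        vec = np.array([coph[frozenset(p)] for p in pair_order], dtype=float)
        return list(pair_order), vec

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = len(self.labels)
        height: Dict[int, float] = {i: 0.0 for i in range(n)}
        text: Dict[int, str] = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h) in enumerate(self.merges):
            la = h - height[a]
            lb = h - height[b]
            text[n + i] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
            height[n + i] = h
        return text[n + len(self.merges) - 1] + ";"


def jaccard_distance_matrix(sets: Dict[str, Set]) -> pd.DataFrame:
    """Symmetric Jaccard distance (1 - |A&B|/|A|B|) matrix over labelled sets.

    A pair of empty sets is at distance 0 (identical absence)."""
    labels = sorted(sets)
    _check_min_samples(labels)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[labels[i]], sets[labels[j]]
            union = len(a | b)
            d = 0.0 if union == 0 else 1.0 - len(a & b) / union
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def euclidean_distance_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix over the rows of a DataFrame."""
    labels = sorted(vectors.index)
    _check_min_samples(labels)
    x = vectors.loc[labels].to_numpy(dtype=float)
    from scipy.spatial.distance import pdist, squareform

    mat = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(mat, index=labels, columns=labels)


def _check_min_samples(labels: Sequence[str]) -> None:
    if len(labels) < 3:
        raise UndefinedMetricError(
            f"co-evolution analysis needs >= 3 samples, got {len(labels)} "
            f"(a 2-leaf tree has a single height; correlation is undefined)"
        )


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of a symmetric distance matrix.

    Ties in the minimum inter-cluster distance are broken by the smallest
    canonical label pair (lexicographically smallest member labels), so
    the result is deterministic.
    """
    if list(dist.index) != list(dist.columns):
        raise ValidationError("distance matrix must have identical row/column labels")
    arr = dist.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("distance matrix contains NaN")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    labels = tuple(dist.index)
    n = len(labels)
    # active clusters: id -> (sorted member leaf indices)
    members: Dict[int, Tuple[int, ...]] = {i: (i,) for i in range(n)}
    active = set(range(n))
    # complete-linkage distance between active clusters
    d: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = arr[i, j]
    merges: List[Tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            key = (min(i, j), max(i, j))
            cand_labels = tuple(
                sorted(labels[m] for m in members[i] + members[j])
            )
            cand = (d[key], cand_labels, key)
            if best is None or cand < best:
                best = cand
        h, _, (i, j) = best
        merges.append((i, j, h))
        members[next_id] = tuple(sorted(members[i] + members[j]))
        active -= {i, j}
        for k in sorted(active):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            d[(k, next_id)] = max(d[a], d[b])
        active.add(next_id)
        next_id += 1
    return Dendrogram(labels=labels, merges=merges)


def _matched_vectors(t1: Dendrogram, t2: Dendrogram) -> Tuple[np.ndarray, np.ndarray]:
    if set(t1.labels) != set(t2.labels):
        raise ValidationError(
            f"leaf sets differ: {sorted(set(t1.labels) ^ set(t2.labels))}"
        )
    pairs = list(itertools.combinations(sorted(t1.labels), 2))
    _, v1 = t1.cophenetic_vector(pairs)
    _, v2 = t2.cophenetic_vector(pairs)
    return v1, v2


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc * xc).sum()) * float((yc * yc).sum()))
    if denom == 0:
        raise UndefinedMetricError(
            "cophenetic correlation undefined: constant distance vector"
        )
    return float((xc * yc).sum() / denom)


def cophenetic_correlation(t1: Dendrogram, t2: Dendrogram) -> float:
    """Pearson correlation of the two cophenetic distance vectors over all
    unordered leaf pairs, matched by leaf label (not leaf order)."""
    v1, v2 = _matched_vectors(t1, t2)
    if len(v1) < 2:
        raise UndefinedMetricError("need >= 3 leaves for a cophenetic correlation")
    return _pearson(v1, v2)


def permutation_pvalue(
    t1: Dendrogram,
    t2: Dendrogram,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    two_sided: bool = False,
    rng: Optional[np.random.Generator] = None,
    max_exhaustive: int = EXHAUSTIVE_MAX_LEAVES,
) -> Tuple[float, float, bool]:
    """Leaf-label permutation test of the cophenetic correlation.

    The null redistributes t2's leaf labels uniformly.  Returns
    ``(r_observed, p, exhaustive)``.  With at most 7 leaves, all n!
    permutations are enumerated and p is the exact null fraction with
    ``r_perm >= r_obs`` (the identity permutation guarantees p >= 1/n!).
    Otherwise p uses the add-one estimator over ``n_perm`` sampled
    permutations.
    """
    labels = sorted(t1.labels)
    pairs = list(itertools.combinations(labels, 2))
    _, v1 = t1.cophenetic_vector(pairs)
    coph2 = t2.cophenetic()
    if set(t1.labels) != set(t2.labels):
        raise ValidationError("leaf sets differ between the two dendrograms")
    v2 = np.array([coph2[frozenset(p)] for p in pairs])
    r_obs = _pearson(v1, v2)
    idx = {lab: i for i, lab in enumerate(labels)}

    def r_of(perm: Sequence[str]) -> float:
        mapping = dict(zip(labels, perm))
        vp = np.array(
            [coph2[frozenset((mapping[a], mapping[b]))] for a, b in pairs]
        )
        return _pearson(v1, vp)

    tol = 1e-12

    def beats(r: float) -> bool:
        return abs(r) >= abs(r_obs) - tol if two_sided else r >= r_obs - tol

    n = len(labels)
    if n <= max_exhaustive:
        total = math.factorial(n)
        hits = sum(1 for perm in itertools.permutations(labels) if beats(r_of(perm)))
        return r_obs, hits / total, True
    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    arr = np.array(labels)
    for _ in range(n_perm):
        perm = arr[rng.permutation(n)]
        if beats(r_of(perm)):
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm), False


@dataclass
class CoevolutionTest:
    patient_id: str
    modality_a: str
    modality_b: str
    r: float
    p: float
    n_perm: int
    exhaustive: bool
    n_leaves: int


def coevolution_test(
    patient_id: str,
    dendrograms: Dict[str, Dendrogram],
    n_perm: int = 10000,
    seed: Optional[int] = None,
    two_sided: bool = False,
) -> List[CoevolutionTest]:
    """All pairwise co-evolution tests between a patient's modality trees."""
    out: List[CoevolutionTest] = []
    names = sorted(dendrograms)
    for a, b in itertools.combinations(names, 2):
        t1, t2 = dendrograms[a], dendrograms[b]
        r, p, exhaustive = permutation_pvalue(
            t1, t2, n_perm=n_perm, seed=seed, two_sided=two_sided
        )
        out.append(
            CoevolutionTest(
                patient_id=patient_id,
                modality_a=a,
                modality_b=b,
                r=r,
                p=p,
                n_perm=n_perm if not exhaustive else math.factorial(t1.n_leaves),
                exhaustive=exhaustive,
                n_leaves=t1.n_leaves,
            )
        )
    return out
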