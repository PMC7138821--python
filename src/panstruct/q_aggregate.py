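"""Alignment, clustering and averaging of replicate admixture Q matrices.

Independent estimation runs of the admixture model suffer label switching
(arbitrary permutation of ancestry columns) and may converge to genuinely
different solutions ("modes"), typically differing in which lower-level
group is split.  This module removes label switching by exact least-squares
column assignment, clusters runs by their aligned distance, discards
singleton outlier runs, averages within each cluster, and links groups
across consecutive K into a named refinement ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .core_io import QMatrix, ValidationError


@dataclass
class RunEnsemble:
    """Replicate Q matrices for one K, with per-run provenance."""

    K: int
    replicates: list[QMatrix]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for q in self.replicates:
            if q.K != self.K:
                raise ValidationError(f"replicate has K={q.K}, ensemble K={self.K}")
            if q.sample_ids != self.replicates[0].sample_ids:
                raise ValidationError("replicates disagree on sample ids")
        if not self.provenance:
            self.provenance = [{"run_id": i} for i in range(len(self.replicates))]

    @property
    def n_runs(self) -> int:
        return len(self.replicates)


@dataclass
class ModeSummary:
    """One stable mode at a given K: the averaged Q over a cluster of runs."""

    K: int
    mode_label: str
    averaged: QMatrix
    member_runs: list[int]
    discarded_runs: list[int]


def align_columns(q_ref: QMatrix, q_other: QMatrix) -> tuple[np.ndarray, QMatrix]:
    """Permute columns of *q_other* to best match *q_ref* (least squares).

    The K x K cost matrix of squared column distances is solved exactly by
    optimal assignment.  Returns ``(perm, aligned)`` where
    ``aligned[:, j] == q_other[:, perm[j]]``.
    """
    if q_ref.K != q_other.K:
        raise ValidationError(f"K mismatch: {q_ref.K} vs {q_other.K}")
    if q_ref.sample_ids != q_other.sample_ids:
        raise ValidationError("sample sets differ")
    a, b = q_ref.proportions, q_other.proportions
    # cost[p, q] = sum_i (a[i, p] - b[i, q])^2
    cost = (
        (a**2).sum(axis=0)[:, None]
        + (b**2).sum(axis=0)[None, :]
        - 2.0 * (a.T @ b)
    )
    rows, cols = linear_sum_assignment(cost)
    perm = cols[np.argsort(rows)]
    aligned = QMatrix(list(q_other.sample_ids), b[:, perm])
    return perm, aligned


def run_distance(q_a: QMatrix, q_b: QMatrix) -> float:
    """Per-cell RMS difference after optimal column alignment, in [0, 1].

    Normalized by sqrt(2 * n_samples): two disjoint hard assignments differ
    by 2 per row, so the value reaches 1 only for maximally different runs.
    """
    _, aligned = align_columns(q_a, q_b)
    diff = q_a.proportions - aligned.proportions
    return float(np.sqrt((diff**2).sum() / (2.0 * q_a.n_samples)))


def distance_matrix(ensemble: RunEnsemble) -> np.ndarray:
    n = ensemble.n_runs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = run_distance(ensemble.replicates[i], ensemble.replicates[j])
    return d


def cluster_runs(ensemble: RunEnsemble, cut_threshold: float = 0.1) -> list[list[int]]:
    """Average-linkage clustering of runs on the aligned-Q distance matrix.

    The dendrogram is cut at *cut_threshold*; clusters are returned
    largest-first (ties broken by smallest member index).
    """
    if ensemble.n_runs < 2:
        raise ValidationError("need at least 2 runs to cluster")
    d = distance_matrix(ensemble)
    link = average(squareform(d, checks=False))
    labels = fcluster(link, t=cut_threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for run, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(run)
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0]))


def _medoid(ensemble: RunEnsemble, members: Sequence[int], d: np.ndarray) -> int:
    sub = d[np.ix_(members, members)]
    return members[int(np.argmin(sub.sum(axis=1)))]


def aggregate_modes(ensemble: RunEnsemble, cut_threshold: float = 0.1) -> list[ModeSummary]:
    """Cluster runs, drop singleton outliers, and average within clusters.

    Surviving clusters become modes labelled ``"K"`` for the largest, then
    ``"K.1"``, ``"K.2"``, ... in decreasing size order.  Within each cluster
    every run is aligned to the cluster medoid before cell-wise averaging,
    so the result does not depend on run order.
    """
    clusters = cluster_runs(ensemble, cut_threshold)
    d = distance_matrix(ensemble)
    discarded = sorted(run for c in clusters if len(c) == 1 for run in c)
    surviving = [c for c in clusters if len(c) > 1]
    if not surviving:
        raise ValidationError("no stable mode: all run clusters are singletons")
    summaries = []
    for rank, members in enumerate(surviving):
        ref = ensemble.replicates[_medoid(ensemble, members, d)]
        acc = np.zeros_like(ref.proportions)
        for run in members:
            _, aligned = align_columns(ref, ensemble.replicates[run])
            acc += aligned.proportions
        avg = acc / len(members)
        avg /= avg.sum(axis=1, keepdims=True)  # keep rows on the simplex
        label = str(ensemble.K) if rank == 0 else f"{ensemble.K}.{rank}"
        summaries.append(
            ModeSummary(ensemble.K, label, QMatrix(list(ref.sample_ids), avg),
                        list(members), discarded)
        )
    return summaries


@dataclass
class GroupLadder:
    """Named groups per K and parent-child refinement edges across K levels."""

    names: dict[int, list[str]]
    edges: list[tuple[int, int, int]]  # (K_child_level, parent_col_at_K-1, child_col)

    def splits(self, k: int) -> list[int]:
        """Parent columns at level k-1 that split into >=2 children at k."""
        counts: dict[int, int] = {}
        for lev, parent, _ in self.edges:
            if lev == k:
                counts[parent] = counts.get(parent, 0) + 1
        return sorted(p for p, c in counts.items() if c >= 2)


def ladder_match(summaries: Sequence[ModeSummary],
                 base_names: Sequence[str] | None = None) -> GroupLadder:
    """Link groups across consecutive K levels into a refinement ladder.

    Each column at K+1 is matched to the K column whose admixture-proportion
    vector (across samples) it correlates with best (Pearson).  A parent with
    two or more children is a split; child names extend the parent name with
    ``1``, ``2``, ... ordered by decreasing mean proportion, otherwise the
    child inherits the parent name.
    """
    by_k = sorted(summaries, key=lambda s: s.K)
    ks = [s.K for s in by_k]
    if ks != list(range(ks[0], ks[-1] + 1)):
        missing = sorted(set(range(ks[0], ks[-1] + 1)) - set(ks))
        raise ValidationError(f"missing K level(s) {missing} in ladder input")
    first = by_k[0]
    if base_names is None:
        base_names = [f"G{j + 1}" for j in range(first.K)]
    if len(base_names) != first.K:
        raise ValidationError("base_names length must equal the lowest K")
    names: dict[int, list[str]] = {first.K: list(base_names)}
    edges: list[tuple[int, int, int]] = []
    for prev, cur in zip(by_k, by_k[1:]):
        P, C = prev.averaged.proportions, cur.averaged.proportions
        parents = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns yield nan corr
            corr = np.corrcoef(P.T, C.T)[: prev.K, prev.K:]
        corr = np.nan_to_num(corr, nan=-1.0)
        for j in range(cur.K):
            parents.append(int(np.argmax(corr[:, j])))
            edges.append((cur.K, parents[j], j))
        child_names = [""] * cur.K
        for p in range(prev.K):
            children = [j for j in range(cur.K) if parents[j] == p]
            if len(children) == 1:
                child_names[children[0]] = names[prev.K][p]
            else:
                # split: larger mean proportion gets suffix 1
                children.sort(key=lambda j: -C[:, j].mean())
                for rank, j in enumerate(children, 1):
                    child_names[j] = f"{names[prev.K][p]}{rank}"
        names[cur.K] = child_names
    return GroupLadder(names, edges)
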