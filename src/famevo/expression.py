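"""Hierarchical clustering of expression profiles and duplicate-pair
expression divergence.

The clustering follows the classic expression-analysis recipe: log2
transform with a pseudocount, 1 - Pearson correlation between gene rows
(centered by default), and average-linkage agglomeration with
deterministic smallest-index tie-breaks. Duplicate pairs are scored by
the Pearson correlation of their two profiles and flagged divergent below
a configurable threshold (default 0.5 — an explicit operationalization of
"strongly divergent" expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .phylo import DistanceMatrix

__all__ = [
    "Dendrogram",
    "log_transform",
    "correlation_distance",
    "average_linkage",
    "cut_clusters",
    "pair_expression_divergence",
    "DEFAULT_DIVERGENCE_THRESHOLD",
]

DEFAULT_DIVERGENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class Dendrogram:
    """Merge list over n items: (node_i, node_j, height) per step.

    Items are 0..n-1; merge k creates node n+k. ``leaf_order`` is a
    left-to-right leaf ordering consistent with the merges.
    """

    n_items: int
    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_items - 1:
            raise ValueError("a dendrogram over n items requires n-1 merges")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """v -> log2(v + pseudocount); negative input values are an error."""
    if np.any(m.values < 0):
        raise ValueError("expression values must be non-negative")
    return ExpressionMatrix(
        m.gene_ids, m.tissue_labels, np.log2(m.values + pseudocount)
    )


def correlation_distance(
    m: ExpressionMatrix, centered: bool = True
) -> DistanceMatrix:
    """d = 1 - Pearson correlation between gene rows.

    With ``centered=False`` the uncentered (cosine-style) correlation is
    used instead. A constant row has undefined centered correlation and
    raises an error naming the gene.
    """
    if len(m.tissue_labels) < 2:
        raise ValueError("correlation distance requires >= 2 tissues")
    values = m.values.astype(float)
    if centered:
        sd = values.std(axis=1)
        bad = [g for g, s in zip(m.gene_ids, sd) if s == 0]
        if bad:
            raise ValueError(f"constant expression row(s): {bad}")
        corr = np.corrcoef(values)
    else:
        norms = np.linalg.norm(values, axis=1)
        bad = [g for g, s in zip(m.gene_ids, norms) if s == 0]
        if bad:
            raise ValueError(f"all-zero expression row(s): {bad}")
        normalized = values / norms[:, None]
        corr = normalized @ normalized.T
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(ids=list(m.gene_ids), values=d)


def average_linkage(d: DistanceMatrix) -> Dendrogram:
    """UPGMA-style average-linkage agglomeration.

    At each step the pair of clusters with the smallest average pairwise
    distance merges; ties break on the smallest (i, j) cluster-index pair.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("clustering requires >= 2 items")
    dist = d.values.astype(float).copy()
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    cluster_dist: dict[tuple[int, int], float] = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    order: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        (ci, cj), height = min(
            cluster_dist.items(), key=lambda kv: (kv[1], kv[0])
        )
        merges.append((ci, cj, height))
        merged = members[ci] + members[cj]
        order[next_id] = order[ci] + order[cj]
        del clusters[ci], clusters[cj]
        for key in [k for k in cluster_dist if ci in k or cj in k]:
            del cluster_dist[key]
        for ck in clusters:
            pairs = [
                dist[a, b] for a in merged for b in members[ck]
            ]
            cluster_dist[(min(ck, next_id), max(ck, next_id))] = float(
                np.mean(pairs)
            )
        clusters[next_id] = merged
        members[next_id] = merged
        next_id += 1
    return Dendrogram(
        n_items=n,
        merges=tuple(merges),
        leaf_order=tuple(order[next_id - 1]),
    )


def cut_clusters(dendro: Dendrogram, k: int) -> list[int]:
    """Cluster labels (0..k-1) from cutting the dendrogram at k clusters.

    Labels are assigned in order of each cluster's smallest item index.
    """
    if not 1 <= k <= dendro.n_items:
        raise ValueError("k must be between 1 and the number of items")
    parent = list(range(dendro.n_items + len(dendro.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (i, j, _h) in enumerate(dendro.merges[: dendro.n_items - k]):
        node = dendro.n_items + step
        parent[find(i)] = node
        parent[find(j)] = node
    roots: dict[int, list[int]] = {}
    for item in range(dendro.n_items):
        roots.setdefault(find(item), []).append(item)
    labels = [0] * dendro.n_items
    for label, (_root, items) in enumerate(
        sorted(roots.items(), key=lambda kv: min(kv[1]))
    ):
        for item in items:
            labels[item] = label
    return labels


def pair_expression_divergence(
    pairs: Sequence,
    m: ExpressionMatrix,
    threshold: float = DEFAULT_DIVERGENCE_THRESHOLD,
) -> pd.DataFrame:
    """Pearson correlation of duplicate-pair profiles; divergent below
    ``threshold``. ``pairs`` may be DuplicationEvents or (a, b) tuples."""
    rows = []
    for pair in pairs:
        gene_a = getattr(pair, "gene_a", None) or pair[0]
        gene_b = getattr(pair, "gene_b", None) or pair[1]
        for gene in (gene_a, gene_b):
            if gene not in m.gene_ids:
                raise ValueError(f"gene {gene!r} absent from expression matrix")
        corr = float(np.corrcoef(m.row(gene_a), m.row(gene_b))[0, 1])
        rows.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "correlation": corr,
                "divergent": bool(corr < threshold),
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation", "divergent"])
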