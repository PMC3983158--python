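"""Protein MSA, p-distances, neighbor-joining, bootstrap and rooting.

The tree pipeline mirrors the classical distance workflow: progressive
multiple alignment (k-mer guide tree, profile-profile global alignment
with affine gaps), uncorrected p-distances under pairwise deletion,
Saitou-Nei neighbor joining with deterministic tie-breaks, bootstrap
supports from column resampling, outgroup rooting, and lineage-label
monophyly reports.

Determinism: NJ breaks Q-criterion ties on the smallest (i, j) index pair;
profile alignment traceback prefers diagonal over up over left; bootstrap
replicates derive from a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import Scoring
from .io import SeqRecordSet
from .tree import PhyloTree, TreeNode

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "progressive_align",
    "pdistance_matrix",
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
    "assign_groups",
]

_GAP = "-"
_AA = "ACDEFGHIKLMNPQRSTVWYBZX*"


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over named sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows]

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(_GAP, "")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distance")


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    """1 - fraction of shared distinct k-mers (relative to the smaller set)."""
    kmer_sets = [
        {s[i : i + k] for i in range(len(s) - k + 1)} for s in seqs
    ]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(kmer_sets[i]), len(kmer_sets[j]))
            shared = len(kmer_sets[i] & kmer_sets[j]) if denom else 0
            d[i, j] = d[j, i] = 1.0 - (shared / denom if denom else 0.0)
    return d


def _profile_columns(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue frequency vectors (gaps excluded, renormalized)."""
    index = {aa: i for i, aa in enumerate(_AA)}
    ncol = len(rows[0])
    freq = np.zeros((ncol, len(_AA)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != _GAP:
                freq[j, index[ch]] += 1.0
    totals = freq.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return freq / totals


def _substitution_array(scoring: Scoring) -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(scoring.matrix or "BLOSUM62")
    arr = np.zeros((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            try:
                arr[i, j] = mat[a, b]
            except (KeyError, IndexError):
                arr[i, j] = 0.0
    return arr


def _align_profiles(
    rows_a: list[str], rows_b: list[str], sub: np.ndarray, scoring: Scoring
) -> tuple[list[str], list[str]]:
    """Global affine-gap DP between two profiles; returns gapped row sets."""
    fa = _profile_columns(rows_a)
    fb = _profile_columns(rows_b)
    score = fa @ sub @ fb.T  # column-column expected substitution score
    la, lb = score.shape
    go, ge = scoring.gap_open, scoring.gap_extend
    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, lb + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, la + 1):
        si = score[i - 1]
        for j in range(1, lb + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + si[j - 1]
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
    # traceback, preferring diagonal > up (gap in B) > left (gap in A)
    i, j = la, lb
    ops: list[str] = []
    state = max(
        (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])), key=lambda t: t[1]
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = "MXY"[int(np.argmax(prev))]
        elif state == "X":
            ops.append("U")
            from_m = M[i - 1, j] + go
            from_x = X[i - 1, j] + ge
            from_y = Y[i - 1, j] + go
            i -= 1
            state = "MXY"[int(np.argmax([from_m, from_x, from_y]))]
        else:
            ops.append("L")
            from_m = M[i, j - 1] + go
            from_y = Y[i, j - 1] + ge
            from_x = X[i, j - 1] + go
            j -= 1
            state = "MYX"[int(np.argmax([from_m, from_y, from_x]))]
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[ib])
            ia += 1
            ib += 1
        elif op == "U":
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            for r in range(len(rows_b)):
                out_b[r].append(_GAP)
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append(_GAP)
            for r, row in enumerate(rows_b):
                out_b[r].append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(
    seqs: SeqRecordSet, scoring: Optional[Scoring] = None
) -> MultipleAlignment:
    """Progressive multiple alignment along a k-mer NJ guide tree.

    With two sequences this reduces to a single global profile alignment
    of the pair; stripping gaps from any row recovers the input sequence
    exactly.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment requires >= 2 sequences")
    scoring = scoring or Scoring.protein()
    sub = _substitution_array(scoring)
    ids = seqs.ids
    residues = [seqs[i].residues for i in ids]
    if len(ids) == 2:
        rows_a, rows_b = _align_profiles(
            [residues[0]], [residues[1]], sub, scoring
        )
        return MultipleAlignment(ids=list(ids), rows=[rows_a[0], rows_b[0]])
    d = _kmer_distance_matrix(residues)
    guide = nj_tree(DistanceMatrix(ids=list(ids), values=d))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [residues[ids.index(node.name)]]
        child_profiles = [merge(c) for c in node.children]
        acc_ids, acc_rows = child_profiles[0]
        for nxt_ids, nxt_rows in child_profiles[1:]:
            rows_a, rows_b = _align_profiles(acc_rows, nxt_rows, sub, scoring)
            acc_ids = acc_ids + nxt_ids
            acc_rows = rows_a + rows_b
        return acc_ids, acc_rows

    merged_ids, merged_rows = merge(guide.root)
    order = [merged_ids.index(i) for i in ids]
    return MultipleAlignment(
        ids=list(ids), rows=[merged_rows[k] for k in order]
    )


# ---------------------------------------------------------------------------
# distances


def pdistance_matrix(
    aln: MultipleAlignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Uncorrected p-distance with pairwise deletion of gap columns.

    For each pair only columns where both rows are ungapped count; a pair
    sharing no columns is an error naming the pair.
    """
    if deletion != "pairwise":
        raise ValueError("only pairwise deletion is supported")
    arr = np.array([list(row) for row in aln.rows])
    nongap = arr != _GAP
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = int(both.sum())
            if shared == 0:
                raise ValueError(
                    f"no shared ungapped columns for pair "
                    f"({aln.ids[i]}, {aln.ids[j]})"
                )
            mism = float((arr[i][both] != arr[j][both]).mean())
            d[i, j] = d[j, i] = mism
    return DistanceMatrix(ids=list(aln.ids), values=d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root node).

    Ties in the Q criterion break on the smallest (i, j) pair of current
    node indices. Negative branch-length estimates are clamped to zero
    with the deficit moved to the sibling edge.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    D = d.values.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))  # row-major: smallest (i, j) on ties
        ai, aj = int(iu[0][k]), int(iu[1][k])
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        ni, nj_ = active[ai], active[aj]
        nodes[ni].length = li
        nodes[nj_].length = lj
        parent = TreeNode(children=[nodes[ni], nodes[nj_]])
        new_row = 0.5 * (
            D[ni, :] + D[nj_, :] - dij
        )
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row)] = new_row
        D[: len(new_row), -1] = new_row
        D[-1, -1] = 0.0
        nodes.append(parent)
        new_index = len(nodes) - 1
        active = [a for a in active if a not in (ni, nj_)] + [new_index]
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: MultipleAlignment, n_reps: int = 1000, seed: int = 0
) -> tuple[PhyloTree, dict]:
    """NJ tree with bootstrap supports from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds
    the p-distance matrix and the NJ tree, and records its bipartitions;
    support is the percentage of valid replicates containing the same
    split. Replicates where some pair shares no ungapped columns are
    dropped and counted in the returned info dict.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(pdistance_matrix(aln))
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    counts: dict[frozenset, int] = {s: 0 for s in tree.splits()}
    dropped = 0
    valid = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in aln.rows]
        rep_aln = MultipleAlignment(ids=list(aln.ids), rows=rows)
        try:
            rep_tree = nj_tree(pdistance_matrix(rep_aln))
        except ValueError:
            dropped += 1
            continue
        valid += 1
        for split in rep_tree.splits():
            if split in counts:
                counts[split] += 1
    supports = {
        s: (100.0 * c / valid if valid else 0.0) for s, c in counts.items()
    }
    _attach_supports(tree, supports)
    info = {"replicates": n_reps, "valid": valid, "dropped": dropped}
    return tree, info


def _attach_supports(tree: PhyloTree, supports: Mapping[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(c) for c in node.children))
        side = below if ref not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1 and side in supports:
            node.support = supports[side]
        return below

    for child in tree.root.children:
        visit(child)


# ---------------------------------------------------------------------------
# rooting and groups


def root_with_outgroup(tree: PhyloTree, outgroup_ids: Sequence[str]) -> PhyloTree:
    """Root on the edge separating the outgroup set from the rest.

    The outgroup must be present and monophyletic in the unrooted tree.
    """
    outgroup = frozenset(outgroup_ids)
    leaves = frozenset(tree.leaf_names)
    missing = outgroup - leaves
    if missing:
        raise ValueError(f"unknown outgroup id(s): {sorted(missing)}")
    if not outgroup or outgroup == leaves:
        raise ValueError("outgroup must be a proper non-empty leaf subset")
    ingroup = leaves - outgroup

    target = None
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = frozenset(node.leaf_names())
        if below == outgroup or below == ingroup:
            target = node
            break
    if target is None:
        raise ValueError("outgroup is not monophyletic in the unrooted tree")
    rooted = tree.reroot_on_edge(target)
    # orient: outgroup side first
    first = frozenset(rooted.root.children[0].leaf_names())
    if first != outgroup:
        rooted.root.children.reverse()
    return rooted


def assign_groups(
    tree: PhyloTree, leaf_labels: Mapping[str, str]
) -> dict[str, dict]:
    """Monophyly report per lineage label on a rooted tree.

    For each label: whether its leaves form one clade, and the maximal
    pure clades (every descendant leaf carries the label).
    """
    leaves = tree.leaf_names
    unlabeled = [l for l in leaves if l not in leaf_labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled}")
    label_sets: dict[str, set] = {}
    for leaf in leaves:
        label_sets.setdefault(leaf_labels[leaf], set()).add(leaf)

    pure: dict[int, str] = {}
    below_map: dict[int, frozenset] = {}

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf:
            below = frozenset([node.name])
        else:
            below = frozenset().union(*(visit(c) for c in node.children))
        below_map[id(node)] = below
        node_labels = {leaf_labels[l] for l in below}
        if len(node_labels) == 1:
            pure[id(node)] = next(iter(node_labels))
        return below

    visit(tree.root)

    maximal: dict[str, list[list[str]]] = {lab: [] for lab in label_sets}

    def collect(node: TreeNode, parent_pure: bool) -> None:
        is_pure = id(node) in pure
        if is_pure and not parent_pure:
            maximal[pure[id(node)]].append(sorted(below_map[id(node)]))
        for c in node.children:
            collect(c, is_pure)

    collect(tree.root, False)
    report = {}
    for label, members in label_sets.items():
        clades = maximal[label]
        mono = any(frozenset(c) == frozenset(members) for c in clades)
        report[label] = {"monophyletic": mono, "clades": clades}
    return report
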