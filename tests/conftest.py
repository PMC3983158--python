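import numpy as np
import pytest

from famevo.simulate import SimConfig, generate_family_genome
from famevo.tree import PhyloTree, TreeNode


@pytest.fixture(scope="session")
def genome():
    """One deterministic synthetic genome shared across tests."""
    return generate_family_genome(SimConfig(seed=11))


def random_leafy_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """Random binary tree with positive branch lengths (additive oracle)."""
    nodes = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 0.5)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right, left = nodes.pop(int(j)), nodes.pop(int(i))
        nodes.append(
            TreeNode(
                length=float(rng.uniform(0.05, 0.5)), children=[left, right]
            )
        )
    return PhyloTree(TreeNode(children=nodes), rooted=False)


def tree_leaf_distances(tree: PhyloTree):
    """Leaf-to-leaf path lengths (independent of NJ): ids, matrix."""
    parents = {}

    def walk(node):
        for child in node.children:
            parents[id(child)] = (node, child.length)
            walk(child)

    walk(tree.root)
    leaves = [n for n in tree.root.walk() if n.is_leaf]
    ids = [n.name for n in leaves]

    def path_to_root(node):
        out = {}
        total = 0.0
        while id(node) in parents:
            parent, length = parents[id(node)]
            total += length
            out[id(parent)] = total
            node = parent
        out.setdefault(id(node), total)
        return out

    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        pa = path_to_root(leaves[i])
        for j in range(i + 1, n):
            pb = path_to_root(leaves[j])
            d[i, j] = d[j, i] = min(
                pa[k] + pb[k] for k in pa if k in pb
            )
    return ids, d
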