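"""NJ phylogeny with bootstrap support from a protein alignment.

The family proteins are aligned progressively, pairwise-deletion
p-distances feed neighbor joining, and clade support is the percentage
of column-resampled replicates containing the same leaf bipartition.
"""

from famevo import (
    bootstrap_support,
    generate_family_genome,
    progressive_align,
    write_newick,
)
from famevo.simulate import SimConfig

cds, proteins, models, _, truth = generate_family_genome(SimConfig(seed=42))
family = proteins.subset(truth.family_member_ids)

aln = progressive_align(family)
tree, info = bootstrap_support(aln, n_reps=200, seed=42)

print(f"alignment: {len(aln.ids)} sequences x {aln.n_columns} columns")
print(f"bootstrap: {info['valid']} valid replicates of {info['replicates']}")
print("tree:", write_newick(tree))
for split, support in sorted(
    tree.splits(with_support=True).items(), key=lambda kv: -kv[1]
):
    print(f"  split {sorted(split)}: {support:.0f}% support")

# the two planted duplicate pairs form strongly supported cherries: the
# pair members are each other's closest relatives by construction.
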