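"""Motif architecture table, logo information content, intron statistics.

The architecture table is a presence/absence matrix of the catalytic
motifs across proteins; column information (in bits, 0 to log2(20))
measures per-position conservation of an alignment; intron statistics
summarize the exon/intron organisation of the family.
"""

from famevo import (
    architecture_table,
    column_information,
    generate_family_genome,
    intron_stats,
    progressive_align,
)
from famevo.simulate import SimConfig

cds, proteins, models, _, truth = generate_family_genome(SimConfig(seed=42))
family = proteins.subset(truth.family_member_ids)

print("motif architecture (1 = motif present):")
print(architecture_table(family).to_string())

aln = progressive_align(family)
cols = column_information([aln.column(j) for j in range(aln.n_columns)])
most = max(cols, key=lambda c: c.information)
print(f"\n{sum(c.information > 4.0 for c in cols)} of {len(cols)} alignment "
      f"columns are near-invariant (> 4 bits of log2(20) = 4.32 max); "
      f"e.g. column {most.position} at {most.information:.2f} bits")

records, summary = intron_stats([m for m in models
                                 if m.gene_id in truth.family_member_ids])
print(f"\nintron counts: modal {summary['modal_introns']} "
      f"({summary['modal_fraction']:.0%} of genes), "
      f"range {summary['min_introns']}-{summary['max_introns']}")
# the canonical family structure is 3 introns per gene.
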