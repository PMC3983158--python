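# famevo

Gene-family expansion analysis on annotated genomes — the classical
comparative-genomics survey of a plant enzyme family (the motivating case
is 3-hydroxy-3-methylglutaryl-CoA reductase, HMGR, the rate-limiting
enzyme of the cytosolic mevalonate pathway), packaged as a reusable,
tested pipeline:

1. **Identification** — local-alignment screen of a proteome with seed
   queries, confirmed by presence of conserved catalytic motifs (the two
   HMG-CoA binding motifs `EMPVGYVQIP` and `TTEGCLVA`, and the two
   NADP(H) binding motifs `DAMGMNM` and `GTVGGGT`), isoform
   deduplication, chromosome-order naming.
2. **Motif architecture** — presence/absence tables and sequence-logo
   column information, I = log₂20 + Σₐ pₐ log₂ pₐ bits.
3. **Gene structure** — intron/exon statistics from GFF3 annotation.
4. **Phylogeny** — progressive protein alignment, p-distances with
   pairwise deletion, Saitou–Nei neighbor joining, bootstrap supports
   from column resampling, outgroup rooting, lineage monophyly reports.
5. **Duplications** — duplicate pairs called when a global CDS alignment
   covers >80% of the longer gene with >80% identity; pairs classified
   tandem (same chromosome, ≤50 kb apart, ≤1 intervening gene) or
   segmental.
6. **Ka/Ks and dating** — Nei–Gojobori counting (fractional synonymous
   sites, pathway-averaged differences) with Jukes–Cantor correction
   d = −¾ ln(1 − 4p/3); selection regime from Ka/Ks (<1 purifying,
   =1 neutral, >1 positive); duplication age T = Ks/2λ with per-species
   synonymous clock rates λ (e.g. 6.5×10⁻⁹ /site/year for maize).
7. **Expression** — log₂ transform, correlation distance, average-linkage
   clustering, and duplicate-pair expression-divergence flags.

Because genome-scale inputs require large downloads, the package ships a
first-class **synthetic-genome generator**: a multi-chromosome toy genome
with a planted gene family (shared catalytic motifs, canonical 3-intron
structure, duplicate pairs evolved at chosen ω and target Ks, tandem and
segmental placements), decoy genes, and a clustered expression matrix —
all deterministic per seed, so every stage is validated against known
ground truth.

## Worked example

```python
from famevo import (SimConfig, generate_family_genome, call_duplications,
                    classify_duplication, analyze_pair)

cds, proteins, models, expression, truth = generate_family_genome(SimConfig(seed=42))
family = cds.subset(truth.family_member_ids)
for event in (classify_duplication(e, models) for e in call_duplications(family)):
    r = analyze_pair(cds[event.gene_a].residues, cds[event.gene_b].residues,
                     species_code="Zm")
    print(event.gene_a, event.gene_b, event.dup_type,
          f"Ka={r.Ka:.4f} Ks={r.Ks:.4f} ratio={r.ratio:.3f} T={r.T_mya:.1f} Mya")
```

prints

```
g1 g2 tandem Ka=0.0382 Ks=0.1727 ratio=0.221 T=13.3 Mya
g3 g4 segmental Ka=0.0494 Ks=0.2912 ratio=0.170 T=22.4 Mya
```

Both planted pairs are recovered with their true tandem/segmental labels;
the estimated Ks values sit near the planted synonymous divergences (0.2
and 0.3), the Ka/Ks ratios well below 1 reflect the purifying selection
built into the simulation, and the ages follow from the maize synonymous
clock. The `examples/` directory contains one short script per capability
(simulation, identification, motifs/structure, phylogeny,
duplications/Ka/Ks, expression), each printing the numbers it computes
and what they mean.

A thin CLI mirrors the stages:

```bash
famevo simulate --seed 42 --out demo/
famevo identify --queries demo/queries.faa --proteome demo/proteins.faa \
                --gff demo/genes.gff3 --species-code Zm --out demo/names.tsv
famevo run --seed 42 --out demo/run/        # the whole pipeline
```

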