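"""Synthetic gene-family genomes with known duplication history.

Generates a toy multi-chromosome genome containing a planted gene family
(members share the four catalytic consensus motifs and a canonical
3-intron structure; chosen pairs evolve at a given omega and target Ks and
are placed tandemly or segmentally), random decoy genes, and a clustered
expression matrix. Everything is deterministic per seed, so every
downstream stage of the pipeline can be tested against ground truth.

Codon evolution is an accept/reject scheme indexed by omega: random
single-nucleotide proposals, synonymous proposals always accepted,
nonsynonymous ones accepted with probability omega, stop-creating
proposals rejected. The process stops once the accepted synonymous event
count reaches ``target_ks`` times the Nei-Gojobori synonymous site count
of the ancestor — the same definition of "site" the downstream estimator
uses. Nonsynonymous proposals inside motif codons are always rejected,
mimicking the strong purifying selection acting on catalytic residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ExpressionMatrix, GeneModel, SeqRecord, SeqRecordSet
from .kaks import SENSE_CODONS, STOP_CODONS, count_sites, translate_codon
from .motifs import CATALYTIC_MOTIFS, scan_motif

__all__ = [
    "SimConfig",
    "PlantedPair",
    "GroundTruth",
    "simulate_codon_pair",
    "generate_family_genome",
    "simulate_expression_matrix",
]

_BASES = "ACGT"
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# synonymous codon choices per amino acid
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(translate_codon(_codon), []).append(_codon)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic genome."""

    n_chromosomes: int = 5
    chromosome_length: int = 1_000_000
    n_family_genes: int = 6
    n_decoys: int = 6
    planted_pairs: tuple[tuple[str, float, float], ...] = (
        ("tandem", 0.2, 0.2),
        ("segmental", 0.2, 0.3),
    )
    intron_count_per_gene: int = 3
    protein_length: int = 300
    background_ks: float = 1.2
    background_omega: float = 0.5
    n_tissues: int = 6
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length,
               self.n_family_genes, self.protein_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.n_decoys < 0 or self.intron_count_per_gene < 0:
            raise ValueError("n_decoys and intron count must be >= 0")
        for pair_type, omega, target_ks in self.planted_pairs:
            if pair_type not in {"tandem", "segmental"}:
                raise ValueError(f"unknown pair type {pair_type!r}")
            if omega < 0 or target_ks < 0:
                raise ValueError("omega and target_ks must be >= 0")
        if 2 * len(self.planted_pairs) > self.n_family_genes:
            raise ValueError("not enough family genes for the planted pairs")


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    pair_type: str
    omega: float
    target_ks: float
    realized_ks: float
    syn_events: int
    nonsyn_events: int


@dataclass
class GroundTruth:
    """What was planted: the acceptance oracle for the whole pipeline."""

    family_member_ids: list[str]
    decoy_ids: list[str]
    duplicate_pairs: list[PlantedPair]
    expression_clusters: dict[str, int] = field(default_factory=dict)
    #: ancestral family protein — the natural seed query for identification
    ancestor_protein: str = ""

    def __post_init__(self) -> None:
        members = set(self.family_member_ids)
        for pair in self.duplicate_pairs:
            if pair.gene_a not in members or pair.gene_b not in members:
                raise ValueError(
                    f"planted pair {pair.gene_a}/{pair.gene_b} references "
                    "non-family genes"
                )


# ---------------------------------------------------------------------------
# codon-level evolution


def _random_sense_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        choices = _CODONS_FOR_AA[aa]
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _synonymous_sites(cds: str) -> float:
    return sum(count_sites(cds[i : i + 3])[0] for i in range(0, len(cds), 3))


def _evolve(
    cds: str,
    omega: float,
    delta_ks: float,
    rng: np.random.Generator,
    protected_codons: frozenset[int] = frozenset(),
) -> tuple[str, int, int]:
    """Evolve a CDS until accepted synonymous events reach
    ``delta_ks * S(ancestor)``; returns (cds, syn_events, nonsyn_events)."""
    target = delta_ks * _synonymous_sites(cds)
    seq = list(cds)
    syn = nonsyn = 0
    while syn < target:
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        base = _BASES[rng.integers(0, 4)]
        if base == old:
            continue
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        mutant = codon[: pos % 3] + base + codon[pos % 3 + 1 :]
        if mutant in STOP_CODONS:
            continue
        if translate_codon(mutant) == translate_codon(codon):
            seq[pos] = base
            syn += 1
        else:
            if ci in protected_codons:
                continue
            if rng.random() < omega:
                seq[pos] = base
                nonsyn += 1
    return "".join(seq), syn, nonsyn


def simulate_codon_pair(
    n_codons: int, omega: float, target_ks: float, seed: int
) -> tuple[str, str, dict]:
    """Simulate a duplicate CDS pair diverged to a target synonymous level.

    Returns the ancestral copy, the evolved copy, and realized counts
    (accepted synonymous/nonsynonymous events, ancestor synonymous sites,
    realized event-based Ks).
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    rng = np.random.default_rng(seed)
    cds_a = _random_sense_cds(n_codons, rng)
    cds_b, syn, nonsyn = _evolve(cds_a, omega, target_ks, rng)
    s_anc = _synonymous_sites(cds_a)
    counts = {
        "syn_events": syn,
        "nonsyn_events": nonsyn,
        "ancestor_syn_sites": s_anc,
        "realized_ks": syn / s_anc,
    }
    return cds_a, cds_b, counts


# ---------------------------------------------------------------------------
# expression


def simulate_expression_matrix(
    n_genes: int,
    n_tissues: int,
    clusters: Sequence[tuple[int, Sequence[float]]],
    noise_sd: float,
    seed: int | np.random.Generator,
    gene_ids: Optional[Sequence[str]] = None,
    tissue_labels: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, list[int]]:
    """Draw gene expression rows around per-cluster mean profiles.

    Rows of cluster c are ``mean_profile(c) + N(0, noise_sd)`` truncated at
    zero. Returns the matrix and the per-gene cluster assignment (genes
    are assigned to clusters in listed order).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if sum(size for size, _ in clusters) != n_genes:
        raise ValueError("cluster sizes must sum to n_genes")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    gene_ids = list(gene_ids) if gene_ids else [f"g{i+1}" for i in range(n_genes)]
    tissue_labels = (
        list(tissue_labels) if tissue_labels
        else [f"tissue{j+1}" for j in range(n_tissues)]
    )
    rows = []
    labels: list[int] = []
    for c, (size, profile) in enumerate(clusters):
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (n_tissues,):
            raise ValueError("mean profile length must equal n_tissues")
        for _ in range(size):
            row = profile + rng.normal(0.0, noise_sd, size=n_tissues)
            rows.append(np.clip(row, 0.0, None))
            labels.append(c)
    matrix = ExpressionMatrix(gene_ids, tissue_labels, np.vstack(rows))
    return matrix, labels


# ---------------------------------------------------------------------------
# genome assembly


def _random_decoy_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition protein guaranteed to miss every catalytic motif
    even at one mismatch."""
    while True:
        protein = "".join(
            _AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)
        )
        if not any(
            scan_motif(protein, consensus, max_mismatch=1)
            for consensus in CATALYTIC_MOTIFS.values()
        ):
            return protein


def _motif_layout(protein_length: int) -> list[tuple[int, str]]:
    """Fixed offsets for the four catalytic motifs inside the scaffold."""
    names = list(CATALYTIC_MOTIFS)
    spacing = protein_length // (len(names) + 1)
    layout = []
    offset = spacing // 2
    for name in names:
        layout.append((offset, CATALYTIC_MOTIFS[name]))
        offset += spacing
    last_off, last_motif = layout[-1]
    if last_off + len(last_motif) > protein_length:
        raise ValueError("protein_length too small to host the motif library")
    return layout


def _family_ancestor(
    protein_length: int, rng: np.random.Generator
) -> tuple[str, frozenset[int]]:
    protein = list(
        "".join(_AMINO_ACIDS[i] for i in rng.integers(0, 20, size=protein_length))
    )
    protected: set[int] = set()
    for offset, motif in _motif_layout(protein_length):
        protein[offset : offset + len(motif)] = motif
        protected.update(range(offset, offset + len(motif)))
    return "".join(protein), frozenset(protected)


def _translate_cds(cds: str) -> str:
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def _exon_layout(
    cds_len: int, n_introns: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Split a CDS into exon lengths and draw intron lengths."""
    n_exons = n_introns + 1
    if cds_len < 10 * n_exons:
        raise ValueError("CDS too short for the requested intron count")
    cuts = sorted(
        int(c) for c in rng.choice(
            np.arange(10, cds_len - 9), size=n_introns, replace=False
        )
    )
    # keep exons >= 10 bp by re-drawing rather than clamping
    while any(b - a < 10 for a, b in zip([0] + cuts, cuts + [cds_len])):
        cuts = sorted(
            int(c) for c in rng.choice(
                np.arange(10, cds_len - 9), size=n_introns, replace=False
            )
        )
    exon_lengths = [b - a for a, b in zip([0] + cuts, cuts + [cds_len])]
    intron_lengths = [int(rng.integers(100, 1001)) for _ in range(n_introns)]
    return exon_lengths, intron_lengths


def _gene_span(exon_lengths: Sequence[int], intron_lengths: Sequence[int]) -> int:
    return sum(exon_lengths) + sum(intron_lengths)


def _build_model(
    gene_id: str,
    chromosome: str,
    strand: str,
    start: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
) -> GeneModel:
    exons = []
    pos = start
    for k, elen in enumerate(exon_lengths):
        exons.append((pos, pos + elen - 1))
        if k < len(intron_lengths):
            pos += elen + intron_lengths[k]
        else:
            pos += elen
    return GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        start=start,
        end=exons[-1][1],
        exons=tuple(exons),
        mrna_id=f"{gene_id}.t1",
    )


class _Placer:
    """Non-overlapping interval placement with rejection sampling."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {
            f"chr{i+1}": [] for i in range(config.n_chromosomes)
        }
        self.family_positions: dict[str, list[tuple[int, int]]] = {
            c: [] for c in self.occupied
        }

    def _fits(self, chrom: str, start: int, end: int, margin: int = 2000) -> bool:
        if end > self.config.chromosome_length:
            return False
        return all(
            end + margin < s or start - margin > e
            for s, e in self.occupied[chrom]
        )

    def reserve(self, chrom: str, start: int, end: int, family: bool) -> None:
        self.occupied[chrom].append((start, end))
        if family:
            self.family_positions[chrom].append((start, end))

    def place(
        self,
        span: int,
        family: bool,
        chrom: Optional[str] = None,
        exclude_chroms: Sequence[str] = (),
        family_margin: int = 60_000,
        max_tries: int = 2000,
    ) -> tuple[str, int]:
        chroms = sorted(set(self.occupied) - set(exclude_chroms))
        if span + 1 >= self.config.chromosome_length:
            raise ValueError(
                "could not place gene: chromosomes are over capacity for this config"
            )
        for _ in range(max_tries):
            c = chrom or chroms[self.rng.integers(0, len(chroms))]
            start = int(self.rng.integers(1, self.config.chromosome_length - span))
            end = start + span - 1
            if not self._fits(c, start, end):
                continue
            if family and any(
                not (end + family_margin < s or start - family_margin > e)
                for s, e in self.family_positions[c]
            ):
                continue
            self.reserve(c, start, end, family)
            return c, start
        raise ValueError(
            "could not place gene: chromosomes are over capacity for this config"
        )


def generate_family_genome(
    config: SimConfig,
) -> tuple[SeqRecordSet, SeqRecordSet, list[GeneModel], ExpressionMatrix, GroundTruth]:
    """Generate CDS, proteins, gene models, expression and ground truth.

    Family members descend from one ancestral gene carrying all four
    catalytic motifs; planted pairs split from a pair ancestor and each
    lineage accumulates half the target synonymous divergence. Remaining
    family members diverge at ``background_ks`` so they stay well below
    the duplicate-calling identity threshold. Decoys share nothing with
    the family and contain no motif even at one mismatch.
    """
    rng = np.random.default_rng(config.seed)
    anc_protein, protected = _family_ancestor(config.protein_length, rng)
    anc_cds = _back_translate(anc_protein, rng)

    family_cds: dict[str, str] = {}
    pairs: list[PlantedPair] = []
    gene_counter = 0

    def next_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter}"

    for pair_type, omega, target_ks in config.planted_pairs:
        pair_anc, _, _ = _evolve(
            anc_cds, config.background_omega, config.background_ks / 2.0,
            rng, protected,
        )
        s_pair_anc = _synonymous_sites(pair_anc)
        cds_a, syn_a, non_a = _evolve(pair_anc, omega, target_ks / 2.0, rng, protected)
        cds_b, syn_b, non_b = _evolve(pair_anc, omega, target_ks / 2.0, rng, protected)
        id_a, id_b = next_id(), next_id()
        family_cds[id_a] = cds_a
        family_cds[id_b] = cds_b
        pairs.append(
            PlantedPair(
                gene_a=id_a,
                gene_b=id_b,
                pair_type=pair_type,
                omega=omega,
                target_ks=target_ks,
                realized_ks=(syn_a + syn_b) / s_pair_anc,
                syn_events=syn_a + syn_b,
                nonsyn_events=non_a + non_b,
            )
        )
    for _ in range(config.n_family_genes - 2 * len(config.planted_pairs)):
        cds, _, _ = _evolve(
            anc_cds, config.background_omega, config.background_ks, rng, protected
        )
        family_cds[next_id()] = cds

    decoy_cds: dict[str, str] = {}
    for k in range(config.n_decoys):
        protein = _random_decoy_protein(config.protein_length, rng)
        decoy_cds[f"d{k+1}"] = _back_translate(protein, rng)

    # --- placement ---------------------------------------------------------
    placer = _Placer(config, rng)
    models: dict[str, GeneModel] = {}
    layouts = {
        gid: _exon_layout(len(cds), config.intron_count_per_gene, rng)
        for gid, cds in {**family_cds, **decoy_cds}.items()
    }

    pair_members = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    for pair in pairs:
        exo_a, intr_a = layouts[pair.gene_a]
        exo_b, intr_b = layouts[pair.gene_b]
        span_a = _gene_span(exo_a, intr_a)
        span_b = _gene_span(exo_b, intr_b)
        if pair.pair_type == "tandem":
            gap = int(rng.integers(2000, 20001))
            chrom, start_a = placer.place(span_a + gap + span_b, family=True)
            start_b = start_a + span_a + gap
        else:
            chrom, start_a = placer.place(span_a, family=True)
            chrom_b, start_b = placer.place(
                span_b, family=True, exclude_chroms=[chrom]
            )
        strand_a = "+-"[rng.integers(0, 2)]
        strand_b = "+-"[rng.integers(0, 2)]
        models[pair.gene_a] = _build_model(
            pair.gene_a, chrom, strand_a, start_a, exo_a, intr_a
        )
        if pair.pair_type == "tandem":
            models[pair.gene_b] = _build_model(
                pair.gene_b, chrom, strand_b, start_b, exo_b, intr_b
            )
        else:
            models[pair.gene_b] = _build_model(
                pair.gene_b, chrom_b, strand_b, start_b, exo_b, intr_b
            )
    for gid in family_cds:
        if gid in pair_members:
            continue
        exo, intr = layouts[gid]
        chrom, start = placer.place(_gene_span(exo, intr), family=True)
        models[gid] = _build_model(
            gid, chrom, "+-"[rng.integers(0, 2)], start, exo, intr
        )
    for gid in decoy_cds:
        exo, intr = layouts[gid]
        chrom, start = placer.place(_gene_span(exo, intr), family=False)
        models[gid] = _build_model(
            gid, chrom, "+-"[rng.integers(0, 2)], start, exo, intr
        )

    # --- assemble outputs --------------------------------------------------
    all_cds = {**family_cds, **decoy_cds}
    cds_set = SeqRecordSet(
        [SeqRecord(gid, cds) for gid, cds in all_cds.items()], coding=True
    )
    protein_set = SeqRecordSet(
        [SeqRecord(gid, _translate_cds(cds)) for gid, cds in all_cds.items()]
    )
    gene_models = sorted(
        models.values(),
        key=lambda m: (_chrom_key(m.chromosome), m.start),
    )

    family_ids = list(family_cds)
    n_fam = len(family_ids)
    size_a = (n_fam + 1) // 2
    base = np.linspace(9.0, 1.0, config.n_tissues)
    expr, labels = simulate_expression_matrix(
        n_genes=n_fam,
        n_tissues=config.n_tissues,
        clusters=[(size_a, base), (n_fam - size_a, base[::-1])],
        noise_sd=config.noise_sd,
        seed=rng,
        gene_ids=family_ids,
    )
    truth = GroundTruth(
        family_member_ids=family_ids,
        decoy_ids=list(decoy_cds),
        duplicate_pairs=pairs,
        expression_clusters=dict(zip(family_ids, labels)),
        ancestor_protein=anc_protein,
    )
    return cds_set, protein_set, gene_models, expr, truth


def _chrom_key(chrom: str) -> tuple:
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (int(digits) if digits else 10**9, chrom)
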