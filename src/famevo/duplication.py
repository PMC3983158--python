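"""Duplicate-pair calling and tandem/segmental classification.

A gene pair is a duplication event when its global CDS alignment covers
more than 80% of the longer gene and more than 80% of the aligned columns
are identical (both strict inequalities). Located events are classified
tandem when the genes sit on the same chromosome within ``tandem_max_gap``
base pairs with at most ``max_intervening`` annotated genes between them;
every other qualifying pair is segmental. The tandem parameters are this
package's operationalization (a common convention) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

from .align import PairAlignment, Scoring, global_align
from .io import GeneModel, SeqRecordSet

__all__ = [
    "DuplicationEvent",
    "global_align_cds",
    "coverage_identity",
    "call_duplications",
    "classify_duplication",
    "chromosome_map",
    "DEFAULT_TANDEM_MAX_GAP",
    "DEFAULT_MAX_INTERVENING",
]

DEFAULT_TANDEM_MAX_GAP = 50_000
DEFAULT_MAX_INTERVENING = 1


@dataclass(frozen=True)
class DuplicationEvent:
    """One qualifying duplicate gene pair."""

    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    dup_type: Optional[str] = None  # tandem | segmental, once located
    cluster: Optional[int] = None  # connected-component id among events


def global_align_cds(
    cds_a: str, cds_b: str, scoring: Optional[Scoring] = None
) -> PairAlignment:
    """Optimal global alignment of two CDS (nucleotide scoring)."""
    return global_align(cds_a, cds_b, scoring or Scoring.nucleotide())


def coverage_identity(
    aln: PairAlignment, len_a: int, len_b: int
) -> tuple[float, Optional[float]]:
    """Coverage of the longer gene and identity of the aligned regions.

    coverage = aligned_columns / max(len_a, len_b);
    identity = matches / aligned_columns (None when nothing aligned).
    """
    if aln.aligned_columns == 0:
        return 0.0, None
    coverage = aln.aligned_columns / max(len_a, len_b)
    identity = aln.matches / aln.aligned_columns
    return coverage, identity


def call_duplications(
    family: SeqRecordSet,
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
    scoring: Optional[Scoring] = None,
) -> list[DuplicationEvent]:
    """Test all unordered pairs; each qualifying pair is one event.

    Events in the same connected component (multi-member clusters of
    mutually similar genes) share a ``cluster`` id.
    """
    if len(family) < 2:
        raise ValueError("duplicate calling requires >= 2 family members")
    events = []
    for rec_a, rec_b in combinations(family, 2):
        aln = global_align_cds(rec_a.residues, rec_b.residues, scoring)
        coverage, identity = coverage_identity(
            aln, len(rec_a.residues), len(rec_b.residues)
        )
        if identity is None:
            continue
        if coverage > min_coverage and identity > min_identity:
            events.append(
                DuplicationEvent(
                    gene_a=rec_a.id,
                    gene_b=rec_b.id,
                    coverage=coverage,
                    identity=identity,
                )
            )
    return _annotate_clusters(events)


def _annotate_clusters(events: list[DuplicationEvent]) -> list[DuplicationEvent]:
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ev in events:
        ra, rb = find(ev.gene_a), find(ev.gene_b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots: dict[str, int] = {}
    out = []
    for ev in events:
        root = find(ev.gene_a)
        if root not in roots:
            roots[root] = len(roots)
        out.append(replace(ev, cluster=roots[root]))
    return out


def classify_duplication(
    event: DuplicationEvent,
    gene_models: Sequence[GeneModel],
    tandem_max_gap: int = DEFAULT_TANDEM_MAX_GAP,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> DuplicationEvent:
    """Type an event: tandem iff same chromosome, gap <= ``tandem_max_gap``
    and at most ``max_intervening`` annotated genes in between."""
    by_gene = {m.gene_id: m for m in gene_models}
    by_gene.update({m.mrna_id: m for m in gene_models})
    try:
        ma, mb = by_gene[event.gene_a], by_gene[event.gene_b]
    except KeyError as exc:
        raise ValueError(f"unlocated gene in event: {exc.args[0]!r}") from exc
    if ma.chromosome != mb.chromosome:
        return replace(event, dup_type="segmental")
    left, right = (ma, mb) if ma.start <= mb.start else (mb, ma)
    gap = max(0, right.start - left.end - 1)
    if gap > tandem_max_gap:
        return replace(event, dup_type="segmental")
    intervening = sum(
        1
        for m in gene_models
        if m.chromosome == ma.chromosome
        and m.gene_id not in (ma.gene_id, mb.gene_id)
        and m.start > left.end
        and m.end < right.start
    )
    dup_type = "tandem" if intervening <= max_intervening else "segmental"
    return replace(event, dup_type=dup_type)


def _chrom_key(chrom: str) -> tuple:
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (int(digits) if digits else 10**9, chrom)


def chromosome_map(
    gene_models: Sequence[GeneModel],
    names: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Tabular chromosome map: genes grouped by chromosome, sorted by start."""
    names = names or {}
    rows = sorted(gene_models, key=lambda m: (_chrom_key(m.chromosome), m.start))
    return pd.DataFrame(
        {
            "chromosome": [m.chromosome for m in rows],
            "name": [names.get(m.gene_id, m.gene_id) for m in rows],
            "start": [m.start for m in rows],
            "end": [m.end for m in rows],
            "strand": [m.strand for m in rows],
        }
    )
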