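"""Exon/intron statistics per gene and family-level summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import GeneModel

__all__ = ["StructureRecord", "intron_stats", "structure_track"]


@dataclass(frozen=True)
class StructureRecord:
    gene_id: str
    intron_count: int
    exon_lengths: tuple[int, ...]
    total_cds_span: int


def intron_stats(
    gene_models: Sequence[GeneModel],
) -> tuple[list[StructureRecord], dict]:
    """Per-gene intron counts plus a family summary.

    The summary reports min, max, modal intron count and the modal
    fraction (ties on the mode broken toward the smaller count). An empty
    input yields an empty record list and a summary flagged ``empty``.
    """
    records = []
    for m in gene_models:
        exon_lengths = tuple(e - s + 1 for s, e in m.exons)
        records.append(
            StructureRecord(
                gene_id=m.gene_id,
                intron_count=m.intron_count,
                exon_lengths=exon_lengths,
                total_cds_span=sum(exon_lengths),
            )
        )
    if not records:
        return records, {"empty": True}
    counts = pd.Series([r.intron_count for r in records])
    mode = int(counts.value_counts().sort_index().idxmax())
    summary = {
        "empty": False,
        "n_genes": len(records),
        "min_introns": int(counts.min()),
        "max_introns": int(counts.max()),
        "modal_introns": mode,
        "modal_fraction": float((counts == mode).mean()),
    }
    return records, summary


def structure_track(model: GeneModel) -> list[tuple[str, int, int]]:
    """Alternating exon/intron segments as (kind, relative_start, length).

    Relative starts are 0-based offsets from the gene start; segment
    lengths sum to the gene span.
    """
    segments: list[tuple[str, int, int]] = []
    prev_end: Optional[int] = None
    for s, e in model.exons:
        if prev_end is not None:
            segments.append(("intron", prev_end - model.start + 1, s - prev_end - 1))
        segments.append(("exon", s - model.start, e - s + 1))
        prev_end = e
    return segments
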