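"""Conserved-motif scanning, architecture tables and logo information.

The motif library defaults to the four catalytic consensus motifs of plant
HMG-CoA reductase: two HMG-CoA binding motifs (EMPVGYVQIP, TTEGCLVA) and
two NADP(H) binding motifs (DAMGMNM, GTVGGGT). Scanning is exhaustive
Hamming-window matching — the downstream use is presence/absence of these
short, highly conserved blocks, for which consensus scanning suffices.
Sequence-logo conservation is the classical per-column information content
in bits, log2(20) + sum_a p_a log2 p_a, without small-sample correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import SeqRecordSet

__all__ = [
    "CATALYTIC_MOTIFS",
    "MotifHit",
    "LogoColumn",
    "scan_motif",
    "architecture_table",
    "column_information",
]

#: the four catalytic-domain consensus motifs (name -> consensus)
CATALYTIC_MOTIFS: dict[str, str] = {
    "HMG-CoA-1": "EMPVGYVQIP",
    "HMG-CoA-2": "TTEGCLVA",
    "NADPH-1": "DAMGMNM",
    "NADPH-2": "GTVGGGT",
}


@dataclass(frozen=True)
class MotifHit:
    """One window of a protein matching a consensus motif."""

    motif_name: str
    consensus: str
    start: int  # 0-based offset in the protein
    mismatches: int


@dataclass(frozen=True)
class LogoColumn:
    """Residue frequencies and information content of one alignment column."""

    position: int
    frequencies: Mapping[str, float]
    information: float


def scan_motif(
    protein: str,
    consensus: str,
    max_mismatch: int = 0,
    motif_name: Optional[str] = None,
) -> list[MotifHit]:
    """All windows of ``protein`` within ``max_mismatch`` Hamming distance
    of ``consensus``, sorted by start offset.

    A consensus longer than the protein yields an empty list.
    """
    if len(consensus) < 4:
        raise ValueError("consensus must be at least 4 residues long")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    name = motif_name if motif_name is not None else consensus
    k = len(consensus)
    hits = []
    for start in range(len(protein) - k + 1):
        window = protein[start : start + k]
        mismatches = sum(1 for a, b in zip(window, consensus) if a != b)
        if mismatches <= max_mismatch:
            hits.append(
                MotifHit(
                    motif_name=name,
                    consensus=consensus,
                    start=start,
                    mismatches=mismatches,
                )
            )
    return hits


def architecture_table(
    proteins: SeqRecordSet,
    motif_library: Mapping[str, str] | None = None,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Presence/absence matrix (proteins x motifs): 1 iff >= 1 hit."""
    library = dict(motif_library) if motif_library else dict(CATALYTIC_MOTIFS)
    if not library:
        raise ValueError("motif library is empty")
    rows = {}
    for rec in proteins:
        rows[rec.id] = {
            name: int(bool(scan_motif(rec.residues, consensus, max_mismatch, name)))
            for name, consensus in library.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(library))


def column_information(columns: Sequence[Sequence[str]]) -> list[LogoColumn]:
    """Information content per alignment column, gaps excluded.

    A column that is empty after gap removal has undefined information and
    raises ``ValueError`` (flagged rather than silently zeroed).
    """
    out = []
    max_bits = math.log2(20)
    for pos, column in enumerate(columns):
        residues = [r for r in column if r != "-"]
        if not residues:
            raise ValueError(f"column {pos} is all-gap: information undefined")
        freqs: dict[str, float] = {}
        for r in residues:
            freqs[r] = freqs.get(r, 0.0) + 1.0
        total = float(len(residues))
        freqs = {r: c / total for r, c in freqs.items()}
        entropy = -sum(p * math.log2(p) for p in freqs.values())
        info = max(0.0, max_bits - entropy)
        out.append(LogoColumn(position=pos, frequencies=freqs, information=info))
    return out
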