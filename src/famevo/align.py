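"""Pairwise sequence alignment with affine gap penalties.

Exact dynamic-programming alignment (Smith-Waterman local, Needleman-Wunsch
global) computed by :class:`Bio.Align.PairwiseAligner`; this module adapts it
to the pipeline's :class:`PairAlignment` quantities (aligned columns of the
two sequences, match count, coverage and identity fractions).

Gap convention: a gap of length k costs ``gap_open + (k - 1) * gap_extend``
(both scores are negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["Scoring", "PairAlignment", "local_align", "global_align"]

_NUCLEOTIDES = set("ACGT")


@dataclass(frozen=True)
class Scoring:
    """Substitution scoring plus affine gap penalties.

    Either a named substitution matrix (``matrix``, e.g. ``"BLOSUM62"``) or
    flat ``match``/``mismatch`` scores.
    """

    matrix: Optional[str] = None
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -11.0
    gap_extend: float = -1.0

    @staticmethod
    def protein(gap_open: float = -11.0, gap_extend: float = -1.0) -> "Scoring":
        return Scoring(matrix="BLOSUM62", gap_open=gap_open, gap_extend=gap_extend)

    @staticmethod
    def nucleotide(
        match: float = 2.0,
        mismatch: float = -3.0,
        gap_open: float = -5.0,
        gap_extend: float = -2.0,
    ) -> "Scoring":
        return Scoring(
            matrix=None, match=match, mismatch=mismatch,
            gap_open=gap_open, gap_extend=gap_extend,
        )

    def make_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        # end gaps penalized like internal ones (global mode), so coverage
        # of the longer gene stays well defined
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass(frozen=True)
class PairAlignment:
    """Two gapped sequences of equal length with summary quantities.

    ``aligned_columns`` counts columns where both sequences are ungapped;
    ``matches`` counts those columns with identical residues.
    """

    aligned_a: str
    aligned_b: str
    score: float
    aligned_columns: int
    matches: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences must have equal length")
        if self.matches > self.aligned_columns:
            raise ValueError("matches cannot exceed aligned columns")

    @staticmethod
    def from_gapped(aligned_a: str, aligned_b: str, score: float) -> "PairAlignment":
        cols = 0
        matches = 0
        for x, y in zip(aligned_a, aligned_b):
            if x != "-" and y != "-":
                cols += 1
                if x == y:
                    matches += 1
        return PairAlignment(aligned_a, aligned_b, score, cols, matches)


def _align(a: str, b: str, scoring: Scoring, mode: str) -> PairAlignment:
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = scoring.make_aligner(mode)
    result = aligner.align(a, b)
    best = result[0]  # deterministic first optimal traceback
    return PairAlignment.from_gapped(str(best[0]), str(best[1]), best.score)


def local_align(query: str, target: str, scoring: Scoring | None = None) -> PairAlignment:
    """Optimal local (Smith-Waterman) alignment; default BLOSUM62 scoring."""
    return _align(query, target, scoring or Scoring.protein(), "local")


def local_score(query: str, target: str, scoring: Scoring | None = None) -> float:
    """Optimal local alignment score without traceback (fast path)."""
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    aligner = (scoring or Scoring.protein()).make_aligner("local")
    return float(aligner.score(query, target))


def global_align(a: str, b: str, scoring: Scoring | None = None) -> PairAlignment:
    """Optimal global (Needleman-Wunsch) alignment of two nucleotide CDS."""
    scoring = scoring or Scoring.nucleotide()
    if scoring.matrix is None:
        for seq, name in ((a, "first"), (b, "second")):
            bad = set(seq) - _NUCLEOTIDES
            if bad:
                raise ValueError(
                    f"non-nucleotide symbol(s) {sorted(bad)} in {name} sequence"
                )
    return _align(a, b, scoring, "global")
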