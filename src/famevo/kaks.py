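"""Nei-Gojobori Ka/Ks estimation, selection classification and Ks dating.

The estimator is the classical counting method: fractional synonymous (S)
and nonsynonymous (N) site totals per sequence (averaged over the pair),
pathway-averaged synonymous/nonsynonymous difference counts per codon
column, proportions pS = sd/S and pN = nd/N, and the Jukes-Cantor
multiple-hit correction d = -(3/4) ln(1 - (4/3) p) applied to each
proportion. Divergence times come from the synonymous molecular clock
T = Ks / (2 lambda), with lambda the per-site per-year synonymous rate.

Conventions (standard for this estimator):

* site counting enumerates the 9 single-nucleotide neighbors of each codon;
  changes producing a stop codon are excluded, so such codons contribute
  fewer than 3 sites in total;
* differences between two codons are averaged over all minimal mutational
  pathways, weighting the stop-free pathways equally and discarding
  pathways that traverse a stop codon;
* a codon column whose every pathway traverses a stop is excluded entirely
  and counted in ``KaKsResult.flags``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Optional, Sequence

from Bio.Data import CodonTable

from .align import PairAlignment

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "codon_align",
    "count_sites",
    "count_differences",
    "nei_gojobori",
    "jukes_cantor",
    "classify_selection",
    "divergence_time",
    "SENSE_CODONS",
    "STOP_CODONS",
    "translate_codon",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon under the standard genetic code."""
    return _TABLE.forward_table[codon]


def translate_cds(cds: str) -> str:
    """Translate a stop-free CDS (length divisible by 3)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class CodonAlignment:
    """Paired codon columns: two gap-free, stop-free sense codons each."""

    columns: tuple[tuple[str, str], ...]
    dropped_columns: int = 0

    def __post_init__(self) -> None:
        for a, b in self.columns:
            for codon in (a, b):
                if len(codon) != 3 or set(codon) - set(_BASES):
                    raise ValueError(f"not an unambiguous codon: {codon!r}")
                if codon in STOP_CODONS:
                    raise ValueError(f"stop codon {codon!r} in codon alignment")

    @property
    def n_codons(self) -> int:
        return len(self.columns)


@dataclass
class KaKsResult:
    """Nei-Gojobori estimates for one gene pair."""

    S: float
    N: float
    sd: float
    nd: float
    pS: Optional[float]
    pN: Optional[float]
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    selection_class: str
    T_mya: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def codon_align(
    protein_aln: tuple[str, str], cds_a: str, cds_b: str
) -> CodonAlignment:
    """Back-translate a pairwise protein alignment onto the two CDS.

    Protein gap columns are removed; codon columns containing ambiguity
    codes or stop codons are dropped (their number is recorded). The CDS
    must translate exactly to the ungapped proteins.
    """
    row_a, row_b = protein_aln
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows differ in length")
    for cds, row, label in ((cds_a, row_a, "a"), (cds_b, row_b, "b")):
        if len(cds) % 3 != 0:
            raise ValueError(f"cds_{label} length not divisible by 3")
        ungapped = row.replace("-", "")
        n_codons = len(cds) // 3
        if len(ungapped) != n_codons:
            raise ValueError(
                f"cds_{label} has {n_codons} codons but protein has "
                f"{len(ungapped)} residues"
            )
        for k in range(n_codons):
            codon = cds[3 * k : 3 * k + 3]
            if set(codon) <= set(_BASES) and codon not in STOP_CODONS:
                aa = translate_codon(codon)
                if aa != ungapped[k]:
                    raise ValueError(
                        f"cds_{label} codon {k} ({codon}) translates to {aa}, "
                        f"protein has {ungapped[k]}"
                    )
    columns = []
    dropped = 0
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if x != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            continue
        ok = all(
            set(c) <= set(_BASES) and c not in STOP_CODONS
            for c in (codon_a, codon_b)
        )
        if ok:
            columns.append((codon_a, codon_b))
        else:
            dropped += 1
    return CodonAlignment(tuple(columns), dropped_columns=dropped)


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous sites of one sense codon.

    Each of the 9 single-nucleotide neighbors contributes weight 1/3 to s
    (synonymous) or n (nonsynonymous); neighbors that are stop codons
    contribute nothing, so s + n < 3 for codons with stop neighbors.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    aa = translate_codon(codon)
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if translate_codon(mutant) == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> Optional[tuple[float, float]]:
    """Pathway-averaged synonymous/nonsynonymous differences between two
    sense codons; ``None`` when every minimal pathway traverses a stop."""
    for codon in (codon_a, codon_b):
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon!r} in difference count")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathway_counts = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if translate_codon(nxt) == translate_codon(current):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if valid:
            pathway_counts.append((sd, nd))
    if not pathway_counts:
        return None
    k = len(pathway_counts)
    return (
        sum(p[0] for p in pathway_counts) / k,
        sum(p[1] for p in pathway_counts) / k,
    )


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; ``None`` (saturated) when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def nei_gojobori(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori proportions with Jukes-Cantor correction for one pair."""
    if aln.n_codons == 0:
        raise ValueError("empty codon alignment")
    flags: list[str] = []
    S_a = N_a = S_b = N_b = 0.0
    sd_total = nd_total = 0.0
    excluded = 0
    for codon_a, codon_b in aln.columns:
        diffs = count_differences(codon_a, codon_b)
        if diffs is None:
            excluded += 1
            continue
        sa, na = count_sites(codon_a)
        sb, nb = count_sites(codon_b)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd_total += diffs[0]
        nd_total += diffs[1]
    if excluded:
        flags.append(f"excluded_columns:{excluded}")
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    if S == 0 or N == 0:
        raise ValueError("alignment yields zero synonymous or nonsynonymous sites")
    pS = sd_total / S
    pN = nd_total / N
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    if Ks is None:
        flags.append("Ks_saturated")
    if Ka is None:
        flags.append("Ka_saturated")
    ratio: Optional[float] = None
    if Ka is not None and Ks is not None:
        if Ks > 0:
            ratio = Ka / Ks
        else:
            flags.append("ratio_undefined_Ks_zero")
    selection = classify_selection(ratio)
    return KaKsResult(
        S=S, N=N, sd=sd_total, nd=nd_total, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, ratio=ratio, selection_class=selection, flags=flags,
    )


def classify_selection(ratio: Optional[float], tol: float = 1e-6) -> str:
    """Selection regime from Ka/Ks: >1 positive (accelerated evolution),
    =1 neutral, <1 purifying (functional constraint)."""
    if ratio is None:
        return "undetermined"
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


#: synonymous substitutions per site per year, per species code
DEFAULT_LAMBDAS: dict[str, float] = {
    "Zm": 6.5e-9,  # Zea mays
    "Pt": 9.1e-9,  # Populus trichocarpa
    "Gm": 6.1e-9,  # Glycine max
}


def divergence_time(ks: float, lam: float) -> float:
    """Age of a duplication in Mya via the synonymous clock T = Ks / (2 lambda)."""
    if lam <= 0:
        raise ValueError("substitution rate lambda must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * lam) * 1e-6


def analyze_pair(
    cds_a: str,
    cds_b: str,
    species_code: Optional[str] = None,
    lambdas: Optional[Mapping[str, float]] = None,
) -> KaKsResult:
    """Full Ka/Ks analysis of one duplicate pair from raw CDS.

    Globally aligns the translated proteins (BLOSUM62), back-translates
    onto the CDS, runs the Nei-Gojobori estimator, and dates the pair
    when a clock rate is known for ``species_code``.
    """
    from .align import Scoring, global_align

    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aln = global_align(prot_a, prot_b, Scoring.protein())
    codon_aln = codon_align((aln.aligned_a, aln.aligned_b), cds_a, cds_b)
    result = nei_gojobori(codon_aln)
    table = dict(lambdas) if lambdas is not None else DEFAULT_LAMBDAS
    if species_code in table and result.Ks is not None:
        result.T_mya = divergence_time(result.Ks, table[species_code])
    return result
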