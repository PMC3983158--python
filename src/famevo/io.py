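"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: GFF3 coordinates are 1-based inclusive (the format's
dialect); all internal arithmetic uses 0-based half-open intervals, and the
conversion happens only at this I/O boundary via :func:`to_half_open` /
:func:`from_half_open`.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .tree import read_newick, write_newick  # noqa: F401  (tree I/O lives here too)

__all__ = [
    "read_newick",
    "write_newick",
    "SeqRecord",
    "SeqRecordSet",
    "GeneModel",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_expression_tsv",
    "write_expression_tsv",
    "to_half_open",
    "from_half_open",
]


def to_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GFF3) -> 0-based half-open."""
    return start - 1, end


def from_half_open(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GFF3)."""
    return start0 + 1, end0


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with an optional species tag."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)


class SeqRecordSet:
    """An ordered set of uniquely named protein or nucleotide sequences.

    Parameters
    ----------
    records:
        Sequence records; ids must be unique within the set.
    coding:
        If true, every sequence is validated to have length divisible by 3.
    """

    def __init__(self, records: Sequence[SeqRecord], coding: bool = False):
        self.records: list[SeqRecord] = list(records)
        self.coding = coding
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            if coding and len(rec.residues) % 3 != 0:
                raise ValueError(
                    f"coding sequence {rec.id!r} has length {len(rec.residues)} "
                    "not divisible by 3"
                )
        self._index = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __getitem__(self, rec_id: str) -> SeqRecord:
        return self._index[rec_id]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def subset(self, ids: Sequence[str]) -> "SeqRecordSet":
        return SeqRecordSet([self._index[i] for i in ids], coding=self.coding)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SeqRecordSet):
            return NotImplemented
        return self.records == other.records


@dataclass(frozen=True)
class GeneModel:
    """A located gene: one mRNA with its exon chain.

    Coordinates are 1-based inclusive; exons are stored in ascending
    coordinate order regardless of strand (biological order is derived on
    demand for minus-strand genes).
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    mrna_id: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start {s} > end {e}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons overlap or are unsorted at ({s},{e})"
                )
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model requires >= 1 exon")

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def exons_biological(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (reversed for minus strand)."""
        return self.exons if self.strand == "+" else self.exons[::-1]


class ExpressionMatrix:
    """Non-negative expression values, genes x tissues."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        tissue_labels: Sequence[str],
        values: np.ndarray,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(tissue_labels)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(tissue_labels)} tissues"
            )
        if any(not g for g in gene_ids) or any(not t for t in tissue_labels):
            raise ValueError("gene and tissue labels must be non-empty")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")
        self.gene_ids = list(gene_ids)
        self.tissue_labels = list(tissue_labels)
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.tissue_labels
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species: str = "", coding: bool = False) -> SeqRecordSet:
    """Read a FASTA file into a :class:`SeqRecordSet`.

    Record ids are the token before the first whitespace in the header;
    residues are upper-cased with whitespace stripped. Duplicate ids and
    empty files raise ``ValueError``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(id=rec.id, residues=str(rec.seq).upper(), species=species)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SeqRecordSet(records, coding=coding)


def write_fasta(seqs: SeqRecordSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute field: {part!r}")
        key, val = part.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/exon features into gene models.

    One :class:`GeneModel` per mRNA. Exons attach to their mRNA via the
    ``Parent`` attribute; an exon without a Parent, or any feature with
    end < start, is an error.
    """
    mrnas: dict[str, dict] = {}
    exon_rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} < start {start}"
                )
            attr = _parse_attributes(attrs)
            if ftype == "mRNA":
                parent = attr.get("Parent", attr.get("ID", ""))
                mrnas[attr["ID"]] = {
                    "gene_id": parent,
                    "chromosome": seqid,
                    "strand": strand,
                    "start": start,
                    "end": end,
                }
            elif ftype == "exon":
                if "Parent" not in attr:
                    raise ValueError(
                        f"{path}:{lineno}: exon feature lacks a Parent attribute"
                    )
                for parent in attr["Parent"].split(","):
                    exon_rows.append((parent, start, end))
    exons_by_mrna: dict[str, list[tuple[int, int]]] = {m: [] for m in mrnas}
    for parent, start, end in exon_rows:
        if parent not in exons_by_mrna:
            raise ValueError(f"exon Parent {parent!r} is not a known mRNA")
        exons_by_mrna[parent].append((start, end))
    models = []
    for mrna_id, info in mrnas.items():
        exons = tuple(sorted(exons_by_mrna[mrna_id]))
        models.append(
            GeneModel(
                gene_id=info["gene_id"],
                chromosome=info["chromosome"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                exons=exons,
                mrna_id=mrna_id,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/exon GFF3 features."""
    buf = _stdio.StringIO()
    buf.write("##gff-version 3\n")
    for m in models:
        attrs_gene = f"ID={m.gene_id}"
        buf.write(
            "\t".join(
                [m.chromosome, "famevo", "gene", str(m.start), str(m.end),
                 ".", m.strand, ".", attrs_gene]
            )
            + "\n"
        )
        buf.write(
            "\t".join(
                [m.chromosome, "famevo", "mRNA", str(m.start), str(m.end),
                 ".", m.strand, ".", f"ID={m.mrna_id};Parent={m.gene_id}"]
            )
            + "\n"
        )
        for k, (s, e) in enumerate(m.exons, 1):
            buf.write(
                "\t".join(
                    [m.chromosome, "famevo", "exon", str(s), str(e),
                     ".", m.strand, ".",
                     f"ID={m.mrna_id}.exon{k};Parent={m.mrna_id}"]
                )
                + "\n"
            )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read genes x tissues TSV (first column gene id, header tissues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        tissue_labels=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")
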