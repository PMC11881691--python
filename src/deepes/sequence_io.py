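"""Ordered protein FASTA input and sequence admissibility filtering.

Genomes arrive as protein FASTA files whose record order encodes gene order
along the genome (the usual shape of a MAG protein catalogue).  Each record
becomes a :class:`GeneRecord` carrying its rank — its position in the gene
order of its contig — which downstream window sliding relies on.

Sequences longer than 4000 residues or containing the ambiguity code "J"
(leucine-or-isoleucine) are inadmissible for embedding and are removed by
:func:`filter_admissible`; the ranks of surviving genes are *not* renumbered,
so a removed gene leaves a gap and windows still reflect genomic adjacency.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "GenomeTable",
    "Rejection",
    "EmptyFastaError",
    "DuplicateGeneIdError",
    "read_ordered_fasta",
    "read_gene_order_tsv",
    "filter_admissible",
    "write_fasta",
    "write_rejection_report",
    "contig_from_token",
    "DEFAULT_MAX_LEN",
    "DEFAULT_FORBIDDEN",
]

DEFAULT_MAX_LEN = 4000
DEFAULT_FORBIDDEN = frozenset({"J"})


class EmptyFastaError(ValueError):
    """Raised when a FASTA input contains no records."""


class DuplicateGeneIdError(ValueError):
    """Raised when a gene identifier appears more than once in a genome."""


@dataclass(frozen=True)
class GeneRecord:
    """One ordered gene: identifier, location in the gene order, and sequence."""

    gene_id: str
    genome_id: str
    contig_id: str
    rank: int
    sequence: str

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError(f"rank must be non-negative, got {self.rank}")
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")


@dataclass
class GenomeTable:
    """Ordered genes of one genome, grouped by contig in input order."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def genes(self) -> Iterator[GeneRecord]:
        for records in self.contigs.values():
            yield from records

    def __len__(self) -> int:
        return sum(len(r) for r in self.contigs.values())

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes()]

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def contig_from_token(prefix: str = "contig=") -> Callable[[str], str | None]:
    """Header rule extracting the contig id from a ``contig=<id>`` token."""

    def rule(description: str) -> str | None:
        for token in description.split():
            if token.startswith(prefix):
                return token[len(prefix):]
        return None

    return rule


def read_ordered_fasta(
    path: str | Path,
    genome_id: str,
    contig_rule: Callable[[str], str | None] | None = None,
) -> GenomeTable:
    """Read a protein FASTA into a :class:`GenomeTable`, preserving order.

    Parameters
    ----------
    path
        FASTA file of amino-acid sequences; record order encodes gene order.
    genome_id
        Identifier attached to every record.
    contig_rule
        Optional callable mapping a record's description line to a contig id
        (see :func:`contig_from_token`).  When absent, or when the rule
        returns None for a record, all such records land on a single default
        contig named after the genome.

    Sequences are uppercased and a trailing stop symbol ``*`` is stripped.
    Rank is assigned per contig by order of appearance.
    """
    path = Path(path)
    contigs: dict[str, list[GeneRecord]] = {}
    seen: set[str] = set()
    default_contig = f"{genome_id}_contig0"
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise DuplicateGeneIdError(
                f"duplicate gene_id {gene_id!r} in {path.name}"
            )
        seen.add(gene_id)
        contig_id = None
        if contig_rule is not None:
            contig_id = contig_rule(rec.description)
        if contig_id is None:
            contig_id = default_contig
        seq = str(rec.seq).upper().rstrip("*")
        records = contigs.setdefault(contig_id, [])
        records.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=contig_id,
                rank=len(records),
                sequence=seq,
            )
        )
    if not seen:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return GenomeTable(genome_id=genome_id, contigs=contigs)


def read_gene_order_tsv(
    tsv_path: str | Path, fasta_path: str | Path
) -> GenomeTable:
    """Read gene order from an explicit TSV sidecar plus a sequence FASTA.

    TSV columns: genome_id, contig_id, gene_id, rank.  All rows must carry
    the same genome_id; ranks within a contig must be consecutive from 0.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().rstrip("*")
    rows: list[tuple[str, str, str, int]] = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                (row["genome_id"], row["contig_id"], row["gene_id"], int(row["rank"]))
            )
    if not rows:
        raise EmptyFastaError(f"no rows in {tsv_path}")
    genome_ids = {r[0] for r in rows}
    if len(genome_ids) != 1:
        raise ValueError(f"gene-order TSV mixes genomes: {sorted(genome_ids)}")
    genome_id = rows[0][0]
    contigs: dict[str, list[GeneRecord]] = {}
    seen: set[str] = set()
    for _, contig_id, gene_id, rank in sorted(rows, key=lambda r: (r[1], r[3])):
        if gene_id in seen:
            raise DuplicateGeneIdError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        records = contigs.setdefault(contig_id, [])
        if rank != len(records):
            raise ValueError(
                f"ranks on contig {contig_id!r} are not consecutive from 0"
            )
        if gene_id not in seqs:
            raise KeyError(f"gene {gene_id!r} missing from FASTA")
        records.append(
            GeneRecord(gene_id, genome_id, contig_id, rank, seqs[gene_id])
        )
    return GenomeTable(genome_id=genome_id, contigs=contigs)


@dataclass(frozen=True)
class Rejection:
    gene_id: str
    reason: str


def filter_admissible(
    genes: GenomeTable,
    max_len: int = DEFAULT_MAX_LEN,
    forbidden_chars: frozenset[str] | set[str] = DEFAULT_FORBIDDEN,
) -> tuple[GenomeTable, list[Rejection]]:
    """Drop genes the embedder cannot accept; keep ranks (gaps remain).

    A gene survives iff ``len(sequence) <= max_len`` (inclusive boundary:
    only sequences of *more* than ``max_len`` residues are removed) and the
    sequence contains none of ``forbidden_chars``.  Each rejected gene is
    reported with the rule that fired.
    """
    kept: dict[str, list[GeneRecord]] = {}
    rejected: list[Rejection] = []
    for contig_id, records in genes.contigs.items():
        surviving: list[GeneRecord] = []
        for rec in records:
            if len(rec.sequence) > max_len:
                rejected.append(Rejection(rec.gene_id, "length"))
                continue
            bad = sorted(set(rec.sequence) & set(forbidden_chars))
            if bad:
                rejected.append(
                    Rejection(rec.gene_id, f"forbidden character {bad[0]}")
                )
                continue
            surviving.append(rec)
        if surviving:
            kept[contig_id] = surviving
    return GenomeTable(genome_id=genes.genome_id, contigs=kept), rejected


def write_fasta(genes: GenomeTable, path: str | Path) -> None:
    """Write a GenomeTable back to FASTA with ``contig=`` header tokens."""
    records = [
        SeqRecord(
            Seq(g.sequence),
            id=g.gene_id,
            description=f"contig={g.contig_id} rank={g.rank}",
        )
        for g in genes.genes()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_rejection_report(rejected: list[Rejection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "reason"])
        for r in rejected:
            writer.writerow([r.gene_id, r.reason])
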