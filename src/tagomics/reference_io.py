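"""Reference genome and gene-model I/O plus strand-aware interval geometry.

Genomic coordinates are 0-based half-open internally; the GFF3 interface is
1-based inclusive, converted at the boundary. One model per gene_id (a
filtered-model set); alternative transcripts are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeSequence",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "extend_three_prime",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A reference file violates the expected format."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome/scaffold sequence over {A,C,G,T,N}, stored uppercase."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"empty sequence for {self.chrom_id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"invalid characters {sorted(bad)} in sequence {self.chrom_id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware genomic interval carrying a gene identifier.

    ``start``/``end`` are 0-based half-open on the forward axis regardless of
    strand. ``exons`` are non-overlapping, sorted sub-intervals contained in
    [start, end); a model without explicit exons gets a single spanning exon.
    """

    gene_id: str
    chrom_id: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: strand required for tag assignment "
                f"(got {self.strand!r})"
            )
        if not self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start must be < end "
                f"({self.start} >= {self.end})"
            )
        exons = tuple(tuple(e) for e in self.exons) or ((self.start, self.end),)
        prev_end = None
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise FormatError(
                    f"gene {self.gene_id!r}: exon [{s},{e}) outside gene span"
                )
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id!r}: exons overlap or unsorted")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def three_prime_end(self) -> int:
        """Forward-axis coordinate of the 3′ end (end for +, start for −)."""
        return self.end if self.strand == "+" else self.start


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence records, in file order."""
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[GenomeSequence], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene (and optional exon) features from GFF3.

    GFF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention. The ``ID`` attribute of the gene feature is the
    gene_id; exon features are attached via ``Parent``.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # sqlite/attribute parse failures
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    models: list[GeneModel] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        if gene_id in seen:
            raise FormatError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        if gene.strand not in ("+", "-"):
            raise FormatError(
                f"gene {gene_id!r}: strand required for tag assignment "
                f"(got {gene.strand!r})"
            )
        if gene.end < gene.start:
            raise FormatError(f"gene {gene_id!r}: end < start in {path}")
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            if exon.end < exon.start:
                raise FormatError(f"exon of gene {gene_id!r}: end < start in {path}")
            exons.append((exon.start - 1, exon.end))
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom_id=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=tuple(exons),
            )
        )
    return models


def write_gene_models(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Write models as GFF3 gene + exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom_id}\ttagomics\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chrom_id}\ttagomics\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def extend_three_prime(
    models: list[GeneModel],
    length_bp: int,
    genome: list[GenomeSequence],
) -> list[GeneModel]:
    """Extend every model ``length_bp`` into its 3′ UTR, clipped to the chromosome.

    Pure function: the input models are untouched. The extension is appended
    to the 3′-most exon. Extensions are NOT clipped at neighbouring genes;
    overlaps are resolved at assignment time.
    """
    if length_bp < 0:
        raise ValueError("length_bp must be >= 0")
    chrom_len = {g.chrom_id: len(g) for g in genome}
    out: list[GeneModel] = []
    for m in models:
        if m.chrom_id not in chrom_len:
            raise ValueError(f"gene {m.gene_id!r} references unknown chrom {m.chrom_id!r}")
        exons = list(m.exons)
        if m.strand == "+":
            new_end = min(m.end + length_bp, chrom_len[m.chrom_id])
            last = exons[-1]
            exons[-1] = (last[0], max(last[1], new_end))
            out.append(replace(m, end=new_end, exons=tuple(exons)))
        else:
            new_start = max(m.start - length_bp, 0)
            first = exons[0]
            exons[0] = (min(first[0], new_start), first[1])
            out.append(replace(m, start=new_start, exons=tuple(exons)))
    return out
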