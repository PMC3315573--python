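"""Exact tag-to-genome mapping, uniqueness filtering and gene assignment.

Mapping is exact (100% identity, no mismatches) against an index of every
CATG-anchored 21-mer on both genome strands. Tags hitting more than one
location (strand-distinct locations count as distinct) are discarded as
multi-mapped. Uniquely mapped tags are assigned to gene models: sense hits are
pooled per gene, antisense hits are tallied but excluded from gene counts,
hits outside every model are intergenic. Gene models may be extended into the
3' UTR before assignment.
"""

from __future__ import annotations

import bisect
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .reference_io import GeneModel, GenomeSequence
from .tag_extraction import ANCHOR, TAG_LENGTH, reverse_complement, validate_tag

__all__ = [
    "TagLibrary",
    "TagHit",
    "AssignmentReport",
    "CATEGORIES",
    "read_tag_library",
    "write_tag_library",
    "build_tag_index",
    "map_tags",
    "assign_to_genes",
    "mapping_summary",
]

CATEGORIES = (
    "gene_sense",
    "gene_antisense",
    "intergenic",
    "multi_mapped",
    "unmapped",
    "ambiguous",
)


@dataclass
class TagLibrary:
    """A multiset of 21-nt CATG-anchored tags with counts (one sequencing library)."""

    condition_label: str
    entries: dict[str, int]

    def __post_init__(self) -> None:
        for tag, count in self.entries.items():
            if count < 1:
                raise ValueError(f"tag {tag!r}: count {count} < 1")

    @property
    def total_tags(self) -> int:
        return sum(self.entries.values())


@dataclass(frozen=True)
class TagHit:
    """Exact genomic locations of one tag; an empty list means unmapped."""

    tag: str
    locations: tuple[tuple[str, int, str], ...]  # (chrom_id, anchor position, strand)


@dataclass
class AssignmentReport:
    """Per-tag categories and per-gene sense counts for one library.

    Category read tallies partition the library: their sum equals the library
    total. ``ambiguous`` holds equidistant ties between overlapping same-strand
    models (excluded from gene counts, normally zero).
    """

    condition_label: str
    total_reads: int
    utr_extension_bp: int
    read_tally: dict[str, int]
    unique_tag_tally: dict[str, int]
    gene_counts: Counter = field(default_factory=Counter)
    tag_category: dict[str, str] = field(default_factory=dict)
    intergenic_distance: dict[str, int] = field(default_factory=dict)

    def check_partition(self) -> None:
        total = sum(self.read_tally.values())
        if total != self.total_reads:
            raise AssertionError(
                f"category tallies ({total}) do not partition library "
                f"({self.total_reads})"
            )


def read_tag_library(path: str | os.PathLike, condition_label: str) -> TagLibrary:
    """Read a two-column TSV (tag, count) into a TagLibrary."""
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    if not {"tag", "count"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'tag' and 'count'")
    return TagLibrary(condition_label, dict(zip(df["tag"], df["count"])))


def write_tag_library(library: TagLibrary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(library.entries):
            fh.write(f"{tag}\t{library.entries[tag]}\n")


def build_tag_index(
    genome_sequences: list[GenomeSequence],
) -> dict[str, list[tuple[str, int, str]]]:
    """Index every CATG-anchored 21-mer on both strands of the genome.

    CATG is palindromic, so each genomic site carries a candidate tag on each
    strand. Locations are recorded as (chrom, forward-axis position of the
    site's first base, strand); windows truncated by a chromosome end are not
    indexed.
    """
    index: dict[str, list[tuple[str, int, str]]] = {}
    for chrom in genome_sequences:
        seq = chrom.sequence
        n = len(seq)
        i = seq.find(ANCHOR)
        while i != -1:
            if i + TAG_LENGTH <= n:
                tag = seq[i : i + TAG_LENGTH]
                index.setdefault(tag, []).append((chrom.chrom_id, i, "+"))
            if i - (TAG_LENGTH - len(ANCHOR)) >= 0:
                window = seq[i - (TAG_LENGTH - len(ANCHOR)) : i + len(ANCHOR)]
                tag = reverse_complement(window)
                index.setdefault(tag, []).append((chrom.chrom_id, i, "-"))
            i = seq.find(ANCHOR, i + 1)
    # dedupe while keeping order (palindromic windows can repeat)
    for tag, locs in index.items():
        index[tag] = list(dict.fromkeys(locs))
    return index


def map_tags(
    library: TagLibrary, index: dict[str, list[tuple[str, int, str]]]
) -> list[TagHit]:
    """Exact lookup of every library tag; no mismatches tolerated."""
    hits = []
    for tag in library.entries:
        validate_tag(tag)
        hits.append(TagHit(tag, tuple(index.get(tag, ()))))
    return hits


def _extended_span(model: GeneModel, ext: int) -> tuple[int, int]:
    # unclipped on the right: no mapped position can lie beyond the chromosome
    if model.strand == "+":
        return model.start, model.end + ext
    return max(model.start - ext, 0), model.end


def assign_to_genes(
    hits: list[TagHit],
    library: TagLibrary,
    models: list[GeneModel],
    utr_extension_bp: int = 0,
) -> AssignmentReport:
    """Assign uniquely mapped tags to (optionally 3'-extended) gene models.

    Sense hits are pooled per gene; antisense hits are tallied and excluded.
    A hit inside two overlapping same-strand models goes to the model whose 3'
    end is nearest (tag-seq signal is 3'-anchored); exact ties are excluded as
    ambiguous.
    """
    trees: dict[str, IntervalTree] = {}
    three_prime_positions: dict[str, list[int]] = {}
    for m in models:
        span = _extended_span(m, utr_extension_bp)
        trees.setdefault(m.chrom_id, IntervalTree()).addi(span[0], span[1], m)
        three_prime_positions.setdefault(m.chrom_id, []).append(m.three_prime_end)
    for pos_list in three_prime_positions.values():
        pos_list.sort()

    report = AssignmentReport(
        condition_label=library.condition_label,
        total_reads=library.total_tags,
        utr_extension_bp=utr_extension_bp,
        read_tally={c: 0 for c in CATEGORIES},
        unique_tag_tally={c: 0 for c in CATEGORIES},
    )

    for hit in hits:
        count = library.entries[hit.tag]
        if len(hit.locations) == 0:
            category = "unmapped"
        elif len(hit.locations) > 1:
            category = "multi_mapped"
        else:
            chrom, pos, strand = hit.locations[0]
            overlapping = [
                iv.data for iv in trees.get(chrom, IntervalTree()).at(pos)
            ]
            same = [m for m in overlapping if m.strand == strand]
            if same:
                dists = [abs(m.three_prime_end - pos) for m in same]
                best = min(dists)
                nearest = [m for m, d in zip(same, dists) if d == best]
                if len(nearest) == 1:
                    category = "gene_sense"
                    report.gene_counts[nearest[0].gene_id] += count
                else:
                    category = "ambiguous"
            elif overlapping:
                category = "gene_antisense"
            else:
                category = "intergenic"
                ends = three_prime_positions.get(chrom, [])
                if ends:
                    j = bisect.bisect_left(ends, pos)
                    cands = ends[max(j - 1, 0) : j + 1]
                    report.intergenic_distance[hit.tag] = min(
                        abs(e - pos) for e in cands
                    )
        report.read_tally[category] += count
        report.unique_tag_tally[category] += 1
        report.tag_category[hit.tag] = category

    report.check_partition()
    return report


def mapping_summary(
    report_ext0: AssignmentReport, report_ext: AssignmentReport
) -> dict[str, float]:
    """Tag-accounting summary for one library at two 3' extensions.

    Reports the fraction of reads and of unique tags that map to the genome,
    the fraction of mapped reads falling inside gene models at each extension,
    and the extension gain both in percentage points and as a relative
    increase (the two readings of "increases by roughly N%").
    """
    if report_ext0.total_reads != report_ext.total_reads:
        raise ValueError("reports cover different library totals")
    if report_ext0.total_reads == 0:
        raise ValueError("empty library")

    def _fractions(r: AssignmentReport) -> tuple[float, float, float]:
        mapped_reads = r.total_reads - r.read_tally["unmapped"] - r.read_tally["multi_mapped"]
        n_tags = sum(r.unique_tag_tally.values())
        mapped_tags = n_tags - r.unique_tag_tally["unmapped"] - r.unique_tag_tally["multi_mapped"]
        in_gene = r.read_tally["gene_sense"] + r.read_tally["gene_antisense"]
        frac_in_gene = in_gene / mapped_reads if mapped_reads else 0.0
        return mapped_reads / r.total_reads, mapped_tags / n_tags, frac_in_gene

    reads0, tags0, in_gene0 = _fractions(report_ext0)
    reads1, tags1, in_gene1 = _fractions(report_ext)
    return {
        "extension_bp": report_ext.utr_extension_bp,
        "frac_reads_mapped": reads0,
        "frac_unique_tags_mapped": tags0,
        "frac_mapped_reads_in_genes_ext0": in_gene0,
        "frac_mapped_reads_in_genes_ext": in_gene1,
        "extension_gain_points": in_gene1 - in_gene0,
        "extension_gain_relative": (in_gene1 - in_gene0) / in_gene0 if in_gene0 else float("nan"),
    }
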