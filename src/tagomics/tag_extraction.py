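"""In-silico NlaIII tag logic.

A tag is the 21-mer starting at the CATG of an NlaIII restriction site, read
5'->3' on the transcript (anchor + 17 downstream bases). The canonical tag of
a transcript comes from its most 3' site; secondary tags (incomplete
digestion) come from more 5' sites. Sites closer than 17 nt to the 3' end are
padded with 'A' — read-through into the poly-A tail of an oligo-dT-captured
transcript.
"""

from __future__ import annotations

from .reference_io import GeneModel, GenomeSequence

ANCHOR = "CATG"
TAG_LENGTH = 21

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "ANCHOR",
    "TAG_LENGTH",
    "reverse_complement",
    "validate_tag",
    "find_nlaiii_sites",
    "canonical_tag",
    "all_expected_tags",
    "transcript_sequence",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_tag(tag: str) -> str:
    """Check the tag invariants (length 21, CATG prefix, DNA alphabet)."""
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag {tag!r}: length {len(tag)} != {TAG_LENGTH}")
    if not tag.startswith(ANCHOR):
        raise ValueError(f"tag {tag!r}: missing {ANCHOR} anchor prefix")
    if set(tag) - set("ACGTN"):
        raise ValueError(f"tag {tag!r}: non-ACGTN characters")
    return tag


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")


def find_nlaiii_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CATG occurrence, ascending.

    CATG cannot overlap itself, but the scan is exhaustive regardless.
    """
    _check_alphabet(seq)
    sites: list[int] = []
    i = seq.find(ANCHOR)
    while i != -1:
        sites.append(i)
        i = seq.find(ANCHOR, i + 1)
    return sites


def _tag_at(seq: str, site: int) -> str:
    window = seq[site : site + TAG_LENGTH]
    if len(window) < TAG_LENGTH:
        window = window + "A" * (TAG_LENGTH - len(window))  # poly-A read-through
    return window


def canonical_tag(transcript_seq: str) -> str | None:
    """The 21-bp tag from the most 3' NlaIII site, or None if the transcript
    carries no site (an undigestable molecule, not an error)."""
    sites = find_nlaiii_sites(transcript_seq)
    if not sites:
        return None
    return _tag_at(transcript_seq, sites[-1])


def all_expected_tags(transcript_seq: str) -> list[tuple[int, str]]:
    """All (site_rank_from_3prime, tag) pairs; rank 1 is the most 3' site.

    The rank-1 entry equals ``canonical_tag``.
    """
    sites = find_nlaiii_sites(transcript_seq)
    return [
        (rank, _tag_at(transcript_seq, site))
        for rank, site in enumerate(reversed(sites), start=1)
    ]


def transcript_sequence(model: GeneModel, genome: GenomeSequence) -> str:
    """Exon-spliced transcript sequence, 5'->3' (reverse-complemented for − strand)."""
    if model.chrom_id != genome.chrom_id:
        raise ValueError(
            f"gene {model.gene_id!r} is on {model.chrom_id!r}, not {genome.chrom_id!r}"
        )
    spliced = "".join(genome.sequence[s:e] for s, e in model.exons)
    return spliced if model.strand == "+" else reverse_complement(spliced)
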