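"""Tag index, exact mapping, uniqueness filtering and gene assignment."""

import numpy as np
import pytest

from tagomics.reference_io import GeneModel, GenomeSequence
from tagomics.tag_extraction import reverse_complement
from tagomics.tag_mapping import (
    TagLibrary,
    assign_to_genes,
    build_tag_index,
    map_tags,
    mapping_summary,
    read_tag_library,
    write_tag_library,
)

from oracles import scan_tag_locations


def _random_genome(rng, length):
    return GenomeSequence(
        "c1", "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    )


def test_index_forward_entry_positions():
    g = GenomeSequence("c1", "AACATG" + "T" * 30)
    index = build_tag_index([g])
    tag = g.sequence[2:23]
    assert index[tag] == [("c1", 2, "+")]


def test_index_reverse_strand_entry():
    # CATG present; the reverse-strand 21-mer is anchored at the same site
    rng = np.random.default_rng(3)
    g = _random_genome(rng, 200)
    index = build_tag_index([g])
    rev_tags = {t: locs for t, locs in index.items() if any(s == "-" for _, _, s in locs)}
    assert rev_tags
    for tag, locs in rev_tags.items():
        for chrom, pos, strand in locs:
            if strand == "-":
                window = g.sequence[pos - 17 : pos + 4]
                assert reverse_complement(window) == tag


@pytest.mark.parametrize("seed", range(5))
def test_index_equals_brute_force_scan(seed):
    """Oracle equivalence: the index lists exactly the locations a naive
    both-strand window scan finds, for every indexed tag."""
    rng = np.random.default_rng(seed)
    g = _random_genome(rng, 3000)
    index = build_tag_index([g])
    assert index  # random 3 kb contains sites
    for tag, locs in index.items():
        assert sorted(locs) == sorted(scan_tag_locations({"c1": g.sequence}, tag))


def test_map_tags_unique_multi_and_mismatch():
    seq = "AA" + "CATG" + "C" * 17 + "TTTT" + "CATG" + "G" * 17
    g = GenomeSequence("c1", seq)
    index = build_tag_index([g])
    unique_tag = "CATG" + "C" * 17
    lib = TagLibrary("x", {unique_tag: 5})
    (hit,) = map_tags(lib, index)
    assert len(hit.locations) == 1
    # one substitution: unmapped under 100% identity
    mm = "CATG" + "C" * 16 + "A"
    (hit,) = map_tags(TagLibrary("x", {mm: 1}), index)
    assert hit.locations == ()
    # duplicated 21-mer: multi-mapped
    dup = GenomeSequence("c2", seq + "AA" + "CATG" + "C" * 17)
    index2 = build_tag_index([g, dup])
    (hit,) = map_tags(TagLibrary("x", {unique_tag: 1}), index2)
    assert len(hit.locations) > 1


def test_map_tags_rejects_invalid_tag():
    with pytest.raises(ValueError, match="AATG"):
        map_tags(TagLibrary("x", {"AATG" + "A" * 17: 1}), {})


def _toy_assignment(ext=0):
    # distinct non-CATG fillers so no window repeats on either strand
    seq = "AC" * 50 + "CATG" + "A" * 17 + "AG" * 40 + "CATG" + "G" * 17 + "TC" * 40
    g = GenomeSequence("c1", seq)
    gene = GeneModel("gene1", "c1", "+", 90, 150)
    sense = seq[100:121]
    downstream = seq[201:222]  # 51 bp past the gene end
    anti = reverse_complement(seq[100 - 17 : 104])
    lib = TagLibrary("x", {sense: 10, downstream: 4, anti: 3})
    index = build_tag_index([g])
    hits = map_tags(lib, index)
    return assign_to_genes(hits, lib, [gene], ext), lib


def test_assignment_sense_antisense_intergenic():
    report, lib = _toy_assignment(ext=0)
    assert report.read_tally["gene_sense"] == 10
    assert report.read_tally["gene_antisense"] == 3
    assert report.read_tally["intergenic"] == 4
    assert report.gene_counts["gene1"] == 10  # antisense excluded from counts
    assert sum(report.read_tally.values()) == lib.total_tags


def test_assignment_extension_captures_downstream_tag():
    report, _ = _toy_assignment(ext=200)
    assert report.read_tally["intergenic"] == 0
    assert report.gene_counts["gene1"] == 14


def test_overlapping_genes_resolved_by_nearest_three_prime_end():
    seq = "AG" * 25 + "CATG" + "A" * 17 + "TC" * 100
    g = GenomeSequence("c1", seq)
    near = GeneModel("near", "c1", "+", 0, 80)  # 3' end at 80
    far = GeneModel("far", "c1", "+", 0, 260)  # 3' end at 260
    tag = seq[50:71]
    lib = TagLibrary("x", {tag: 7})
    report = assign_to_genes(map_tags(lib, build_tag_index([g])), lib, [near, far])
    assert report.gene_counts == {"near": 7}


def test_equidistant_overlap_is_ambiguous():
    seq = "AG" * 25 + "CATG" + "A" * 17 + "TC" * 50
    g = GenomeSequence("c1", seq)
    a = GeneModel("a", "c1", "+", 0, 100)  # 3' end 100, distance 50
    b = GeneModel("b", "c1", "+", 10, 100)  # 3' end 100, distance 50
    tag = seq[50:71]
    lib = TagLibrary("x", {tag: 2})
    report = assign_to_genes(map_tags(lib, build_tag_index([g])), lib, [a, b])
    assert report.read_tally["ambiguous"] == 2
    assert not report.gene_counts


def test_category_partition_on_simulated_library(small_reference, small_libraries):
    genome, models, _ = small_reference
    lib1, lib2, _ = small_libraries
    index = build_tag_index(genome)
    for lib in (lib1, lib2):
        report = assign_to_genes(map_tags(lib, index), lib, models, 0)
        assert sum(report.read_tally.values()) == lib.total_tags
        assert sum(report.unique_tag_tally.values()) == len(lib.entries)


def test_gene_sense_reads_monotone_in_extension(small_reference, small_libraries):
    genome, models, _ = small_reference
    lib1, _, _ = small_libraries
    index = build_tag_index(genome)
    hits = map_tags(lib1, index)
    previous = -1
    for ext in (0, 50, 200, 1000):
        report = assign_to_genes(hits, lib1, models, ext)
        sense = report.read_tally["gene_sense"]
        assert sense >= previous
        previous = sense


def test_clean_simulation_recovers_emitted_counts(small_reference, small_libraries):
    """With no errors and no antisense strand flips pending, each gene's
    recovered sense count equals its emitted sense tag count."""
    genome, models, _ = small_reference
    lib1, _, truth = small_libraries
    index = build_tag_index(genome)
    report = assign_to_genes(map_tags(lib1, index), lib1, models, 0)
    emitted = (
        truth.emissions.query("condition == 'replete' and strand == 'sense'")
        .groupby("gene_id")["count"]
        .sum()
    )
    for gene_id, expected in emitted.items():
        assert report.gene_counts.get(gene_id, 0) == expected


def test_mapping_summary_and_errors(small_reference, small_libraries):
    genome, models, _ = small_reference
    lib1, _, _ = small_libraries
    index = build_tag_index(genome)
    hits = map_tags(lib1, index)
    r0 = assign_to_genes(hits, lib1, models, 0)
    r200 = assign_to_genes(hits, lib1, models, 200)
    s = mapping_summary(r0, r200)
    assert 0.99 <= s["frac_reads_mapped"] <= 1.0  # e=0, unique canonical tags
    assert s["extension_gain_points"] >= 0.0
    with pytest.raises(ValueError, match="empty library"):
        empty = assign_to_genes([], TagLibrary("x", {}), models, 0)
        mapping_summary(empty, empty)


def test_tag_library_tsv_roundtrip(tmp_path, small_libraries):
    lib1, _, _ = small_libraries
    p = tmp_path / "tags.tsv"
    write_tag_library(lib1, p)
    back = read_tag_library(p, lib1.condition_label)
    assert back.entries == lib1.entries
    assert back.total_tags == lib1.total_tags
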