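"""Synthetic genome, tag-library and spectral-count generation.

The generator emulates the study design the pipeline targets: two pooled,
replicate-free tag-seq libraries of fixed depth from one genome (P-replete =
condition 1, P-deficient = condition 2), a subset of genes with planted log2
fold changes, incomplete NlaIII digestion (each site cut independently with
probability ``cleavage_prob``, the emitted tag anchored at the 3'-most cut
site, so the rank-k site from the 3' end fires with probability c*(1-c)**(k-1)),
antisense emission as a per-tag strand flip at the same site, and per-base
substitution errors restricted to the 17 non-anchor bases (reads whose CATG
anchor is corrupted would never be extracted as tags upstream). A companion
protein table makes protein fold changes an attenuated, noisy linear function
of transcript fold changes, with only the most abundant fraction of genes
detected.

Defaults are at the scale of a deep tag-seq study of a diatom-sized genome
(11,242 genes, 12 million tags per library, 318 DE genes); tests and the
bundled analyses run reduced configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .proteomics import ProteinCountTable
from .reference_io import GeneModel, GenomeSequence
from .tag_extraction import (
    TAG_LENGTH,
    all_expected_tags,
    find_nlaiii_sites,
    reverse_complement,
)
from .tag_mapping import TagLibrary, build_tag_index

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_reference",
    "generate_truth",
    "simulate_count_table",
    "simulate_tag_libraries",
    "simulate_spectral_counts",
]

_BASES = np.array(list("ACGT"))

# RNG stream codes: one independent stream per operation, keyed by (seed, code)
_STREAM_REFERENCE = 1
_STREAM_TAGS = 2
_STREAM_SPECTRA = 3


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    ``log2_fc_values`` are cycled across the ``n_de_genes`` DE genes.
    ``baseline_abundance`` is (mean, sd) of the natural log of the per-gene
    relative abundance. ``cleavage_prob``/``antisense_rate``/``seq_error_rate``
    have no published estimates; the defaults are configurable conventions.
    """

    n_genes: int = 11_242
    gene_length_range: tuple[int, int] = (600, 3000)
    intron_rate: float = 0.0
    n_de_genes: int = 318
    log2_fc_values: tuple[float, ...] = (2.0, -2.0)
    baseline_abundance: tuple[float, float] = (0.0, 1.0)
    library_sizes: tuple[int, int] = (12_000_000, 12_000_000)
    cleavage_prob: float = 0.8
    antisense_rate: float = 0.1
    seq_error_rate: float = 0.005
    intergenic_length_range: tuple[int, int] = (400, 2000)
    utr_unannotated_bp: int = 100
    enforce_unique_tags: bool = True
    balanced_composition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cleavage_prob", "antisense_rate", "seq_error_rate", "intron_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if min(self.library_sizes) <= 0:
            raise ValueError("library_sizes must be positive")
        if self.gene_length_range[0] < TAG_LENGTH:
            raise ValueError(
                f"genes shorter than {TAG_LENGTH} bp cannot carry a tag"
            )
        if self.n_de_genes > 0 and not self.log2_fc_values:
            raise ValueError("log2_fc_values required when n_de_genes > 0")


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``genes``: per-gene frame (gene_id, strand, length, has_intron, n_sites,
    canonical_tag, abundance_1, abundance_2, delta). ``site_tags`` maps
    gene_id to a list of (rank_from_3prime, sense_tag, antisense_tag_or_None).
    ``emissions`` (after :func:`simulate_tag_libraries`): intended pre-error
    per-category counts. ``undigested_weight``: expected fraction of molecules
    escaping digestion entirely under the configured cleavage probability.
    """

    genes: pd.DataFrame
    site_tags: dict[str, list[tuple[int, str, str | None]]]
    emissions: pd.DataFrame | None = None
    undigested_weight: float = field(default=float("nan"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_transcript(rng: np.random.Generator, length: int) -> tuple[str, list[int]]:
    """Random transcript whose 3'-most CATG leaves a full 21-mer inside it."""
    for _ in range(200):
        seq = _random_seq(rng, length)
        sites = find_nlaiii_sites(seq)
        if sites and sites[-1] + TAG_LENGTH <= length:
            return seq, sites
    raise RuntimeError(f"could not place an NlaIII site in a {length} bp transcript")


def _plant_abundances(
    rng: np.random.Generator, config: SimConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline abundances with planted fold changes; returns (abundance_1, delta)."""
    abundance_1 = rng.lognormal(
        config.baseline_abundance[0], config.baseline_abundance[1], size=n
    )
    delta = np.zeros(n)
    if config.n_de_genes > 0:
        de_idx = rng.choice(n, size=config.n_de_genes, replace=False)
        fc = np.array(config.log2_fc_values, dtype=float)
        if config.balanced_composition:
            # plant DE as abundance-swap pairs: for magnitude m, the up gene
            # sits at A*2^(-m/2) and its partner at A*2^(+m/2) with -m, so each
            # pair's total transcript output is condition-invariant (the
            # compositional assumption behind total-count/tpm normalization)
            for j in range(0, config.n_de_genes - 1, 2):
                m = abs(fc[(j // 2) % len(fc)])
                up, down = de_idx[j], de_idx[j + 1]
                delta[up] = m
                delta[down] = -m
                base = abundance_1[up]
                abundance_1[up] = base * 2.0 ** (-m / 2.0)
                abundance_1[down] = base * 2.0 ** (m / 2.0)
            if config.n_de_genes % 2:
                delta[de_idx[-1]] = abs(fc[(config.n_de_genes // 2) % len(fc)])
        else:
            delta[de_idx] = fc[np.arange(config.n_de_genes) % len(fc)]
    return abundance_1, delta


def generate_truth(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Count-level ground truth without a genome (abundances and planted delta).

    Useful for statistical calibration studies where the mapping stage is not
    under test; pair with :func:`simulate_count_table`.
    """
    rng = _rng(config.seed if seed is None else seed, _STREAM_REFERENCE)
    n = config.n_genes
    abundance_1, delta = _plant_abundances(rng, config, n)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(n)],
            "strand": "+",
            "length": 0,
            "has_intron": False,
            "n_sites": 0,
            "canonical_tag": "",
            "abundance_1": abundance_1,
            "abundance_2": abundance_1 * np.exp2(delta),
            "delta": delta,
        }
    )
    return SimTruth(genes=genes, site_tags={})


def simulate_count_table(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-gene counts for both libraries, multinomial at the configured depths.

    This is the count table a lossless extract-map-assign pass would deliver
    (columns gene_id, x1, x2).
    """
    rng = _rng(config.seed if seed is None else seed, _STREAM_TAGS)
    genes = truth.genes
    a1 = genes["abundance_1"].to_numpy()
    a2 = genes["abundance_2"].to_numpy()
    x1 = rng.multinomial(int(config.library_sizes[0]), a1 / a1.sum())
    x2 = rng.multinomial(int(config.library_sizes[1]), a2 / a2.sum())
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(), "x1": x1, "x2": x2})


def generate_reference(
    config: SimConfig, seed: int | None = None
) -> tuple[list[GenomeSequence], list[GeneModel], SimTruth]:
    """One-chromosome genome with i.i.d.-uniform background, gene models, truth.

    Every gene's transcript contains at least one CATG so a canonical tag
    exists. With ``intron_rate`` > 0, affected genes carry one intron inserted
    inside the 3'-most CATG (between CA and TG), so their canonical transcript
    tag spans a splice junction and cannot map to the genome. With
    ``enforce_unique_tags``, genes whose canonical 21-mer occurs more than
    once in the assembled genome (either strand) are regenerated.

    ``utr_unannotated_bp`` emulates gene models that stop short of the true
    3' UTR: each annotated model's 3' end is truncated by a per-gene uniform
    draw up to that many bp, while transcripts (and hence tags) still come
    from the full gene region — so a realistic fraction of tags lands just
    past annotated 3' ends and is only recovered by extension.

    Fully reproducible from the seed.
    """
    rng = _rng(config.seed if seed is None else seed, _STREAM_REFERENCE)
    n = config.n_genes
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    has_intron = rng.random(n) < config.intron_rate
    intron_lens = rng.integers(50, 151, size=n)
    utr_trunc = (
        rng.integers(0, config.utr_unannotated_bp + 1, size=n)
        if config.utr_unannotated_bp > 0
        else np.zeros(n, dtype=int)
    )
    spacers = [
        _random_seq(
            rng,
            int(
                rng.integers(
                    config.intergenic_length_range[0],
                    config.intergenic_length_range[1] + 1,
                )
            ),
        )
        for _ in range(n + 1)
    ]
    transcripts = [_make_transcript(rng, int(L))[0] for L in lengths]

    def _assemble() -> tuple[GenomeSequence, list[GeneModel], dict, dict]:
        parts: list[str] = []
        models: list[GeneModel] = []
        site_tags: dict[str, list[tuple[int, str, str | None]]] = {}
        canon: dict[str, str] = {}
        offset = 0
        for i in range(n):
            parts.append(spacers[i])
            offset += len(spacers[i])
            tx = transcripts[i]
            sites = find_nlaiii_sites(tx)
            gene_id = f"g{i + 1:05d}"
            tags = all_expected_tags(tx)
            entries: list[tuple[int, str, str | None]] = []
            for rank, sense_tag in tags:
                pos = sites[len(sites) - rank]
                anti = (
                    reverse_complement(tx[pos - (TAG_LENGTH - 4) : pos + 4])
                    if pos >= TAG_LENGTH - 4
                    else None
                )
                entries.append((rank, sense_tag, anti))
            site_tags[gene_id] = entries
            canon[gene_id] = tags[0][1]

            if has_intron[i]:
                cut = sites[-1] + 2  # split the 3'-most CATG between CA|TG
                ilen = int(intron_lens[i])
                pre_mrna = tx[:cut] + _random_seq(rng, ilen) + tx[cut:]
                exon_tx = [(0, cut), (cut + ilen, len(pre_mrna))]
            else:
                pre_mrna = tx
                exon_tx = [(0, len(pre_mrna))]
            glen = len(pre_mrna)
            if strands[i] == "+":
                segment = pre_mrna
                exons = [(offset + a, offset + b) for a, b in exon_tx]
            else:
                segment = reverse_complement(pre_mrna)
                exons = sorted(
                    (offset + glen - b, offset + glen - a) for a, b in exon_tx
                )
            span_start, span_end = offset, offset + glen
            u = int(utr_trunc[i])
            if u:
                # annotated model stops short of the true 3' end (missing UTR)
                if strands[i] == "+":
                    span_end = max(exons[-1][0] + 1, span_end - u)
                    exons[-1] = (exons[-1][0], span_end)
                else:
                    span_start = min(exons[0][1] - 1, span_start + u)
                    exons[0] = (span_start, exons[0][1])
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom_id="chr1",
                    strand=str(strands[i]),
                    start=span_start,
                    end=span_end,
                    exons=tuple(exons),
                )
            )
            parts.append(segment)
            offset += glen
        parts.append(spacers[n])
        return GenomeSequence("chr1", "".join(parts)), models, site_tags, canon

    genome, models, site_tags, canon = _assemble()
    if config.enforce_unique_tags:
        for _ in range(30):
            index = build_tag_index([genome])
            # an intron-spanning canonical tag legitimately has 0 locations;
            # only genuine duplicates trigger regeneration
            bad = [
                i
                for i, m in enumerate(models)
                if len(index.get(canon[m.gene_id], ())) > 1
            ]
            if not bad:
                break
            for i in bad:
                transcripts[i] = _make_transcript(rng, int(lengths[i]))[0]
            genome, models, site_tags, canon = _assemble()
        else:
            raise RuntimeError("could not enforce unique canonical tags")

    abundance_1, delta = _plant_abundances(rng, config, n)
    abundance_2 = abundance_1 * np.exp2(delta)

    genes = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "strand": [m.strand for m in models],
            "length": lengths,
            "has_intron": has_intron,
            "n_sites": [len(site_tags[m.gene_id]) for m in models],
            "canonical_tag": [canon[m.gene_id] for m in models],
            "abundance_1": abundance_1,
            "abundance_2": abundance_2,
            "delta": delta,
        }
    )
    return [genome], models, SimTruth(genes=genes, site_tags=site_tags)


def simulate_tag_libraries(
    reference: tuple[list[GenomeSequence], list[GeneModel]],
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[TagLibrary, TagLibrary, SimTruth]:
    """Draw the two fixed-depth tag libraries.

    Per molecule each NlaIII site is cut independently with probability c and
    the tag comes from the 3'-most cut site (rank k fires with probability
    c*(1-c)**(k-1)); with probability a the emitted tag is the opposite
    strand's 21-mer at the same site (where one exists); each of the 17
    non-anchor bases is substituted with probability e. Counts are multinomial
    across all (gene, site, strand) categories conditioned on the library
    totals, with per-gene expected proportions proportional to abundance.
    """
    rng = _rng(config.seed if seed is None else seed, _STREAM_TAGS)
    genes = truth.genes
    c, a, e = config.cleavage_prob, config.antisense_rate, config.seq_error_rate

    cat_gene: list[str] = []
    cat_rank: list[int] = []
    cat_strand: list[str] = []
    cat_tag: list[str] = []
    cat_weight: list[float] = []  # per-molecule emission probability (sense split)
    for row in genes.itertuples():
        for rank, sense_tag, anti_tag in truth.site_tags[row.gene_id]:
            site_p = c * (1.0 - c) ** (rank - 1)
            anti_p = a if anti_tag is not None else 0.0
            cat_gene.append(row.gene_id)
            cat_rank.append(rank)
            cat_strand.append("sense")
            cat_tag.append(sense_tag)
            cat_weight.append(site_p * (1.0 - anti_p))
            if anti_tag is not None:
                cat_gene.append(row.gene_id)
                cat_rank.append(rank)
                cat_strand.append("antisense")
                cat_tag.append(anti_tag)
                cat_weight.append(site_p * anti_p)
    weight = np.asarray(cat_weight)
    gene_order = {g: i for i, g in enumerate(genes["gene_id"])}
    gene_idx = np.array([gene_order[g] for g in cat_gene])

    abundance = {
        1: genes["abundance_1"].to_numpy(),
        2: genes["abundance_2"].to_numpy(),
    }
    n_sites = genes["n_sites"].to_numpy()
    undig = {
        cond: float(
            np.sum(abundance[cond] * (1.0 - c) ** n_sites) / np.sum(abundance[cond])
        )
        for cond in (1, 2)
    }

    labels = {1: "replete", 2: "deficient"}
    libraries: dict[int, TagLibrary] = {}
    emission_frames = []
    for cond, total in zip((1, 2), config.library_sizes):
        p = abundance[cond][gene_idx] * weight
        if p.sum() <= 0:
            raise ValueError("no emittable tag categories (all sites uncut?)")
        counts = rng.multinomial(int(total), p / p.sum())
        tag_counts: dict[str, int] = {}
        for tag, m in zip(cat_tag, counts):
            if m:
                tag_counts[tag] = tag_counts.get(tag, 0) + int(m)
        if e > 0:
            tag_counts = _apply_sequencing_errors(rng, tag_counts, e)
        libraries[cond] = TagLibrary(labels[cond], tag_counts)
        emission_frames.append(
            pd.DataFrame(
                {
                    "condition": labels[cond],
                    "gene_id": cat_gene,
                    "rank": cat_rank,
                    "strand": cat_strand,
                    "count": counts,
                }
            )
        )

    truth = dc_replace(
        truth,
        emissions=pd.concat(emission_frames, ignore_index=True),
        undigested_weight=float(np.mean([undig[1], undig[2]])),
    )
    return libraries[1], libraries[2], truth


def _apply_sequencing_errors(
    rng: np.random.Generator, tag_counts: dict[str, int], e: float
) -> dict[str, int]:
    """Substitute non-anchor bases with per-base probability e."""
    n_var = TAG_LENGTH - 4
    p_any = 1.0 - (1.0 - e) ** n_var
    k_pmf = np.array(
        [
            math.comb(n_var, k) * e**k * (1 - e) ** (n_var - k)
            for k in range(1, n_var + 1)
        ]
    )
    k_pmf /= k_pmf.sum()
    out: dict[str, int] = {}
    for tag, m in tag_counts.items():
        n_err = rng.binomial(m, p_any)
        if m - n_err:
            out[tag] = out.get(tag, 0) + (m - n_err)
        for _ in range(n_err):
            k = 1 + rng.choice(n_var, p=k_pmf)
            positions = rng.choice(n_var, size=int(k), replace=False) + 4
            mutated = list(tag)
            for pos in positions:
                choices = [b for b in "ACGT" if b != mutated[pos]]
                mutated[pos] = choices[rng.integers(0, 3)]
            mtag = "".join(mutated)
            out[mtag] = out.get(mtag, 0) + 1
    return out


def simulate_spectral_counts(
    truth: SimTruth,
    slope: float = 0.49,
    intercept: float = -0.25,
    noise_sd: float = 0.3,
    detect_top_frac: float = 0.11,
    depth: int = 50_000,
    singleton_frac: float = 0.1,
    seed: int | None = None,
) -> ProteinCountTable:
    """Protein table whose fold changes attenuate the transcript fold changes.

    Protein log2 FC = slope*delta + intercept*1{delta != 0} + Normal(0, noise_sd).
    Only the top ``detect_top_frac`` of genes by abundance are detected (LC-MS
    sees the abundant proteome); spectral counts are Poisson with means
    proportional to abundance scaled to ``depth``. A ``singleton_frac``
    fraction of detected proteins carries exactly one peptide identification
    (to exercise the two-peptide support filter).
    """
    if not 0.0 < detect_top_frac <= 1.0:
        raise ValueError("detect_top_frac must be in (0, 1]")
    rng = _rng(0 if seed is None else seed, _STREAM_SPECTRA)
    genes = truth.genes
    mean_abund = (genes["abundance_1"] + genes["abundance_2"]) / 2.0
    n_detect = int(np.floor(detect_top_frac * len(genes)))
    detected = genes.loc[
        mean_abund.sort_values(ascending=False, kind="stable").index[:n_detect]
    ].reset_index(drop=True)

    delta = detected["delta"].to_numpy()
    protein_fc = (
        slope * delta
        + intercept * (delta != 0.0)
        + rng.normal(0.0, noise_sd, size=len(detected))
    )
    base = detected["abundance_1"].to_numpy()
    mean1 = depth * base / base.sum()
    mean2 = mean1 * np.exp2(protein_fc)
    s1 = rng.poisson(mean1)
    s2 = rng.poisson(mean2)
    singleton = rng.random(len(detected)) < singleton_frac
    peptides = np.where(singleton, 1, 2 + rng.poisson(2.0, size=len(detected)))
    df = pd.DataFrame(
        {
            "protein_id": detected["gene_id"].to_numpy(),
            "peptides": peptides.astype(int),
            "s1": s1.astype(int),
            "s2": s2.astype(int),
            "true_protein_log2fc": protein_fc,
        }
    )
    return ProteinCountTable.from_frame(df)
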