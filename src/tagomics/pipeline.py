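"""Stage orchestration: simulate -> extract -> map -> dge -> prot -> integrate -> report.

Each stage reads the artifacts of its upstream stages from the run directory
and writes its own TSV/JSON artifacts plus a line in ``run_log.jsonl``
(stage, parameters, tallies, wall time). Artifacts are deterministic for a
fixed config and seed; only the run log carries timing.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import dge, integration, proteomics, synthetic, tag_mapping
from .reference_io import read_fasta, read_gene_models, write_fasta, write_gene_models
from .tag_extraction import all_expected_tags, transcript_sequence

__all__ = ["RunConfig", "PipelineError", "run_stage", "STAGES"]

STAGES = ("simulate", "extract", "map", "dge", "prot", "integrate", "report", "all")

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage cannot run (missing upstream artifact or bad configuration)."""


@dataclass
class RunConfig:
    """All pipeline thresholds (defaults are the analysis' stated settings)
    plus the simulation scale."""

    outdir: str = "tagomics_run"
    utr_extension_bp: int = 200
    lfdr_threshold: float = 0.05
    protein_alpha: float = 0.05
    min_peptides: int = 2
    min_fold: float = 2.0
    de_level: str = "gene"  # or "tag"
    seed: int = 0
    # simulation scale (reduced from full-study scale for desk runs)
    n_genes: int = 600
    n_de_genes: int = 60
    library_size: int = 100_000
    cleavage_prob: float = 0.8
    antisense_rate: float = 0.1
    seq_error_rate: float = 0.002
    intron_rate: float = 0.02
    spectral_depth: int = 20_000
    detect_top_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("lfdr_threshold", "protein_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineError(f"{name} must be in (0, 1), got {v}")
        if self.utr_extension_bp < 0:
            raise PipelineError("utr_extension_bp must be >= 0")
        if self.de_level not in ("gene", "tag"):
            raise PipelineError("de_level must be 'gene' or 'tag'")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; later CLI flags win."""
        values: dict[str, object] = {}
        known = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise PipelineError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                values[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                values[key] = int(val)
            elif isinstance(default, float):
                values[key] = float(val)
            else:
                values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def _require(config: RunConfig, name: str, produced_by: str) -> Path:
    p = config.path(name)
    if not p.exists():
        raise PipelineError(
            f"missing artifact {p}; run the '{produced_by}' stage first"
        )
    return p


def _log(config: RunConfig, stage: str, t0: float, **tallies) -> None:
    entry = {
        "stage": stage,
        "parameters": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "tallies": tallies,
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    with open(config.path("run_log.jsonl"), "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
    print(f"[{stage}] {tallies}", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(config: RunConfig) -> None:
    t0 = time.perf_counter()
    sim = synthetic.SimConfig(
        n_genes=config.n_genes,
        n_de_genes=config.n_de_genes,
        log2_fc_values=(2.0, -2.0, 3.0, -3.0, 1.5, -1.5),
        library_sizes=(config.library_size, config.library_size),
        cleavage_prob=config.cleavage_prob,
        antisense_rate=config.antisense_rate,
        seq_error_rate=config.seq_error_rate,
        intron_rate=config.intron_rate,
        gene_length_range=(400, 1500),
        intergenic_length_range=(200, 800),
        seed=config.seed,
    )
    genome, models, truth = synthetic.generate_reference(sim)
    lib1, lib2, truth = synthetic.simulate_tag_libraries((genome, models), truth, sim)
    proteins = synthetic.simulate_spectral_counts(
        truth,
        detect_top_frac=config.detect_top_frac,
        depth=config.spectral_depth,
        seed=config.seed,
    )
    write_fasta(genome, config.path("genome.fasta"))
    write_gene_models(models, config.path("models.gff3"))
    tag_mapping.write_tag_library(lib1, config.path("tags_replete.tsv"))
    tag_mapping.write_tag_library(lib2, config.path("tags_deficient.tsv"))
    _write_tsv(proteins.data, config.path("proteins.tsv"))
    _write_tsv(truth.genes, config.path("truth_genes.tsv"))
    _log(
        config,
        "simulate",
        t0,
        n_genes=len(models),
        library_sizes=[lib1.total_tags, lib2.total_tags],
        n_proteins=len(proteins.data),
    )


def stage_extract(config: RunConfig) -> None:
    t0 = time.perf_counter()
    genome = read_fasta(_require(config, "genome.fasta", "simulate"))
    models = read_gene_models(_require(config, "models.gff3", "simulate"))
    by_chrom = {g.chrom_id: g for g in genome}
    rows = []
    for m in models:
        tags = all_expected_tags(transcript_sequence(m, by_chrom[m.chrom_id]))
        rows.append(
            {
                "gene_id": m.gene_id,
                "canonical_tag": tags[0][1] if tags else "",
                "n_sites": len(tags),
            }
        )
    _write_tsv(pd.DataFrame(rows), config.path("canonical_tags.tsv"))
    _log(config, "extract", t0, n_genes=len(rows))


def stage_map(config: RunConfig) -> None:
    t0 = time.perf_counter()
    genome = read_fasta(_require(config, "genome.fasta", "simulate"))
    models = read_gene_models(_require(config, "models.gff3", "simulate"))
    lib1 = tag_mapping.read_tag_library(
        _require(config, "tags_replete.tsv", "simulate"), "replete"
    )
    lib2 = tag_mapping.read_tag_library(
        _require(config, "tags_deficient.tsv", "simulate"), "deficient"
    )
    index = tag_mapping.build_tag_index(genome)
    summary: dict[str, object] = {"library_totals": {}}
    reports = {}
    per_tag: dict[str, dict[str, int]] = {}
    for key, lib in (("replete", lib1), ("deficient", lib2)):
        hits = tag_mapping.map_tags(lib, index)
        r0 = tag_mapping.assign_to_genes(hits, lib, models, 0)
        r1 = tag_mapping.assign_to_genes(hits, lib, models, config.utr_extension_bp)
        reports[key] = r1
        summary[key] = tag_mapping.mapping_summary(r0, r1)
        summary[key]["read_tally_ext"] = r1.read_tally
        summary[key]["unique_tag_tally_ext"] = r1.unique_tag_tally
        summary["library_totals"][key] = lib.total_tags
        for tag, cat in r1.tag_category.items():
            if cat == "gene_sense":
                per_tag.setdefault(tag, {"replete": 0, "deficient": 0})[key] = (
                    lib.entries[tag]
                )
    gene_ids = sorted({m.gene_id for m in models})
    counts = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "x1": [reports["replete"].gene_counts.get(g, 0) for g in gene_ids],
            "x2": [reports["deficient"].gene_counts.get(g, 0) for g in gene_ids],
        }
    )
    _write_tsv(counts, config.path("gene_counts.tsv"))
    tag_rows = pd.DataFrame(
        {
            "tag": sorted(per_tag),
            "x1": [per_tag[t]["replete"] for t in sorted(per_tag)],
            "x2": [per_tag[t]["deficient"] for t in sorted(per_tag)],
        }
    )
    _write_tsv(tag_rows, config.path("tag_counts.tsv"))
    _write_json(summary, config.path("mapping_summary.json"))
    _log(
        config,
        "map",
        t0,
        frac_reads_mapped={k: round(summary[k]["frac_reads_mapped"], 4) for k in reports},
    )


def stage_dge(config: RunConfig) -> None:
    t0 = time.perf_counter()
    summary = json.loads(_require(config, "mapping_summary.json", "map").read_text())
    n1 = summary["library_totals"]["replete"]
    n2 = summary["library_totals"]["deficient"]
    if config.de_level == "gene":
        table = pd.read_csv(_require(config, "gene_counts.tsv", "map"), sep="\t")
    else:
        table = pd.read_csv(_require(config, "tag_counts.tsv", "map"), sep="\t")
        table = table.rename(columns={"tag": "gene_id"})
    prior = dge.fit_prior(table, n1, n2)
    results = dge.de_table(table, n1, n2, prior, config.lfdr_threshold)
    called = dge.call_differential(results, config.lfdr_threshold)
    _write_tsv(results, config.path("de_genes.tsv"))
    _write_json(
        {
            "pi0": prior.pi0,
            "tau": prior.tau,
            "converged": prior.converged,
            "n_called": len(called),
            "n_up": called.attrs["n_up"],
            "n_down": called.attrs["n_down"],
            "level": config.de_level,
        },
        config.path("de_summary.json"),
    )
    _log(config, "dge", t0, n_called=len(called), pi0=round(prior.pi0, 4))


def stage_prot(config: RunConfig) -> None:
    t0 = time.perf_counter()
    table = proteomics.read_protein_table(_require(config, "proteins.tsv", "simulate"))
    table = proteomics.filter_by_peptides(table, config.min_peptides)
    n_removed = table.data.attrs.get("n_removed", 0)
    table = proteomics.normalize_spectral_counts(table)
    results = proteomics.fisher_differential(table, config.protein_alpha)
    _write_tsv(results, config.path("protein_de.tsv"))
    _write_json(
        {
            "n_proteins": len(results),
            "n_removed_by_peptide_filter": n_removed,
            "n_significant": int(results["significant"].sum()),
            "n_up": results.attrs["n_up"],
            "n_down": results.attrs["n_down"],
        },
        config.path("protein_summary.json"),
    )
    _log(config, "prot", t0, n_significant=int(results["significant"].sum()))


def stage_integrate(config: RunConfig) -> None:
    t0 = time.perf_counter()
    transcript_de = pd.read_csv(_require(config, "de_genes.tsv", "dge"), sep="\t")
    protein_de = pd.read_csv(_require(config, "protein_de.tsv", "prot"), sep="\t")
    joined = integration.join_results(transcript_de, protein_de)
    classes = integration.classify_coordination(joined)
    _write_tsv(joined, config.path("integration.tsv"))
    out: dict[str, object] = {
        "n_joined": len(joined),
        "coordination": classes,
    }
    try:
        fit = integration.concordance_regression(joined, config.min_fold)
        out["regression"] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        }
    except ValueError as exc:
        out["regression"] = {"error": str(exc)}
    _write_json(out, config.path("regression.json"))
    _log(config, "integrate", t0, n_joined=len(joined))


def stage_report(config: RunConfig) -> None:
    t0 = time.perf_counter()
    mapping = json.loads(_require(config, "mapping_summary.json", "map").read_text())
    de_summary = json.loads(_require(config, "de_summary.json", "dge").read_text())
    prot_summary = json.loads(
        _require(config, "protein_summary.json", "prot").read_text()
    )
    reg = json.loads(_require(config, "regression.json", "integrate").read_text())
    de = pd.read_csv(config.path("de_genes.tsv"), sep="\t")
    joined = pd.read_csv(config.path("integration.tsv"), sep="\t")
    lines = ["# tagomics run report", ""]
    lines.append("## Tag accounting (per library, at configured 3' extension)")
    for key in ("replete", "deficient"):
        m = mapping[key]
        lines.append(
            f"{key}: reads mapped {m['frac_reads_mapped']:.3f}, "
            f"unique tags mapped {m['frac_unique_tags_mapped']:.3f}, "
            f"in-gene fraction ext0 {m['frac_mapped_reads_in_genes_ext0']:.3f} "
            f"-> ext{config.utr_extension_bp} {m['frac_mapped_reads_in_genes_ext']:.3f} "
            f"(gain {m['extension_gain_points']:.3f} points / "
            f"{m['extension_gain_relative']:.3f} relative)"
        )
    lines.append("")
    lines.append("## Differential expression (empirical Bayes, local FDR)")
    lines.append(
        f"called {de_summary['n_called']} at lfdr<{config.lfdr_threshold} "
        f"({de_summary['n_up']} up, {de_summary['n_down']} down); "
        f"pi0={de_summary['pi0']:.3f}, tau={de_summary['tau']:.3f}"
    )
    lines.append("")
    lines.append("## Differential protein abundance (Fisher exact)")
    lines.append(
        f"significant {prot_summary['n_significant']} of {prot_summary['n_proteins']} "
        f"at p<{config.protein_alpha} ({prot_summary['n_up']} up, "
        f"{prot_summary['n_down']} down)"
    )
    lines.append("")
    lines.append("## Transcript/protein scatter data (tpm1 vs tpm2, top |z|)")
    top = de.reindex(de["z"].abs().sort_values(ascending=False).index).head(10)
    lines.append(
        top[["gene_id", "tpm1", "tpm2", "delta_hat", "lfdr"]].to_string(index=False)
    )
    lines.append("")
    lines.append("## Concordance (protein fold vs transcript fold)")
    lines.append(json.dumps(reg.get("regression", {}), sort_keys=True))
    lines.append(f"coordination classes: {json.dumps(reg['coordination'], sort_keys=True)}")
    lines.append(f"joined records: {len(joined)}")
    config.path("report.txt").write_text("\n".join(lines) + "\n")
    _log(config, "report", t0, lines=len(lines))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "map": stage_map,
    "dge": stage_dge,
    "prot": stage_prot,
    "integrate": stage_integrate,
    "report": stage_report,
}


def run_stage(command: str, config: RunConfig) -> None:
    if command not in STAGES:
        raise PipelineError(f"unknown stage {command!r}; choose from {STAGES}")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    if command == "all":
        for name in STAGES[:-1]:
            _STAGE_FUNCS[name](config)
    else:
        _STAGE_FUNCS[command](config)
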