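#!/usr/bin/env python
"""Call differential expression on the pooled gene counts.

Fits the spike-and-slab empirical prior by EM on the two libraries' counts,
computes each gene's posterior mean log2 fold change, shrunken standard
error, standardized score and local false discovery rate, and reports the
genes called at lfdr < 0.05 against the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from tagomics.pipeline import RunConfig, run_stage

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    config = RunConfig(outdir=str(OUTDIR), seed=1)
    run_stage("dge", config)
    s = json.loads((OUTDIR / "de_summary.json").read_text())
    print(
        f"prior: pi0={s['pi0']:.3f}, tau={s['tau']:.2f} "
        f"({'converged' if s['converged'] else 'NOT converged'})"
    )
    print(f"called {s['n_called']} genes at lfdr<0.05 ({s['n_up']} up, {s['n_down']} down)")
    de = pd.read_csv(OUTDIR / "de_genes.tsv", sep="\t")
    truth = pd.read_csv(OUTDIR / "truth_genes.tsv", sep="\t")
    merged = de.merge(truth[["gene_id", "delta"]], on="gene_id")
    called = merged[merged.significant]
    tp = (called.delta != 0).sum()
    print(f"of the calls, {tp} are planted DE genes and {len(called) - tp} are false")
    print(f"planted DE genes in total: {(truth.delta != 0).sum()}")


if __name__ == "__main__":
    main()
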