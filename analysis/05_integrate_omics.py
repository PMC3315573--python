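#!/usr/bin/env python
"""Join transcript and protein results and fit the concordance regression.

Inner-joins the two result tables on the gene identifier, classifies each
pair's coordination (both up, both down, one-sided, opposing), and fits the
ordinary least squares regression of protein log2 fold change on transcript
log2 fold change over proteins changing at least 2-fold. Also renders the
final plain-text report.
"""

import json
from pathlib import Path

from tagomics.pipeline import RunConfig, run_stage

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    config = RunConfig(outdir=str(OUTDIR), seed=1)
    run_stage("integrate", config)
    run_stage("report", config)
    s = json.loads((OUTDIR / "regression.json").read_text())
    print(f"joined {s['n_joined']} transcript/protein pairs")
    print("coordination classes:", json.dumps(s["coordination"]))
    reg = s["regression"]
    if "slope" in reg:
        print(
            f"concordance fit over {reg['n_points']} strongly-changing proteins: "
            f"log2[protein] = {reg['slope']:.2f} * log2[transcript] "
            f"{reg['intercept']:+.2f}  (r^2 = {reg['r_squared']:.2f})"
        )
    else:
        print("concordance fit unavailable:", reg["error"])
    print(f"full report: {OUTDIR / 'report.txt'}")


if __name__ == "__main__":
    main()
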