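"""Transcript-protein integration: join, coordination classes, concordance fit.

Both fold-change axes are log2(deficient:replete). Transcript folds default to
the tpm display convention (0.5 pseudocounts on raw counts); a flag switches
to the posterior mean delta_hat. The concordance regression is ordinary least
squares of protein fold on transcript fold, restricted to proteins changing
at least ``min_fold``-fold in either direction (filter on the protein axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "COORDINATION_CLASSES",
    "RegressionFit",
    "join_results",
    "classify_coordination",
    "concordance_regression",
]

COORDINATION_CLASSES = (
    "both_up",
    "both_down",
    "protein_only_up",
    "protein_only_down",
    "transcript_only",
    "opposing",
    "neither",
)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if self.n_points < 2:
            raise ValueError("regression needs at least 2 points")


def _coordination(t_fold: float, p_fold: float, t_sig: bool, p_sig: bool) -> str:
    up = lambda f: f >= 0  # zero fold with a significance flag counts as up
    if t_sig and p_sig:
        if up(t_fold) and up(p_fold):
            return "both_up"
        if not up(t_fold) and not up(p_fold):
            return "both_down"
        return "opposing"
    if p_sig:
        return "protein_only_up" if up(p_fold) else "protein_only_down"
    if t_sig:
        return "transcript_only"
    return "neither"


def join_results(
    transcript_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    use_posterior_delta: bool = False,
) -> pd.DataFrame:
    """Inner-join transcript and protein results on the shared identifier.

    ``transcript_de`` comes from :func:`tagomics.dge.de_table`; ``protein_de``
    from :func:`tagomics.proteomics.fisher_differential`. Unmatched-side
    tallies are attached as ``.attrs``.
    """
    if transcript_de["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in transcript results")
    if protein_de["protein_id"].duplicated().any():
        raise ValueError("duplicate protein_id in protein results")
    t_fold_col = "delta_hat" if use_posterior_delta else "display_log2fc"
    t = transcript_de[["gene_id", t_fold_col, "significant"]].rename(
        columns={t_fold_col: "t_fold", "significant": "t_sig"}
    )
    p = protein_de[["protein_id", "fold", "significant"]].rename(
        columns={"protein_id": "gene_id", "fold": "p_fold", "significant": "p_sig"}
    )
    joined = t.merge(p, on="gene_id", how="inner")
    joined["coordination"] = [
        _coordination(r.t_fold, r.p_fold, bool(r.t_sig), bool(r.p_sig))
        for r in joined.itertuples()
    ]
    joined.attrs["n_transcript_only_ids"] = len(t) - len(joined)
    joined.attrs["n_protein_only_ids"] = len(p) - len(joined)
    return joined


def classify_coordination(records: pd.DataFrame) -> dict[str, int]:
    """Counts per coordination class; the counts partition the join."""
    counts = {c: 0 for c in COORDINATION_CLASSES}
    for c in records["coordination"]:
        counts[c] += 1
    return counts


def concordance_regression(records: pd.DataFrame, min_fold: float = 2.0) -> RegressionFit:
    """OLS of protein fold on transcript fold over strongly-changing proteins.

    Keeps records with |p_fold| >= log2(min_fold); errors if fewer than two
    remain or the transcript folds are degenerate.
    """
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")
    sel = records[np.abs(records["p_fold"]) >= np.log2(min_fold)]
    if len(sel) < 2:
        raise ValueError(
            f"only {len(sel)} records pass the {min_fold}-fold protein filter; "
            "need at least 2"
        )
    x = sel["t_fold"].to_numpy(dtype=float)
    y = sel["p_fold"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all transcript folds identical")
    fit = linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(sel),
    )
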