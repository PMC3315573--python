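"""Spectral-count differential protein abundance.

Proteins are quantified by spectral counts in two conditions. The pipeline
(i) drops proteins supported by fewer than two distinct tryptic peptides,
(ii) scales counts so both samples have equal totals (the mean of the raw
totals — the standard spectral-counting normalization), and (iii) tests each
protein with a two-sided Fisher exact test on the raw 2x2 table
[s1, T1-s1; s2, T2-s2], calling significance at p < 0.05 (uncorrected, as is
conventional for spectral counting; a Benjamini-Hochberg q column is emitted
for information only). Fold changes are displayed from normalized counts with
0.5 pseudocounts, oriented condition2:condition1 (deficient:replete).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import false_discovery_control

__all__ = [
    "ProteinCountTable",
    "read_protein_table",
    "filter_by_peptides",
    "normalize_spectral_counts",
    "fisher_two_sided",
    "fisher_differential",
]


@dataclass(frozen=True)
class ProteinCountTable:
    """Spectral counts per protein with whole-experiment totals.

    ``data`` columns: protein_id, peptides, s1, s2 (and s1_norm/s2_norm after
    normalization). ``t1``/``t2`` are the raw library totals captured when the
    table was first constructed; they survive peptide filtering so the Fisher
    complements stay whole-library.
    """

    data: pd.DataFrame
    t1: int
    t2: int

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProteinCountTable":
        required = {"protein_id", "peptides", "s1", "s2"}
        if not required.issubset(df.columns):
            raise ValueError(f"protein table needs columns {sorted(required)}")
        if (df[["peptides", "s1", "s2"]] < 0).to_numpy().any():
            raise ValueError("negative counts in protein table")
        if df["protein_id"].duplicated().any():
            raise ValueError("duplicate protein_id in protein table")
        return cls(df.reset_index(drop=True), int(df["s1"].sum()), int(df["s2"].sum()))


def read_protein_table(path: str | os.PathLike) -> ProteinCountTable:
    df = pd.read_csv(path, sep="\t")
    return ProteinCountTable.from_frame(df)


def filter_by_peptides(
    table: ProteinCountTable, min_peptides: int = 2
) -> ProteinCountTable:
    """Drop proteins with fewer than ``min_peptides`` distinct peptide IDs."""
    kept = table.data[table.data["peptides"] >= min_peptides].reset_index(drop=True)
    out = replace(table, data=kept)
    out.data.attrs["n_removed"] = len(table.data) - len(kept)
    return out


def normalize_spectral_counts(table: ProteinCountTable) -> ProteinCountTable:
    """Scale each sample's counts so column totals equal the mean raw total."""
    if table.t1 <= 0 or table.t2 <= 0:
        raise ValueError("cannot normalize a sample with zero total spectral counts")
    target = (table.t1 + table.t2) / 2.0
    df = table.data.copy()
    df["s1_norm"] = df["s1"] * (target / table.t1)
    df["s2_norm"] = df["s2"] * (target / table.t2)
    return replace(table, data=df)


def fisher_two_sided(s1: int, f1: int, s2: int, f2: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [s1, f1; s2, f2].

    Sums hypergeometric probabilities not exceeding that of the observed
    table (with a 1+1e-7 relative guard against floating-point ties). The
    pmf over the support comes from the log-space term recurrence, so large
    margins (whole-library complements) stay fast and stable.
    """
    if min(s1, f1, s2, f2) < 0:
        raise ValueError("negative cell in 2x2 table")
    col1, row1, row2 = s1 + s2, s1 + f1, s2 + f2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    k = np.arange(lo, hi)
    # pmf(k+1)/pmf(k) for the hypergeometric with these margins
    log_ratio = np.log((row1 - k) * (col1 - k)) - np.log(
        (k + 1.0) * (row2 - col1 + k + 1.0)
    )
    log_pmf = np.concatenate(([0.0], np.cumsum(log_ratio)))
    log_pmf -= logsumexp(log_pmf)
    pmf = np.exp(log_pmf)
    p_obs = pmf[s1 - lo]
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def fisher_differential(table: ProteinCountTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein two-sided Fisher exact test on raw counts.

    The test uses raw integer counts against whole-library complements; fold
    changes come from normalized counts (0.5 pseudocounts), oriented
    condition2:condition1. Up/down tallies of significant proteins are
    attached as ``.attrs['n_up']`` / ``.attrs['n_down']``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = table.data
    if "s1_norm" not in df.columns:
        df = normalize_spectral_counts(table).data
    s1 = df["s1"].to_numpy(dtype=np.int64)
    s2 = df["s2"].to_numpy(dtype=np.int64)
    if table.t1 - s1.max(initial=0) < 0 or table.t2 - s2.max(initial=0) < 0:
        raise ValueError("negative margins: protein counts exceed library totals")
    pvals = np.array(
        [
            fisher_two_sided(a, table.t1 - a, b, table.t2 - b)
            for a, b in zip(s1, s2)
        ]
    )
    out = pd.DataFrame(
        {
            "protein_id": df["protein_id"].to_numpy(),
            "peptides": df["peptides"].to_numpy(),
            "s1": s1,
            "s2": s2,
            "s1_norm": df["s1_norm"].to_numpy(),
            "s2_norm": df["s2_norm"].to_numpy(),
            "fold": np.log2(
                (df["s2_norm"].to_numpy() + 0.5) / (df["s1_norm"].to_numpy() + 0.5)
            ),
            "p": pvals,
        }
    )
    out["q_bh"] = false_discovery_control(pvals) if len(pvals) else pvals
    out["significant"] = out["p"] < alpha
    sig = out[out["significant"]]
    out.attrs["n_up"] = int((sig["fold"] > 0).sum())
    out.attrs["n_down"] = int((sig["fold"] < 0).sum())
    return out
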