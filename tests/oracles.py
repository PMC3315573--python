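"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (window scans, direct summation, exact
rational arithmetic) and shares no code with the package internals beyond
elementary helpers.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def scan_catg_positions(seq: str) -> list[int]:
    """Exhaustive sliding-window scan for CATG."""
    return [i for i in range(len(seq) - 3) if seq[i : i + 4] == "CATG"]


def scan_tag_locations(genome: dict[str, str], tag: str) -> list[tuple[str, int, str]]:
    """All exact locations of a 21-mer tag on either strand, by window scan.

    Locations use the convention (chrom, forward-axis position of the CATG
    site's first base, strand).
    """
    locs = []
    rc = revcomp(tag)
    for chrom, seq in genome.items():
        for i in range(len(seq) - 20):
            window = seq[i : i + 21]
            if window == tag:
                locs.append((chrom, i, "+"))
            if window == rc:
                # reverse-strand tag anchored at the CATG ending this window
                locs.append((chrom, i + 17, "-"))
    return locs


def enumerate_expected_tags(transcript: str) -> list[tuple[int, str]]:
    """(rank from 3', padded 21-mer) for every CATG site, by direct windowing."""
    sites = scan_catg_positions(transcript)
    out = []
    for rank, pos in enumerate(reversed(sites), start=1):
        window = transcript[pos : pos + 21]
        out.append((rank, window + "A" * (21 - len(window))))
    return out


def posterior_integrate(
    x1: int, x2: int, n1: float, n2: float, pi0: float, tau: float, grid: np.ndarray
) -> tuple[float, float, float]:
    """Direct-summation posterior over the spike+slab grid prior.

    Returns (posterior mean, posterior SD without flooring, spike mass).
    Uses plain binomial pmf products, no log-space tricks.
    """
    n = x1 + x2

    def binom_pmf(k, size, p):
        return comb(size, k) * p**k * (1 - p) ** (size - k)

    weights = np.exp(-0.5 * (grid / tau) ** 2)
    weights = weights / weights.sum()
    lik = np.array(
        [binom_pmf(x1, n, n1 / (n1 + n2 * 2.0**d)) for d in grid], dtype=float
    )
    zero = int(np.argmin(np.abs(grid)))
    spike = pi0 * lik[zero]
    slab = (1 - pi0) * weights * lik
    total = spike + slab.sum()
    mean = float((slab * grid).sum() / total)
    second = float((slab * grid**2).sum() / total)
    sd = float(np.sqrt(max(second - mean**2, 0.0)))
    return mean, sd, float(spike / total)


def fisher_exact_enumeration(s1: int, f1: int, s2: int, f2: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration in exact
    rational arithmetic (sum of table probabilities <= the observed one)."""
    col1, row1, row2 = s1 + s2, s1 + f1, s2 + f2
    denom = comb(row1 + row2, col1)
    p_obs = Fraction(comb(row1, s1) * comb(row2, s2), denom)
    total = Fraction(0)
    for k in range(max(0, col1 - row2), min(col1, row1) + 1):
        p_k = Fraction(comb(row1, k) * comb(row2, col1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)
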