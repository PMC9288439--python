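"""Annotation and partitioned-heritability enrichment calculi."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = ["EnrichmentTable", "fisher_enrichment", "partition_enrichment"]


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 counts: (in-category annotated, in-category not, background
    annotated, background not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")


def fisher_enrichment(table: EnrichmentTable) -> tuple[float, float, bool]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p_two_sided, haldane_applied)``.  The odds ratio
    is (a*d)/(b*c), with the Haldane correction (0.5 added to every cell)
    applied — and flagged — iff any cell is zero.  The two-sided P sums the
    hypergeometric probabilities of all tables, with the observed margins,
    at most as probable as the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("degenerate 2x2 table: a margin is zero")
    haldane = 0 in (a, b, c, d)
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p), haldane


def partition_enrichment(prop_h2: float, prop_snps: float) -> float:
    """Heritability enrichment of a genomic category: its share of SNP
    heritability divided by its share of SNPs.  Values below 1 indicate
    depletion."""
    if prop_snps <= 0:
        raise ValueError("prop_snps must be positive")
    if prop_h2 < 0:
        warnings.warn("negative heritability proportion; estimate unstable",
                      stacklevel=2)
    return prop_h2 / prop_snps
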