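"""LD clumping and genomic risk locus definition.

Follows the standard post-GWAS locus construction: genome-wide significant
SNPs that are mutually near-independent (r^2 < 0.6) are "independent
significant" SNPs; a stricter r^2 < 0.1 pass among those yields "lead" SNPs;
SNPs in LD (r^2 >= 0.6) with an independent significant SNP, at suggestive P
and adequate MAF, are "candidate" SNPs; candidate spans seed LD blocks which
are merged (r^2 >= 0.1 between independent SNPs, or block gap <= 250 kb) into
genomic risk loci, each represented by its lowest-P member lead SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ld import LdMatrix
from .sumstats import SumStatsTable

__all__ = [
    "ClumpResult",
    "GenomicLocus",
    "independent_significant",
    "lead_snps",
    "candidate_snps",
    "define_loci",
    "clump",
]

GWS_P = 5e-8


@dataclass
class ClumpResult:
    """Clumping output: the three SNP tiers plus candidate assignments."""

    independent_significant: set[str]
    lead: set[str]
    candidate: set[str]
    assignments: dict[str, set[str]]  # candidate -> independent significant SNP(s)


@dataclass
class GenomicLocus:
    locus_id: int
    lead_snp: str
    chrom: str
    start: int
    end: int
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start after end")
        if self.lead_snp not in self.members:
            raise ValueError("lead SNP not among locus members")


def _ordered_by_p(sumstats: SumStatsTable, snp_ids) -> list[str]:
    """Ascending-P order with ties broken by (chrom, pos, snp_id)."""
    sub = sumstats.df[sumstats.df["SNP"].isin(set(snp_ids))]
    from .sumstats import _chrom_sort_key

    key = sorted(
        zip(sub["P"], sub["CHR"].map(_chrom_sort_key), sub["BP"], sub["SNP"]),
    )
    return [s for _, _, _, s in key]


def _greedy_select(order: list[str], ld: LdMatrix, r2_cut: float) -> set[str]:
    selected: list[str] = []
    for snp in order:
        if snp not in ld:
            raise KeyError(f"SNP {snp} absent from LD matrix")
        if all(ld.r2_between(snp, s) < r2_cut for s in selected):
            selected.append(snp)
    return set(selected)


def independent_significant(
    sumstats: SumStatsTable,
    ld: LdMatrix,
    gws_p: float = GWS_P,
    r2_indep: float = 0.6,
) -> set[str]:
    """Greedily select genome-wide significant SNPs mutually at r^2 < ``r2_indep``.

    Selection runs in ascending-P order; a GWS SNP is kept iff its r^2 with
    every previously kept SNP is below the cut-off.
    """
    gws = sumstats.df.loc[sumstats.df["P"] < gws_p, "SNP"].tolist()
    return _greedy_select(_ordered_by_p(sumstats, gws), ld, r2_indep)


def lead_snps(
    independent: set[str],
    ld: LdMatrix,
    sumstats: SumStatsTable,
    r2_lead: float = 0.1,
) -> set[str]:
    """Second, stricter greedy pass (r^2 < ``r2_lead``) among independent
    significant SNPs."""
    return _greedy_select(_ordered_by_p(sumstats, independent), ld, r2_lead)


def candidate_snps(
    sumstats: SumStatsTable,
    ld: LdMatrix,
    independent: set[str],
    p_max: float = 1e-5,
    maf_min: float = 0.005,
    r2_min: float = 0.6,
):
    """SNPs in LD with an independent significant SNP at suggestive P.

    A SNP is a candidate iff r^2 >= ``r2_min`` with at least one independent
    significant SNP, P < ``p_max`` and MAF > ``maf_min``.  Returns the
    candidate set and a map candidate -> qualifying independent SNPs.
    """
    if not independent:
        raise ValueError("independent significant SNP set is empty")
    candidates: set[str] = set()
    assignments: dict[str, set[str]] = {}
    d = sumstats.df
    for snp, p, maf in zip(d["SNP"], d["P"], d["MAF"]):
        if snp not in ld:
            continue
        if not (p < p_max and maf > maf_min):
            continue
        hits = {i for i in independent if ld.r2_between(snp, i) >= r2_min}
        if hits:
            candidates.add(snp)
            assignments[snp] = hits
    return candidates, assignments


def define_loci(
    leads: set[str],
    independent: set[str],
    candidates: set[str],
    assignments: dict[str, set[str]],
    ld: LdMatrix,
    sumstats: SumStatsTable,
    merge_kb: float = 250.0,
) -> list[GenomicLocus]:
    """Merge per-independent-SNP LD blocks into genomic risk loci.

    Each independent significant SNP seeds a block spanning the positions of
    its assigned candidates (itself included).  Blocks are united — by
    union-find transitive closure — when their independent SNPs share
    r^2 >= 0.1 or when their spans on the same chromosome lie within
    ``merge_kb`` kilobases of each other.  Each locus reports the member lead
    SNP with lowest P and the union span.
    """
    if not leads:
        return []
    pos = dict(zip(sumstats.df["SNP"], sumstats.df["BP"]))
    chrom = dict(zip(sumstats.df["SNP"], sumstats.df["CHR"]))
    pvals = dict(zip(sumstats.df["SNP"], sumstats.df["P"]))

    indep = sorted(independent, key=lambda s: (pvals[s], pos[s], s))
    members: dict[str, set[str]] = {i: {i} for i in indep}
    for cand, hit_set in assignments.items():
        for i in hit_set:
            if i in members:
                members[i].add(cand)
    span = {
        i: (min(pos[s] for s in members[i]), max(pos[s] for s in members[i]))
        for i in indep
    }

    parent = {i: i for i in indep}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    gap_bp = merge_kb * 1000.0
    for ai in range(len(indep)):
        for bi in range(ai + 1, len(indep)):
            a, b = indep[ai], indep[bi]
            if ld.r2_between(a, b) >= 0.1:
                union(a, b)
            elif chrom[a] == chrom[b]:
                (s1, e1), (s2, e2) = span[a], span[b]
                gap = max(s1, s2) - min(e1, e2)  # <= 0 when spans overlap
                if gap <= gap_bp:
                    union(a, b)

    groups: dict[str, list[str]] = {}
    for i in indep:
        groups.setdefault(find(i), []).append(i)

    loci = []
    ordered = sorted(
        groups.values(), key=lambda g: (min(span[i][0] for i in g), chrom[g[0]])
    )
    from .sumstats import _chrom_sort_key

    ordered.sort(key=lambda g: (_chrom_sort_key(chrom[g[0]]), min(span[i][0] for i in g)))
    for k, group in enumerate(ordered, start=1):
        mem = set().union(*(members[i] for i in group))
        group_leads = [s for s in group if s in leads] or list(group)
        lead = min(group_leads, key=lambda s: (pvals[s], pos[s], s))
        loci.append(
            GenomicLocus(
                locus_id=k,
                lead_snp=lead,
                chrom=chrom[group[0]],
                start=int(min(span[i][0] for i in group)),
                end=int(max(span[i][1] for i in group)),
                members=mem,
            )
        )
    return loci


def clump(
    sumstats: SumStatsTable,
    ld: LdMatrix,
    gws_p: float = GWS_P,
    r2_indep: float = 0.6,
    r2_lead: float = 0.1,
    p_cand: float = 1e-5,
    maf_min: float = 0.005,
    merge_kb: float = 250.0,
):
    """Full pipeline: tiers + loci.  Returns ``(ClumpResult, [GenomicLocus])``."""
    indep = independent_significant(sumstats, ld, gws_p=gws_p, r2_indep=r2_indep)
    if not indep:
        return ClumpResult(set(), set(), set(), {}), []
    leads = lead_snps(indep, ld, sumstats, r2_lead=r2_lead)
    cands, assign = candidate_snps(
        sumstats, ld, indep, p_max=p_cand, maf_min=maf_min, r2_min=r2_indep
    )
    result = ClumpResult(indep, leads, cands | indep,
                         {**assign, **{i: {i} for i in indep}})
    loci = define_loci(leads, indep, result.candidate, result.assignments,
                       ld, sumstats, merge_kb=merge_kb)
    return result, loci
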