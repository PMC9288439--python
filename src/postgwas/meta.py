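"""Sample-overlap-aware Z-score meta-analysis of GWAS summary statistics.

Case-control studies are weighted by effective sample size
``N_eff = 4 / (1/N_cas + 1/N_con)``; overlap between a pair of studies is
estimated from the cross-trait LD-score-regression intercept as
``N_overlap = i_bivariate * sqrt(N1 * N2)``.  Per variant, signed Z scores
aligned to a common effect allele are combined as

    Z_meta = sum_i w_i Z_i / sqrt(sum_i w_i^2 + 2 sum_{i<j} w_i w_j rho_ij)

with ``w_i = sqrt(N_eff,i)`` and ``rho_ij`` the cross-study intercept — the
correlation induced among null Z statistics by shared subjects.  With no
overlap and equal weights this reduces to the unweighted Stouffer combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStatsTable

__all__ = [
    "StudyMeta",
    "OverlapMatrix",
    "effective_n",
    "overlap_n",
    "shared_h2",
    "align_and_filter",
    "meta_z",
    "meta_analyse",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class StudyMeta:
    """Per-study sample accounting."""

    label: str
    n_cases: int | None = None
    n_controls: int | None = None
    n_total: int | None = None
    neff: float | None = None

    def __post_init__(self) -> None:
        if self.neff is None and self.n_cases and self.n_controls:
            self.neff = effective_n(self.n_cases, self.n_controls)
        if self.n_total is None and self.n_cases and self.n_controls:
            self.n_total = self.n_cases + self.n_controls
        if self.neff is None and self.n_total is not None:
            self.neff = float(self.n_total)  # quantitative trait: N_eff = N
        if self.neff is None:
            raise ValueError(f"study {self.label}: no sample size information")
        if self.n_total is not None and self.neff > self.n_total + 1e-9:
            raise ValueError(f"study {self.label}: neff exceeds total N")


@dataclass
class OverlapMatrix:
    """Pairwise cross-study intercepts and implied overlap counts."""

    labels: list[str]
    i_bivariate: np.ndarray

    def __post_init__(self) -> None:
        self.i_bivariate = np.asarray(self.i_bivariate, float)
        k = len(self.labels)
        if self.i_bivariate.shape != (k, k):
            raise ValueError("intercept matrix shape mismatch")
        if np.max(np.abs(self.i_bivariate - self.i_bivariate.T)) > 1e-10:
            raise ValueError("intercept matrix must be symmetric")


def effective_n(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control study:
    ``4 / (1/N_cas + 1/N_con)``, at most N_cas + N_con (equality iff
    balanced)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def overlap_n(i_bivariate: float, n1: float, n2: float) -> float:
    """Shared-subject count implied by a cross-trait intercept:
    ``i * sqrt(N1 * N2)``, clipped to [0, min(N1, N2)] with a warning."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    raw = i_bivariate * np.sqrt(n1 * n2)
    hi = min(n1, n2)
    if raw < 0 or raw > hi:
        warnings.warn(
            f"implied overlap {raw:.1f} outside [0, {hi}]; clipping",
            stacklevel=2,
        )
    return float(np.clip(raw, 0.0, hi))


def shared_h2(rg: float, h2_1: float, h2_2: float) -> float:
    """Shared SNP heritability: ``rg * sqrt(h2_1 * h2_2)`` (sign follows the
    genetic correlation; local rg estimates may fall outside [-1, 1])."""
    if h2_1 < 0 or h2_2 < 0:
        raise ValueError("heritabilities must be non-negative (clip unstable "
                         "local estimates before calling)")
    return float(rg * np.sqrt(h2_1 * h2_2))


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def align_and_filter(
    tables: list[SumStatsTable],
    mac_min: float = 100.0,
    min_presence: int | None = None,
    drop_ambiguous: bool = False,
):
    """Intersect, allele-align and MAC-filter variants across studies.

    A variant is kept in a study when its minor allele count
    ``MAC = 2 * N * MAF`` is at least ``mac_min``; it enters the meta-analysis
    when it survives in at least ``min_presence`` studies (default: all).
    Alleles are aligned to the first table carrying the variant, flipping the
    Z sign on A1/A2 swaps (with or without strand complement); unalignable
    variants are dropped and logged; strand-ambiguous (A/T, C/G) variants are
    flagged and, by default, retained.

    Returns a DataFrame indexed by SNP with one signed-Z column per study
    (NaN where absent), plus a log dict.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 studies")
    if min_presence is None:
        min_presence = len(tables)
    ref_alleles: dict[str, tuple[str, str]] = {}
    z_cols: list[dict[str, float]] = []
    log = {"mac_dropped": 0, "unalignable": [], "ambiguous": set()}
    for table in tables:
        d = table.df
        z_signed = np.sign(d["BETA"].to_numpy()) * stats.norm.isf(
            d["P"].to_numpy() / 2.0
        )
        col: dict[str, float] = {}
        for snp, a1, a2, maf, n, z in zip(
            d["SNP"], d["A1"], d["A2"], d["MAF"], d["N"], z_signed
        ):
            if pd.isna(maf) or 2.0 * n * maf < mac_min:
                log["mac_dropped"] += 1
                continue
            a1u, a2u = str(a1).upper(), str(a2).upper()
            if _is_ambiguous(a1u, a2u):
                log["ambiguous"].add(snp)
                if drop_ambiguous:
                    continue
            if snp not in ref_alleles:
                ref_alleles[snp] = (a1u, a2u)
                col[snp] = z
                continue
            r1, r2 = ref_alleles[snp]
            f1, f2 = _COMPLEMENT.get(a1u, "?"), _COMPLEMENT.get(a2u, "?")
            if (a1u, a2u) == (r1, r2) or (f1, f2) == (r1, r2):
                col[snp] = z
            elif (a2u, a1u) == (r1, r2) or (f2, f1) == (r1, r2):
                col[snp] = -z
            else:
                log["unalignable"].append((table.study_label or "study", snp))
        z_cols.append(col)
    labels = [t.study_label or f"study{i}" for i, t in enumerate(tables)]
    aligned = pd.DataFrame(z_cols, index=labels).T
    aligned = aligned[aligned.notna().sum(axis=1) >= min_presence]
    return aligned, log


def meta_z(
    z_by_study: np.ndarray,
    neff: np.ndarray,
    i_bivariate: np.ndarray | None = None,
):
    """Overlap-corrected weighted-Z combination for one or more variants.

    ``z_by_study`` is (variants x studies), possibly with NaN for absent
    studies; ``neff`` the per-study effective sample sizes; ``i_bivariate``
    the pairwise intercept (correlation) matrix, zero off-diagonal when
    omitted.  Returns ``(z_meta, p_two_sided, n_eff_total)`` arrays.
    """
    z = np.atleast_2d(np.asarray(z_by_study, float))
    neff = np.asarray(neff, float)
    k = z.shape[1]
    if len(neff) != k:
        raise ValueError("neff length mismatch")
    if i_bivariate is None:
        rho = np.zeros((k, k))
    else:
        rho = np.asarray(i_bivariate, float).copy()
    np.fill_diagonal(rho, 0.0)
    w = np.sqrt(neff)
    present = ~np.isnan(z)
    if np.any(present.sum(axis=1) < 2):
        raise ValueError("every variant needs >= 2 studies after filtering")
    wz = np.where(present, z * w, 0.0).sum(axis=1)
    wmask = present * w
    var = (wmask**2).sum(axis=1) + np.einsum("vi,ij,vj->v", wmask, rho, wmask)
    if np.any(var <= 0):
        raise ValueError("non-positive combination variance; check intercepts")
    z_meta = wz / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(z_meta))
    # total N_eff, adjusted down by the estimated pairwise overlaps
    nmat = present * neff
    n_tot = nmat.sum(axis=1).astype(float)
    for i in range(k):
        for j in range(i + 1, k):
            both = present[:, i] & present[:, j]
            n_tot[both] -= np.clip(
                rho[i, j] * np.sqrt(neff[i] * neff[j]), 0.0,
                min(neff[i], neff[j]),
            )
    return z_meta, p, np.maximum(n_tot, 0.0)


def meta_analyse(
    tables: list[SumStatsTable],
    studies: list[StudyMeta],
    overlap: OverlapMatrix | None = None,
    mac_min: float = 100.0,
    min_presence: int | None = None,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Align, filter and combine studies; returns a per-variant table with
    ``Z``, ``P`` and ``N_EFF``."""
    aligned, log = align_and_filter(tables, mac_min=mac_min,
                                    min_presence=min_presence,
                                    drop_ambiguous=drop_ambiguous)
    labels = list(aligned.columns)
    by_label = {s.label: s for s in studies}
    try:
        neff = np.array([by_label[lab].neff for lab in labels])
    except KeyError as exc:
        raise ValueError(f"no StudyMeta for study label {exc.args[0]!r}") from None
    rho = None
    if overlap is not None:
        order = [overlap.labels.index(lab) for lab in labels]
        rho = overlap.i_bivariate[np.ix_(order, order)]
    z_meta, p, n_tot = meta_z(aligned.to_numpy(), neff, rho)
    return pd.DataFrame({"SNP": aligned.index, "Z": z_meta, "P": p,
                         "N_EFF": n_tot}).reset_index(drop=True)
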