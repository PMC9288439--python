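"""Per-SNP summary-statistic records, I/O, and elementary per-study statistics.

A GWAS summary-statistics table holds, per SNP, the unstandardised effect
``B`` (phenotype units per effect allele), its standard error ``SE``, minor
allele frequency, two-sided ``P`` and sample size ``N``.  This module provides
the canonical tab-separated dialect for such tables, effect standardisation to
SD units, the median-absolute-deviation phenotype outlier rule, and Bonferroni
threshold arithmetic.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpRecord",
    "SumStatsTable",
    "PhenotypeVector",
    "standardize_beta",
    "mad_filter",
    "bonferroni_alpha",
    "read_sumstats",
    "write_sumstats",
    "read_phenotype",
    "write_phenotype",
    "CANONICAL_COLUMNS",
]

#: Header of the canonical sumstats dialect (INFO optional).
CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "MAF", "BETA", "SE", "P", "N"]


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's association record.

    ``beta_raw`` is the unstandardised per-allele effect in phenotype units;
    ``maf`` is the minor allele frequency in (0, 0.5]; ``p`` is two-sided.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float
    beta_raw: float
    se: float
    p: float
    n: float
    info: float | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.maf) and not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside (0, 0.5]")
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: SE must be positive, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.snp_id}: P {self.p} outside (0, 1]")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: N must be positive, got {self.n}")

    @property
    def z(self) -> float:
        return self.beta_raw / self.se


class SumStatsTable:
    """Ordered collection of :class:`SnpRecord` for one study.

    Backed by a :class:`pandas.DataFrame` with the canonical column names.
    SNP ids are unique; rows are kept sorted by (CHR, BP).
    """

    def __init__(self, df: pd.DataFrame, study_label: str = "", trait_label: str = ""):
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sumstats table missing columns: {missing}")
        if df["SNP"].duplicated().any():
            dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
            raise ValueError(f"duplicate SNP id in table: {dup}")
        df = df.copy()
        df["CHR"] = df["CHR"].astype(str)
        df["BP"] = df["BP"].astype(np.int64)
        # natural chromosome order where possible, lexicographic otherwise
        key = df["CHR"].map(_chrom_sort_key)
        order = np.lexsort((df["BP"].to_numpy(), key.to_numpy()))
        self.df = df.iloc[order].reset_index(drop=True)
        self.study_label = study_label
        self.trait_label = trait_label
        self._validate()

    def _validate(self) -> None:
        d = self.df
        bad_se = d["SE"] <= 0
        if bad_se.any():
            raise ValueError(f"non-positive SE for {d.loc[bad_se, 'SNP'].iloc[0]}")
        bad_p = ~((d["P"] > 0) & (d["P"] <= 1))
        if bad_p.any():
            raise ValueError(f"P outside (0,1] for {d.loc[bad_p, 'SNP'].iloc[0]}")
        with_maf = d["MAF"].notna()
        bad_maf = with_maf & ~((d["MAF"] > 0) & (d["MAF"] <= 0.5))
        if bad_maf.any():
            raise ValueError(f"MAF outside (0,0.5] for {d.loc[bad_maf, 'SNP'].iloc[0]}")
        if (d["N"] <= 0).any():
            raise ValueError("non-positive N in table")
        # published tables often carry rounded P, so inconsistency only warns
        z = np.abs(d["BETA"] / d["SE"])
        p_implied = 2 * stats.norm.sf(z)
        both = d["P"].notna() & d["BETA"].notna()
        off = both & (np.abs(d["P"] - p_implied) > 0.01) & (p_implied > 1e-300)
        if off.any():
            warnings.warn(
                f"{int(off.sum())} records have P inconsistent with |BETA/SE| "
                f"(e.g. {d.loc[off, 'SNP'].iloc[0]}); keeping P as given",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.df["SNP"])

    def record(self, snp_id: str) -> SnpRecord:
        row = self.df.loc[self.df["SNP"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        r = row.iloc[0]
        info = float(r["INFO"]) if "INFO" in row.columns and pd.notna(r.get("INFO")) else None
        return SnpRecord(
            snp_id=str(r["SNP"]), chrom=str(r["CHR"]), pos=int(r["BP"]),
            effect_allele=str(r["A1"]), other_allele=str(r["A2"]),
            maf=float(r["MAF"]), beta_raw=float(r["BETA"]), se=float(r["SE"]),
            p=float(r["P"]), n=float(r["N"]), info=info,
        )

    def records(self):
        for snp in self.df["SNP"]:
            yield self.record(snp)


@dataclass
class PhenotypeVector:
    """Per-subject phenotype values (e.g. cerebellar volume in mm^3)."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.subject_ids:
            self.subject_ids = [f"S{i}" for i in range(len(self.values))]
        if len(self.subject_ids) != len(self.values):
            raise ValueError("subject_ids and values differ in length")


def _chrom_sort_key(c: str) -> int:
    c = str(c).removeprefix("chr")
    if c.isdigit():
        return int(c)
    return {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}.get(c, 99)


def standardize_beta(beta_raw: float, se: float, maf: float, n: float) -> float:
    """Standardise an unstandardised GWAS effect to SD units.

    With ``Z = beta_raw / se``, returns

        Z / sqrt(2 * MAF * (1 - MAF) * (N + Z^2))

    which is the per-allele effect expressed in phenotype standard deviations.

    Parameters
    ----------
    beta_raw : unstandardised effect (phenotype units per effect allele).
    se : its standard error, > 0.
    maf : minor allele frequency in (0, 0.5].
    n : sample size, >= 1.
    """
    beta_raw = np.asarray(beta_raw, dtype=float)
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    z = beta_raw / se
    out = z / np.sqrt(2.0 * maf * (1.0 - maf) * (n + z**2))
    return float(out) if out.ndim == 0 else out


def mad_filter(values: Sequence[float], k: float = 3.0, scale: bool = True):
    """Flag values more than ``k`` median absolute deviations from the median.

    Returns ``(retained_idx, removed_idx)`` partitioning ``range(len(values))``.
    By default the MAD carries the normal-consistency constant 1.4826 (the
    convention of R's ``mad()``), under which a k = 3 fence removes ~0.27%
    of a normal sample — the regime of the ~0.4% exclusion rate reported for
    the cerebellar-volume phenotype.  ``scale=False`` uses the raw median of
    absolute deviations.

    If the MAD is zero and the input is not constant, every value differing
    from the median is removed and a warning is emitted.
    """
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 3:
        raise ValueError("mad_filter needs at least 3 finite values")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if scale:
        mad *= 1.4826
    if mad == 0:
        removed = dev > 0
        if removed.any():
            warnings.warn(
                "MAD is zero with non-constant input; removing every value "
                "that differs from the median",
                stacklevel=2,
            )
    else:
        removed = dev > k * mad
    idx = np.arange(len(x))
    return idx[~removed], idx[removed]


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted significance threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


# ---------------------------------------------------------------------------
# I/O: canonical tab-separated dialect


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sumstats(path, study_label: str = "", trait_label: str = "") -> SumStatsTable:
    """Read a canonical-dialect sumstats file (tab-separated, ``NA`` missing,
    gzip transparently supported)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"],
                         float_precision="round_trip")
    return SumStatsTable(df, study_label=study_label, trait_label=trait_label)


def write_sumstats(table: SumStatsTable, path) -> None:
    cols = list(CANONICAL_COLUMNS)
    if "INFO" in table.df.columns:
        cols.append("INFO")
    out = table.df[cols].copy()
    # shortest round-trip repr so read(write(x)) is bit-exact
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_phenotype(path) -> PhenotypeVector:
    """Read a tab-separated ``ID\\tVALUE`` phenotype file."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs ID and VALUE columns")
    return PhenotypeVector(values=df.iloc[:, 1].to_numpy(float),
                           subject_ids=[str(s) for s in df.iloc[:, 0]])


def write_phenotype(pheno: PhenotypeVector, path) -> None:
    pd.DataFrame({"ID": pheno.subject_ids, "VALUE": pheno.values}).to_csv(
        path, sep="\t", index=False
    )
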