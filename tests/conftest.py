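import numpy as np
import pandas as pd
import pytest

from postgwas import LdMatrix, SumStatsTable


def make_sumstats(snps, study_label="toy"):
    """Build a SumStatsTable from (snp, chrom, pos, maf, p) tuples or dicts.

    Betas/SEs are derived from P (two-sided normal) with positive sign unless
    a beta sign is supplied.
    """
    from scipy import stats

    rows = []
    for s in snps:
        if isinstance(s, dict):
            row = dict(s)
        else:
            snp, chrom, pos, maf, p = s
            row = {"SNP": snp, "CHR": chrom, "BP": pos, "MAF": maf, "P": p}
        row.setdefault("A1", "A")
        row.setdefault("A2", "G")
        row.setdefault("N", 10_000)
        z = stats.norm.isf(row["P"] / 2)
        row.setdefault("SE", 1.0)
        row.setdefault("BETA", row.get("sign", 1) * z * row["SE"])
        row.pop("sign", None)
        rows.append(row)
    return SumStatsTable(pd.DataFrame(rows), study_label=study_label)


def make_ld(snp_ids, pairs, default=0.0):
    """LdMatrix from a dict {(a, b): r2}; unlisted off-diagonals = default."""
    n = len(snp_ids)
    index = {s: i for i, s in enumerate(snp_ids)}
    r2 = np.full((n, n), default, dtype=float)
    np.fill_diagonal(r2, 1.0)
    for (a, b), v in pairs.items():
        r2[index[a], index[b]] = r2[index[b], index[a]] = v
    return LdMatrix(snp_ids, r2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def abc_instance():
    """The three-SNP hand-traceable clumping instance."""
    table = make_sumstats([
        ("A", "1", 1000, 0.3, 1e-10),
        ("B", "1", 2000, 0.3, 1e-9),
        ("C", "1", 3000, 0.3, 1e-8 * 0.99),
    ])
    ld = make_ld(["A", "B", "C"], {("A", "B"): 0.8, ("A", "C"): 0.2,
                                   ("B", "C"): 0.3})
    return table, ld
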