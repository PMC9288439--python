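"""Synthetic inputs for every pipeline stage.

Summary statistics are simulated directly in Z-score space under a
spike-and-slab (point-normal) architecture: a SNP is causal with probability
``pi`` and its standardised effect is N(0, sigma_beta2).  Within an LD block
with signed allelic correlation matrix R the marginal Z scores are

    Z ~ MVN(R (sqrt(N) beta_true), R)

the standard distribution of marginal association statistics under LD.
Unstandardised betas and standard errors are back-transformed through the
inverse of the SD-unit standardisation so the tables round-trip.  Defaults
follow the cerebellar-volume study design: discovery N = 27,486, replication
N = 3,906, polygenicity pi = 4.36e-4, discoverability sigma_beta2 = 3.60e-4,
phenotype mean 143,580 mm^3 and SD 14,231 mm^3.

The generator emulates the statistical structure the analyses assume —
LD-block correlation, discovery/replication independence given the true
effects, optional shared subjects — not real genotype panels or imaging
phenotype distributions beyond their first two moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LdMatrix
from .sumstats import PhenotypeVector, SumStatsTable
from .temporal import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_ld_blocks",
    "simulate_sumstats",
    "simulate_gene_level",
    "simulate_phenotype_with_outliers",
    "simulate_lead_snp_pairs",
    "DEFAULT_TIMEPOINTS",
]


@dataclass
class SimulationConfig:
    """Knobs of the summary-statistic simulator.

    ``pi`` and ``sigma_beta2`` default to the study's point-normal mixture
    estimates for cerebellar volume; sample sizes to its discovery and
    replication N.
    """

    m_snps: int = 50_000
    n_disc: int = 27_486
    n_rep: int = 3_906
    pi: float = 4.36e-4
    sigma_beta2: float = 3.60e-4
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_block_sizes: int | list[int] = 20
    ld_decay: float = 0.25
    seed: int = 0
    overlap_fraction: float = 0.0
    pheno_mean: float = 143_580.0
    pheno_sd: float = 14_231.0

    def __post_init__(self) -> None:
        if not (0 <= self.pi <= 1):
            raise ValueError("pi must lie in [0, 1]")
        if self.sigma_beta2 <= 0:
            raise ValueError("sigma_beta2 must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")

    def block_sizes(self) -> list[int]:
        if isinstance(self.ld_block_sizes, int):
            size = self.ld_block_sizes
            if size < 1:
                raise ValueError("block size must be >= 1")
            n_full, rem = divmod(self.m_snps, size)
            return [size] * n_full + ([rem] if rem else [])
        return list(self.ld_block_sizes)


@dataclass
class SimulatedTruth:
    """Ground truth behind a simulated summary-statistic pair."""

    causal: np.ndarray           # bool per SNP
    beta_true: np.ndarray        # standardised effects
    block_of: np.ndarray         # block index per SNP
    maf: np.ndarray = field(default=None)


def _signed_block_corr(size: int, decay: float) -> np.ndarray:
    """AR(1)-style signed allelic correlation, rho = exp(-decay)."""
    if size < 1:
        raise ValueError("block size must be >= 1")
    rho = np.exp(-decay)
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_blocks(config: SimulationConfig) -> list[LdMatrix]:
    """Per-block r^2 matrices: exponentially decaying within-block
    correlation, zero across blocks, positive semi-definite by construction."""
    blocks = []
    offset = 0
    for size in config.block_sizes():
        corr = _signed_block_corr(size, config.ld_decay)
        ids = [f"rs{offset + i}" for i in range(size)]
        blocks.append(LdMatrix(ids, corr**2))
        offset += size
    return blocks


def _sumstats_from_z(z, maf, n, chrom, pos, snp_ids, pheno_sd, label):
    z = np.asarray(z, float)
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    se = pheno_sd / np.sqrt(2 * maf * (1 - maf) * (n + z**2))
    beta = z * se
    df = pd.DataFrame({
        "SNP": snp_ids, "CHR": chrom, "BP": pos,
        "A1": "A", "A2": "G", "MAF": maf,
        "BETA": beta, "SE": se, "P": p, "N": float(n),
    })
    return SumStatsTable(df, study_label=label)


def simulate_sumstats(config: SimulationConfig):
    """Simulate a discovery/replication summary-statistic pair.

    Returns ``(discovery, replication, truth, ld_blocks)``.  The two studies
    share the true effects; their noise is independent unless
    ``overlap_fraction`` > 0, in which case shared subjects induce a noise
    correlation ``N_overlap / sqrt(N_disc * N_rep)`` with
    ``N_overlap = overlap_fraction * min(N_disc, N_rep)``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.block_sizes()
    m = sum(sizes)
    causal = rng.random(m) < config.pi
    beta_true = np.where(causal, rng.normal(0.0, np.sqrt(config.sigma_beta2), m), 0.0)
    maf = rng.uniform(*config.maf_range, size=m)

    n_ov = config.overlap_fraction * min(config.n_disc, config.n_rep)
    rho = n_ov / np.sqrt(config.n_disc * config.n_rep)

    z_disc = np.empty(m)
    z_rep = np.empty(m)
    block_of = np.empty(m, dtype=int)
    starts_all = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    for bi, (size, start) in enumerate(zip(sizes, starts_all)):
        block_of[start:start + size] = bi
    # batch blocks of equal size: one Cholesky and one matmul per size class
    sizes_arr = np.asarray(sizes)
    for size in np.unique(sizes_arr):
        which = np.flatnonzero(sizes_arr == size)
        corr = _signed_block_corr(int(size), config.ld_decay)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(int(size)))
        idx = (starts_all[which][:, None] + np.arange(size)[None, :]).ravel()
        b = beta_true[idx].reshape(len(which), size)
        mean_d = np.sqrt(config.n_disc) * b @ corr  # corr symmetric
        mean_r = np.sqrt(config.n_rep) * b @ corr
        e1 = rng.standard_normal((len(which), size)) @ chol.T
        e2_ind = rng.standard_normal((len(which), size)) @ chol.T
        e2 = rho * e1 + np.sqrt(1 - rho**2) * e2_ind
        z_disc[idx] = (mean_d + e1).ravel()
        z_rep[idx] = (mean_r + e2).ravel()

    snp_ids = [f"rs{i}" for i in range(m)]
    # synthetic map: blocks laid 1 Mb apart on one chromosome, 1 kb spacing
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    pos = np.array(
        [1 + bi * 1_000_000 + (i - starts[bi]) * 1000 for i, bi in enumerate(block_of)],
        dtype=int,
    )
    chrom = "1"
    disc = _sumstats_from_z(z_disc, maf, config.n_disc, chrom, pos, snp_ids,
                            config.pheno_sd, "discovery")
    rep = _sumstats_from_z(z_rep, maf, config.n_rep, chrom, pos, snp_ids,
                           config.pheno_sd, "replication")
    truth = SimulatedTruth(causal=causal, beta_true=beta_true,
                           block_of=block_of, maf=maf)
    return disc, rep, truth, simulate_ld_blocks(config)


#: BrainSpan-like cerebellar design: 25 ages (10 pre-natal), 29 samples
#: (four ages carry duplicate samples).
DEFAULT_TIMEPOINTS = (
    [(f"{w}pcw", True, 2 if w == 21 else 1) for w in (8, 9, 12, 13, 16, 17, 21, 24, 35, 37)]
    + [("4mos", False, 2), ("10mos", False, 1)]
    + [(f"{y}yrs", False, 2 if y in (3, 8) else 1)
       for y in (1, 2, 3, 4, 8, 11, 13, 15, 18, 19, 21, 23, 30)]
)


def simulate_gene_level(
    n_genes: int = 2000,
    timepoints=None,
    effect_pre: float = 0.0,
    effect_post: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_low_expression: int = 0,
    n_missing_id: int = 0,
    baseline_mean: float = 2.0,
    baseline_sd: float = 1.5,
    temporal_sd: float = 0.6,
    temporal_rho: float = 0.85,
    replicate_sd: float = 0.15,
):
    """Coupled gene-association and expression data.

    Expression is log-normal on the RPKM scale: per-gene baseline
    N(``baseline_mean``, ``baseline_sd``^2) on the log2 scale plus an AR(1)
    deviation across age-ordered timepoints (autocorrelation
    ``temporal_rho``, marginal SD ``temporal_sd``), plus per-sample replicate
    noise.  Gene association Z scores are

        Z_g = effect_pre * mean(pre-natal log2 expr)
            + effect_post * mean(post-natal log2 expr) + N(0, noise_sd^2)

    ``n_low_expression`` extra genes get RPKM <= 1 everywhere and
    ``n_missing_id`` extra genes get blank ids, to exercise the filters.

    Returns ``(assoc DataFrame[gene_id, z, p], ExpressionMatrix,
    latent gene x timepoint log2 expression)``.
    """
    if timepoints is None:
        timepoints = DEFAULT_TIMEPOINTS
    if not any(pre for _, pre, _ in timepoints) or not any(
        not pre for _, pre, _ in timepoints
    ):
        raise ValueError("need at least one pre- and one post-natal timepoint")
    rng = np.random.default_rng(seed)
    k = len(timepoints)
    pre_mask = np.array([pre for _, pre, _ in timepoints])

    total = n_genes + n_low_expression + n_missing_id
    baseline = rng.normal(baseline_mean, baseline_sd, total)
    ar = np.empty((total, k))
    ar[:, 0] = rng.standard_normal(total)
    for j in range(1, k):
        ar[:, j] = temporal_rho * ar[:, j - 1] + np.sqrt(
            1 - temporal_rho**2
        ) * rng.standard_normal(total)
    latent = baseline[:, None] + temporal_sd * ar  # log2 scale, gene x timepoint
    low = slice(n_genes, n_genes + n_low_expression)
    latent[low] = rng.uniform(-1.0, 0.9, size=(n_low_expression, k))

    sample_ids, age_labels, prenatal, cols = [], [], [], []
    for j, (label, pre, n_rep) in enumerate(timepoints):
        for r in range(n_rep):
            sample_ids.append(f"{label}.{r}")
            age_labels.append(label)
            prenatal.append(pre)
            cols.append(latent[:, j] + rng.normal(0.0, replicate_sd, total))
    log2_samples = np.column_stack(cols)
    rpkm = np.maximum(2.0**log2_samples - 1.0, 0.0)
    # enforce the low-expression construction after replicate noise
    rpkm[low] = np.minimum(rpkm[low], 0.99)

    gene_ids = [f"G{i}" for i in range(total)]
    for i in range(n_genes + n_low_expression, total):
        gene_ids[i] = ""

    expr = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, age_labels=age_labels,
        prenatal=np.array(prenatal), rpkm=rpkm,
    )
    z = (
        effect_pre * latent[:, pre_mask].mean(axis=1)
        + effect_post * latent[:, ~pre_mask].mean(axis=1)
        + rng.normal(0.0, noise_sd, total)
    )
    assoc = pd.DataFrame({
        "gene_id": gene_ids,
        "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)),
    })
    return assoc, expr, latent


def simulate_phenotype_with_outliers(
    n: int = 10_000,
    mean: float = 143_580.0,
    sd: float = 14_231.0,
    n_outliers: int = 0,
    magnitude: float = 10.0,
    seed: int = 0,
):
    """Normal phenotype draws plus injected outliers at
    median +/- magnitude * MAD of the clean sample.

    Returns ``(PhenotypeVector, outlier index array)``; outliers occupy the
    trailing positions.
    """
    if n_outliers >= n:
        raise ValueError("need n > n_outliers")
    rng = np.random.default_rng(seed)
    clean = rng.normal(mean, sd, n - n_outliers)
    med = np.median(clean)
    mad = np.median(np.abs(clean - med))
    signs = np.where(np.arange(n_outliers) % 2 == 0, 1.0, -1.0)
    outliers = med + signs * magnitude * mad
    values = np.concatenate([clean, outliers])
    idx = np.arange(n - n_outliers, n)
    return PhenotypeVector(values=values), idx


def simulate_lead_snp_pairs(
    n_snps: int,
    n_disc: int = 27_486,
    n_rep: int = 3_906,
    sigma_beta2: float = 3.60e-4,
    gws_p: float = 5e-8,
    seed: int = 0,
    rng: np.random.Generator | None = None,
):
    """Discovery lead SNPs with independent replication, on the standardised
    scale (se = 1/sqrt(N)).

    True effects are drawn from the causal slab N(0, sigma_beta2) and
    discovery estimates rejection-sampled until ``n_snps`` pass the
    genome-wide selection threshold — the sampling distribution of lead-SNP
    estimates under winner's curse.

    Returns a DataFrame with columns ``beta_true, beta_disc, se_disc,
    beta_rep, se_rep, z_disc, z_rep``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    c = stats.norm.isf(gws_p / 2)
    se_d = 1.0 / np.sqrt(n_disc)
    se_r = 1.0 / np.sqrt(n_rep)
    beta_true = np.empty(n_snps)
    z_disc = np.empty(n_snps)
    got = 0
    while got < n_snps:
        batch = max(4 * (n_snps - got), 256)
        b = rng.normal(0.0, np.sqrt(sigma_beta2), batch)
        z = np.sqrt(n_disc) * b + rng.standard_normal(batch)
        keep = np.abs(z) > c
        take = min(int(keep.sum()), n_snps - got)
        beta_true[got:got + take] = b[keep][:take]
        z_disc[got:got + take] = z[keep][:take]
        got += take
    z_rep = np.sqrt(n_rep) * beta_true + rng.standard_normal(n_snps)
    return pd.DataFrame({
        "beta_true": beta_true,
        "beta_disc": z_disc * se_d,
        "se_disc": se_d,
        "beta_rep": z_rep * se_r,
        "se_rep": se_r,
        "z_disc": z_disc,
        "z_rep": z_rep,
    })
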