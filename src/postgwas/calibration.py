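"""Simulation studies of the pipeline's statistical behaviour.

These routines re-run the package's own machinery on synthetic data at the
study's design values and measure operating characteristics: type-I error of
the pre/post-natal contrast, calibration of the expected-replication count,
shrinkage benefit of the winner's-curse correction, and null behaviour of
the overlap-corrected meta-analysis.  They are used by the test suite and
the reproduction script; each is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .replication import correct_and_expect
from .simulate import (
    SimulationConfig,
    simulate_gene_level,
    simulate_lead_snp_pairs,
    simulate_sumstats,
)
from .temporal import preprocess_expression, timepoint_correlation

__all__ = [
    "contrast_null_type_i",
    "replication_calibration",
    "expected_replications_study_scale",
    "winners_curse_rmse",
    "meta_overlap_type_i",
]


def contrast_null_type_i(
    n_genes: int = 2000,
    n_sims: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    partial_r: bool = False,
):
    """Rejection rate of the pre/post-natal contrast under the null.

    One expression matrix is simulated and processed; ``n_sims`` independent
    gene-Z vectors (pure noise, independent of expression) are pushed through
    the per-timepoint conditional regressions — vectorised over simulations,
    algebraically identical to the single-fit path — and the contrast is
    evaluated with R from :func:`timepoint_correlation` (raw by default;
    ``partial_r=True`` uses the avg-residualised variant).

    Returns ``(rejection_rate, p_values)``.
    """
    _, raw, _ = simulate_gene_level(n_genes=n_genes, seed=seed)
    expr = preprocess_expression(raw)
    R = timepoint_correlation(expr, partial=partial_r)
    X = expr.logexpr
    n, k = X.shape
    pre = expr.prenatal
    avg = expr.avg_expr
    rng = np.random.default_rng(seed + 1)
    Z = rng.standard_normal((n, n_sims))
    betas = np.empty((k, n_sims))
    ses = np.empty((k, n_sims))
    for j in range(k):
        Xj = np.column_stack([np.ones(n), X[:, j], avg])
        xtx_inv = np.linalg.inv(Xj.T @ Xj)
        coef = xtx_inv @ Xj.T @ Z
        resid = Z - Xj @ coef
        sigma2 = (resid**2).sum(axis=0) / (n - 3)
        betas[j] = coef[1]
        ses[j] = np.sqrt(sigma2 * xtx_inv[1, 1])
    k_pre = int(pre.sum())
    k_post = k - k_pre
    D = np.where(pre, 1.0 / k_pre, -1.0 / k_post)
    delta = D @ betas
    v = D[:, None] * ses
    var = np.einsum("ks,kj,js->s", v, R, v)
    z = delta / np.sqrt(var)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return float((pvals < alpha).mean()), pvals


def replication_calibration(
    n_leads: int = 200,
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    n_disc: int = 27_486,
    n_rep: int = 3_906,
    sigma_beta2: float = 3.60e-4,
):
    """Expected vs empirically observed replication counts across replicates.

    Each replicate simulates ``n_leads`` threshold-selected discovery lead
    SNPs with independent replication, corrects them, sums Eq.-style
    significance probabilities, and counts actual two-sided replication
    successes.  Returns a dict with the paired mean difference and its
    Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    expected = np.empty(n_replicates)
    observed = np.empty(n_replicates)
    for r in range(n_replicates):
        df = simulate_lead_snp_pairs(n_leads, n_disc=n_disc, n_rep=n_rep,
                                     sigma_beta2=sigma_beta2, rng=rng)
        exp_count, _, _ = correct_and_expect(
            df["beta_disc"], df["se_disc"], df["se_rep"], alpha
        )
        expected[r] = exp_count
        p_rep = 2 * stats.norm.sf(np.abs(df["z_rep"]))
        observed[r] = int((p_rep < alpha).sum())
    diff = expected - observed
    return {
        "mean_expected": float(expected.mean()),
        "mean_observed": float(observed.mean()),
        "mean_diff": float(diff.mean()),
        "se_diff": float(diff.std(ddof=1) / np.sqrt(n_replicates)),
    }


def expected_replications_study_scale(
    n_leads_reference: int = 37,
    n_replicates: int = 25,
    seed: int = 0,
    n_per_replicate: int = 200,
):
    """Expected replication counts on the study's 37-lead-SNP scale.

    Simulates threshold-selected lead SNPs under the study design
    (N_disc = 27,486, N_rep = 3,906, slab variance 3.60e-4), applies the
    conditional-likelihood correction, and reports
    ``n_leads_reference * mean P(sig)`` at alpha = 0.05 and 5e-8, averaged
    over replicates.
    """
    rng = np.random.default_rng(seed)
    frac_05, frac_gws = [], []
    for _ in range(n_replicates):
        df = simulate_lead_snp_pairs(n_per_replicate, rng=rng)
        _, p05, _ = correct_and_expect(df["beta_disc"], df["se_disc"],
                                       df["se_rep"], 0.05)
        _, pgw, _ = correct_and_expect(df["beta_disc"], df["se_disc"],
                                       df["se_rep"], 5e-8)
        frac_05.append(p05.mean())
        frac_gws.append(pgw.mean())
    return {
        "expected_alpha_05": float(n_leads_reference * np.mean(frac_05)),
        "expected_alpha_gws": float(n_leads_reference * np.mean(frac_gws)),
        "mean_p_sig_05": float(np.mean(frac_05)),
        "mean_p_sig_gws": float(np.mean(frac_gws)),
    }


def winners_curse_rmse(
    n_replicates: int = 20,
    m_snps: int = 200_000,
    seed: int = 0,
):
    """Recovery error of raw vs corrected estimates among GWS SNPs.

    Each replicate simulates a full spike-and-slab summary-statistic set at
    the study architecture (LD blocks included), selects the genome-wide
    significant SNPs, applies the conditional-likelihood correction on the
    standardised scale, and measures squared error against the true
    standardised effects (zero for LD-tagged non-causal SNPs).

    Returns a dict with pooled RMSEs and per-replicate arrays.
    """
    sq_raw, sq_adj = [], []
    rmse_raw = np.full(n_replicates, np.nan)
    rmse_adj = np.full(n_replicates, np.nan)
    for r in range(n_replicates):
        cfg = SimulationConfig(m_snps=m_snps, seed=seed + r)
        disc, _, truth, _ = simulate_sumstats(cfg)
        d = disc.df
        gws = (d["P"] < 5e-8).to_numpy()
        if not gws.any():
            continue
        z = (d["BETA"] / d["SE"]).to_numpy()[gws]
        se_std = 1.0 / np.sqrt(cfg.n_disc)
        beta_hat = z * se_std
        se = np.full(gws.sum(), se_std)
        _, _, beta_adj = correct_and_expect(
            beta_hat, se, np.full(gws.sum(), 1.0 / np.sqrt(cfg.n_rep)), 0.05
        )
        err_raw = (beta_hat - truth.beta_true[gws]) ** 2
        err_adj = (beta_adj - truth.beta_true[gws]) ** 2
        sq_raw.extend(err_raw)
        sq_adj.extend(err_adj)
        rmse_raw[r] = np.sqrt(err_raw.mean())
        rmse_adj[r] = np.sqrt(err_adj.mean())
    return {
        "rmse_raw_pooled": float(np.sqrt(np.mean(sq_raw))),
        "rmse_adjusted_pooled": float(np.sqrt(np.mean(sq_adj))),
        "rmse_raw": rmse_raw,
        "rmse_adjusted": rmse_adj,
        "n_selected": len(sq_raw),
    }


def meta_overlap_type_i(
    m_snps: int = 10_000,
    overlap_fraction: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
    n_per_study: int = 20_000,
):
    """Null rejection rates of the meta-analysis with and without the
    overlap correction, under shared subjects across two studies.

    Returns ``(rate_corrected, rate_uncorrected, rho)``.
    """
    from .meta import meta_z

    cfg = SimulationConfig(m_snps=m_snps, pi=0.0, ld_block_sizes=1,
                           overlap_fraction=overlap_fraction,
                           n_disc=n_per_study, n_rep=n_per_study, seed=seed)
    disc, rep, _, _ = simulate_sumstats(cfg)
    z1 = (disc.df["BETA"] / disc.df["SE"]).to_numpy()
    z2 = (rep.df["BETA"] / rep.df["SE"]).to_numpy()
    Z = np.column_stack([z1, z2])
    neff = np.array([float(n_per_study), float(n_per_study)])
    rho = overlap_fraction * min(cfg.n_disc, cfg.n_rep) / np.sqrt(
        cfg.n_disc * cfg.n_rep)
    intercepts = np.array([[1.0, rho], [rho, 1.0]])
    _, p_corr, _ = meta_z(Z, neff, intercepts)
    _, p_raw, _ = meta_z(Z, neff, None)
    return float((p_corr < alpha).mean()), float((p_raw < alpha).mean()), rho
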