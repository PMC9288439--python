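"""Winner's-curse correction and expected replication counts for discovery
lead SNPs.

Effect estimates selected by a significance threshold are biased away from
zero (winner's curse).  The conditional-likelihood correction re-estimates
the effect under the truncated sampling distribution given selection: with
observed estimate ``b``, standard error ``sigma`` and selection cut-off
``c = Phi^-1(1 - alpha/2)`` on the |Z| scale, the conditional density of the
observation given selection is

    phi((b - beta)/sigma) / sigma
    -------------------------------------------
    Phi(beta/sigma - c) + Phi(-beta/sigma - c)

and the corrected estimate is its maximiser over beta (the conditional MLE),
searched on [0, |b|] with the sign restored.  The probability that a
corrected lead SNP is significant in a replication sample with standard
error ``sigma_rep`` at level ``alpha`` is

    P(sig) = Phi(-|beta|/sigma_rep + Phi^-1(alpha/2))
           + [1 - Phi(-|beta|/sigma_rep - Phi^-1(alpha/2))]

and the expected replication count is the sum of P(sig) over lead SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LeadSnpPair",
    "WinnersCurseEstimate",
    "conditional_likelihood_correct",
    "conditional_likelihood_correct_rep",
    "correct_and_expect",
    "replication_probability",
    "expected_replications",
    "observed_replications",
    "read_lead_pairs",
]


@dataclass
class LeadSnpPair:
    """One discovery lead SNP's discovery and replication estimates."""

    snp_id: str
    beta_disc: float
    se_disc: float
    beta_rep: float | None = None
    se_rep: float | None = None
    alpha_disc: float = 5e-8

    def __post_init__(self) -> None:
        if self.se_disc <= 0:
            raise ValueError(f"{self.snp_id}: se_disc must be positive")
        if self.se_rep is not None and self.se_rep <= 0:
            raise ValueError(f"{self.snp_id}: se_rep must be positive")
        c = stats.norm.isf(self.alpha_disc / 2)
        if abs(self.beta_disc / self.se_disc) < c * (1 - 1e-12):
            raise ValueError(
                f"{self.snp_id}: |Z|={abs(self.beta_disc / self.se_disc):.3f} "
                f"below the discovery selection threshold {c:.3f}"
            )


@dataclass
class WinnersCurseEstimate:
    snp_id: str
    beta_adjusted: float
    method_label: str = "conditional-mle"


def _neg_log_cond_lik(mu, z, c):
    # z, mu on the |Z| scale; log selection probability via logsumexp of
    # the two tail log-CDFs for numerical stability at large c
    log_sel = np.logaddexp(stats.norm.logcdf(mu - c), stats.norm.logcdf(-mu - c))
    return 0.5 * (np.asarray(z) - mu) ** 2 + log_sel


def _batch_conditional_mle(z_abs: np.ndarray, c: float, n_grid: int = 129,
                           iters: int = 60) -> np.ndarray:
    """Vectorised conditional-MLE shrinkage on the |Z| scale.

    The conditional likelihood can be multimodal, so the global optimum is
    bracketed on a grid over [0, z] per SNP and refined by golden-section.
    """
    z_abs = np.asarray(z_abs, dtype=float)
    frac = np.linspace(0.0, 1.0, n_grid)
    grid = z_abs[:, None] * frac[None, :]
    vals = _neg_log_cond_lik(grid, z_abs[:, None], c)
    best = np.argmin(vals, axis=1)
    step = z_abs / (n_grid - 1)
    lo = np.maximum((best - 1), 0) * step
    hi = np.minimum((best + 1), n_grid - 1) * step
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    for _ in range(iters):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        take = _neg_log_cond_lik(x1, z_abs, c) < _neg_log_cond_lik(x2, z_abs, c)
        b = np.where(take, x2, b)
        a = np.where(take, a, x1)
    mu_hat = (a + b) / 2.0
    # snap to an endpoint of [0, z] when it beats the interior optimum
    f_hat = _neg_log_cond_lik(mu_hat, z_abs, c)
    for edge in (np.zeros_like(z_abs), z_abs):
        f_edge = _neg_log_cond_lik(edge, z_abs, c)
        mu_hat = np.where(f_edge < f_hat, edge, mu_hat)
        f_hat = np.minimum(f_edge, f_hat)
    return mu_hat


def conditional_likelihood_correct(
    beta_disc: float,
    se_disc: float,
    alpha_disc: float = 5e-8,
    method: str = "mle",
    tol: float = 1e-6,
) -> float:
    """Winner's-curse-corrected effect estimate for a selected SNP.

    ``method="mle"`` (default) maximises the conditional likelihood over
    beta in [0, |beta_disc|] (sign restored); ``method="mean"`` returns the
    conditional expectation correction b - sigma * A'(z)/A(z) with A the
    selection probability, clipped to the same shrinkage range.

    Raises for SNPs that do not pass the selection threshold: the truncated
    sampling model is undefined for them.
    """
    if se_disc <= 0:
        raise ValueError("se_disc must be positive")
    if not (0 < alpha_disc < 1):
        raise ValueError("alpha_disc must lie in (0, 1)")
    c = stats.norm.isf(alpha_disc / 2)
    z = abs(beta_disc) / se_disc
    if z < c * (1 - 1e-12):
        raise ValueError(
            f"SNP not significant at alpha={alpha_disc} (|Z|={z:.3f} < c={c:.3f}); "
            "selection model undefined"
        )
    sign = np.sign(beta_disc) if beta_disc != 0 else 1.0
    if method == "mean":
        # derivative of log selection probability wrt mu, at mu = z
        num = stats.norm.pdf(z - c) - stats.norm.pdf(-z - c)
        den = stats.norm.cdf(z - c) + stats.norm.cdf(-z - c)
        mu_hat = z - num / den
        mu_hat = min(max(mu_hat, 0.0), z)
        return float(sign * mu_hat * se_disc)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    mu_hat = float(_batch_conditional_mle(np.array([z]), c)[0])
    # polish within the achieved bracket to the requested tolerance
    res = optimize.minimize_scalar(
        _neg_log_cond_lik,
        bounds=(max(mu_hat - 1e-3, 0.0), min(mu_hat + 1e-3, z)),
        args=(z, c), method="bounded", options={"xatol": tol},
    )
    if _neg_log_cond_lik(res.x, z, c) < _neg_log_cond_lik(mu_hat, z, c):
        mu_hat = float(res.x)
    return float(sign * mu_hat * se_disc)


def conditional_likelihood_correct_rep(
    beta_disc: float,
    se_disc: float,
    beta_rep: float,
    se_rep: float,
    alpha_disc: float = 5e-8,
    tol: float = 1e-6,
) -> float:
    """Replication-informed conditional-likelihood correction.

    Maximises the product of the truncated discovery likelihood (the
    conditional density given selection) and the untruncated replication
    likelihood — the joint-MLE variant of the conditional-likelihood family.
    Unlike the discovery-only estimator the maximiser may fall outside
    [0, |beta_disc|] in pathological cases; it is clipped to that shrinkage
    range for contract consistency.
    """
    if se_disc <= 0 or se_rep <= 0:
        raise ValueError("standard errors must be positive")
    c = stats.norm.isf(alpha_disc / 2)
    z = abs(beta_disc) / se_disc
    if z < c * (1 - 1e-12):
        raise ValueError("SNP not significant in discovery; selection model undefined")
    sign = np.sign(beta_disc) if beta_disc != 0 else 1.0
    zr = sign * beta_rep / se_rep          # replication Z on the discovery sign
    ratio = se_disc / se_rep               # scales mu (in z_d units) to the rep scale

    def neg(mu):
        log_sel = np.logaddexp(stats.norm.logcdf(mu - c), stats.norm.logcdf(-mu - c))
        return 0.5 * (z - mu) ** 2 + log_sel + 0.5 * (zr - mu * ratio) ** 2

    grid = np.linspace(0.0, z, 257)
    vals = neg(grid)
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 256)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    mu_hat = float(res.x) if neg(res.x) < vals[i] else float(grid[i])
    return float(sign * mu_hat * se_disc)


def correct_and_expect(
    beta_disc: np.ndarray,
    se_disc: np.ndarray,
    se_rep: np.ndarray,
    alpha: float,
    alpha_disc: float = 5e-8,
):
    """Vectorised pipeline: conditional-MLE correction of every discovery
    estimate, then per-SNP replication significance probabilities.

    Returns ``(expected_count, p_sig array, beta_adjusted array)``.
    """
    beta_disc = np.asarray(beta_disc, float)
    se_disc = np.asarray(se_disc, float)
    se_rep = np.asarray(se_rep, float)
    c = stats.norm.isf(alpha_disc / 2)
    z_abs = np.abs(beta_disc) / se_disc
    if np.any(z_abs < c * (1 - 1e-12)):
        raise ValueError("all SNPs must pass the discovery selection threshold")
    mu_hat = _batch_conditional_mle(z_abs, c)
    beta_adj = np.sign(beta_disc) * mu_hat * se_disc
    q = stats.norm.ppf(alpha / 2)
    t = np.abs(beta_adj) / se_rep
    p_sig = stats.norm.cdf(-t + q) + stats.norm.sf(-t - q)
    return float(p_sig.sum()), p_sig, beta_adj


def replication_probability(beta_adjusted: float, se_rep: float, alpha: float) -> float:
    """Probability that a SNP with (corrected) effect ``beta_adjusted`` is
    two-sided significant at ``alpha`` in a replication sample with standard
    error ``se_rep``."""
    if se_rep <= 0:
        raise ValueError("se_rep must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    q = stats.norm.ppf(alpha / 2)  # negative
    t = np.abs(beta_adjusted) / se_rep
    return float(stats.norm.cdf(-t + q) + stats.norm.sf(-t - q))


def expected_replications(
    records: list[LeadSnpPair],
    alpha: float,
    alpha_disc: float | None = None,
    method: str = "mle",
):
    """Expected number of lead SNPs significant in replication.

    Each record is winner's-curse corrected at its discovery threshold, its
    replication significance probability evaluated at ``alpha``, and the
    probabilities summed.  Returns ``(expected_count, per_snp DataFrame)``.
    """
    if not records:
        warnings.warn("no lead SNP records; expected count is 0", stacklevel=2)
        return 0.0, pd.DataFrame(columns=["snp_id", "beta_adjusted", "p_sig"])
    rows = []
    for rec in records:
        if rec.se_rep is None:
            raise ValueError(f"{rec.snp_id}: se_rep required for expected replication")
        a_disc = alpha_disc if alpha_disc is not None else rec.alpha_disc
        if method == "joint":
            if rec.beta_rep is None:
                raise ValueError(f"{rec.snp_id}: joint correction needs beta_rep")
            beta_adj = conditional_likelihood_correct_rep(
                rec.beta_disc, rec.se_disc, rec.beta_rep, rec.se_rep,
                alpha_disc=a_disc,
            )
        else:
            beta_adj = conditional_likelihood_correct(
                rec.beta_disc, rec.se_disc, alpha_disc=a_disc, method=method
            )
        p_sig = replication_probability(beta_adj, rec.se_rep, alpha)
        rows.append({"snp_id": rec.snp_id, "beta_adjusted": beta_adj, "p_sig": p_sig})
    table = pd.DataFrame(rows)
    return float(table["p_sig"].sum()), table


def observed_replications(
    records: list[LeadSnpPair],
    alpha: float,
    require_sign_concordance: bool = True,
) -> int:
    """Count of lead SNPs with two-sided replication P below ``alpha``.

    By default the replication effect must also agree in sign with the
    discovery effect; disable for the bare P-threshold count.
    """
    count = 0
    for rec in records:
        if rec.beta_rep is None or rec.se_rep is None:
            raise ValueError(f"{rec.snp_id}: replication estimate missing")
        p_rep = 2 * stats.norm.sf(abs(rec.beta_rep) / rec.se_rep)
        if p_rep < alpha and (
            not require_sign_concordance
            or np.sign(rec.beta_rep) == np.sign(rec.beta_disc)
        ):
            count += 1
    return count


def read_lead_pairs(path, alpha_disc: float = 5e-8) -> list[LeadSnpPair]:
    """Read a tab-separated ``SNP BETA_DISC SE_DISC BETA_REP SE_REP`` file."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = []
    for _, r in df.iterrows():
        out.append(LeadSnpPair(
            snp_id=str(r["SNP"]),
            beta_disc=float(r["BETA_DISC"]),
            se_disc=float(r["SE_DISC"]),
            beta_rep=None if pd.isna(r.get("BETA_REP")) else float(r["BETA_REP"]),
            se_rep=None if pd.isna(r.get("SE_REP")) else float(r["SE_REP"]),
            alpha_disc=alpha_disc,
        ))
    return out
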