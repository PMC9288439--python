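"""Developmental-expression gene-property analysis and the pre/post-natal
fixed-effects contrast.

Gene-level association Z scores are regressed, one developmental timepoint at
a time, on that timepoint's log expression (conditioning on each gene's
average expression across timepoints).  The per-timepoint marginal effect
estimates b_j are then modelled jointly as

    b_hat ~ MVN(b, S R S)

with S the diagonal matrix of standard errors and R approximated by the
correlation matrix of the expression timepoints, and the difference between
the mean pre-natal and mean post-natal effect is tested with the coding
vector D (1/K_pre on pre-natal timepoints, -1/K_post on post-natal ones):

    delta = D' b_hat,   Var(delta) = D' S R S D,   z = delta / sqrt(Var).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "ProcessedExpression",
    "TimepointEffects",
    "ContrastResult",
    "preprocess_expression",
    "gene_property_regression",
    "timepoint_correlation",
    "prepost_contrast",
    "temporal_contrast_pipeline",
    "read_expression",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM matrix with per-sample age metadata."""

    gene_ids: list
    sample_ids: list[str]
    age_labels: list[str]
    prenatal: np.ndarray  # bool per sample
    rpkm: np.ndarray      # gene x sample, >= 0
    age_days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        self.prenatal = np.asarray(self.prenatal, dtype=bool)
        g, s = self.rpkm.shape
        if g != len(self.gene_ids) or s != len(self.sample_ids):
            raise ValueError("rpkm dimensions inconsistent with metadata")
        if len(self.age_labels) != s or len(self.prenatal) != s:
            raise ValueError("per-sample metadata length mismatch")
        if np.any(self.rpkm < 0):
            raise ValueError("RPKM values must be non-negative")


@dataclass
class ProcessedExpression:
    """Filtered, winsorized, log-transformed, age-averaged expression."""

    gene_ids: list
    timepoints: list[str]
    prenatal: np.ndarray           # bool per timepoint
    logexpr: np.ndarray            # gene x timepoint
    avg_expr: np.ndarray           # per-gene mean over timepoints
    filter_report: dict = field(default_factory=dict)


@dataclass
class TimepointEffects:
    """Per-timepoint marginal effect estimates with their correlation model."""

    beta_hat: np.ndarray
    se: np.ndarray
    prenatal: np.ndarray
    R: np.ndarray
    timepoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, float)
        self.se = np.asarray(self.se, float)
        self.prenatal = np.asarray(self.prenatal, bool)
        self.R = np.asarray(self.R, float)
        k = len(self.beta_hat)
        if not (len(self.se) == len(self.prenatal) == k and self.R.shape == (k, k)):
            raise ValueError("inconsistent dimensions")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")
        if np.max(np.abs(self.R - self.R.T)) > 1e-10:
            raise ValueError("R must be symmetric")
        if np.max(np.abs(np.diag(self.R) - 1)) > 1e-10:
            raise ValueError("R must have unit diagonal")

    @property
    def k_pre(self) -> int:
        return int(self.prenatal.sum())

    @property
    def k_post(self) -> int:
        return int((~self.prenatal).sum())


@dataclass
class ContrastResult:
    mu_pre_hat: float
    mu_post_hat: float
    delta: float
    se_delta: float
    z: float
    p: float
    D: np.ndarray


def preprocess_expression(
    raw: ExpressionMatrix,
    brain_genes: set | None = None,
    winsor_cap: float = 50.0,
    min_rpkm: float = 1.0,
) -> ProcessedExpression:
    """Filter, winsorize, log-transform and age-average an RPKM matrix.

    Steps, in order: (1) drop genes whose RPKM is not > ``min_rpkm`` in at
    least one sample ("age stage"); (2) drop genes with missing ids; (3) keep
    only ``brain_genes`` when given; (4) winsorize RPKM at ``winsor_cap``;
    (5) log2(x + 1); (6) average log values over samples of the same age;
    (7) per-gene mean over ages as covariate.  The filter report counts
    removals at each step.
    """
    if raw.rpkm.size == 0:
        raise ValueError("empty expression matrix")
    n_in = len(raw.gene_ids)
    keep = raw.rpkm.max(axis=1) > min_rpkm
    n_low = int((~keep).sum())

    ids = np.asarray(raw.gene_ids, dtype=object)
    missing = np.array([g is None or (isinstance(g, float) and np.isnan(g)) or str(g) in ("", "NA", "nan")
                        for g in ids])
    n_missing = int((missing & keep).sum())
    keep &= ~missing

    if brain_genes is not None:
        in_brain = np.array([str(g) in brain_genes for g in ids])
        n_nonbrain = int((keep & ~in_brain).sum())
        keep &= in_brain
    else:
        n_nonbrain = 0

    if not keep.any():
        raise ValueError("no genes survive expression filtering")

    x = np.minimum(raw.rpkm[keep], winsor_cap)
    x = np.log2(x + 1.0)

    # average over samples sharing an age label, preserving age order
    seen: dict[str, int] = {}
    order: list[str] = []
    for lab in raw.age_labels:
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
    g = x.shape[0]
    logexpr = np.zeros((g, len(order)))
    pre_flags = np.zeros(len(order), dtype=bool)
    for j, lab in enumerate(order):
        cols = [i for i, l in enumerate(raw.age_labels) if l == lab]
        logexpr[:, j] = x[:, cols].mean(axis=1)
        flags = set(raw.prenatal[cols].tolist())
        if len(flags) != 1:
            raise ValueError(f"age {lab} mixes pre- and post-natal samples")
        pre_flags[j] = flags.pop()

    report = {
        "input_genes": n_in,
        "removed_low_expression": n_low,
        "removed_missing_id": n_missing,
        "removed_not_brain_gene": n_nonbrain,
        "output_genes": int(keep.sum()),
    }
    return ProcessedExpression(
        gene_ids=list(ids[keep]),
        timepoints=order,
        prenatal=pre_flags,
        logexpr=logexpr,
        avg_expr=logexpr.mean(axis=1),
        filter_report=report,
    )


def gene_property_regression(
    assoc: pd.DataFrame,
    expr: ProcessedExpression,
    timepoint: str,
):
    """OLS of gene association Z on one timepoint's log expression.

    ``assoc`` needs columns ``gene_id`` and ``z``.  The design is
    [intercept, timepoint log-expression, average-expression covariate]; the
    returned P is one-sided, upper tail (testing a positive relationship).

    Returns ``(beta_hat, se, p_one_sided)``.
    """
    if timepoint not in expr.timepoints:
        raise KeyError(f"timepoint {timepoint!r} not in processed expression")
    j = expr.timepoints.index(timepoint)
    gene_index = {str(gid): i for i, gid in enumerate(expr.gene_ids)}
    rows = [(gene_index[str(g)], z) for g, z in zip(assoc["gene_id"], assoc["z"])
            if str(g) in gene_index]
    if len(rows) < 3:
        raise ValueError("fewer than 3 genes shared between associations and expression")
    idx = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows], dtype=float)
    x_t = expr.logexpr[idx, j]
    x_avg = expr.avg_expr[idx]
    for name, col in (("timepoint expression", x_t), ("average expression", x_avg)):
        if np.std(col) == 0:
            raise ValueError(f"degenerate (constant) design column: {name}")
    X = sm.add_constant(np.column_stack([x_t, x_avg]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: timepoint expression confounded "
                         "with average expression")
    if np.std(y) == 0:
        # flat response: slope exactly 0, no evidence either way
        return 0.0, 0.0, 0.5
    fit = sm.OLS(y, X).fit()
    beta, se = fit.params[1], fit.bse[1]
    # a perfectly flat response (constant Z) gives se = 0 with beta = 0;
    # the t statistic is then 0, not indeterminate
    if se == 0:
        tval = 0.0 if beta == 0 else np.sign(beta) * np.inf
    else:
        tval = beta / se
    p_one = stats.t.sf(tval, df=fit.df_resid)
    return float(beta), float(se), float(p_one)


def timepoint_correlation(expr: ProcessedExpression, partial: bool = False) -> np.ndarray:
    """Pearson correlation, across genes, between timepoint expression
    vectors — the approximation used for the sampling correlation R.

    With ``partial=True`` each timepoint profile is first residualised on the
    per-gene average expression, matching the covariate the per-timepoint
    regressions condition on; this estimates the actual sampling correlation
    of the conditional effect estimates rather than the raw co-expression.
    The default is the raw correlation.
    """
    if expr.logexpr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    x = expr.logexpr
    if partial:
        design = np.column_stack([np.ones(x.shape[0]), expr.avg_expr])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ coef
    sd = x.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"zero-variance timepoint: {expr.timepoints[j]}")
    R = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return R


def prepost_contrast(effects: TimepointEffects) -> ContrastResult:
    """Fixed-effects test of equal mean pre-natal and post-natal effects.

    Under H0 (mu_pre = mu_post) the difference of group means is normal with
    variance D' S R S D; the returned P is two-sided.
    """
    k_pre, k_post = effects.k_pre, effects.k_post
    if k_pre < 1 or k_post < 1:
        raise ValueError("contrast needs at least one pre- and one post-natal timepoint")
    D = np.where(effects.prenatal, 1.0 / k_pre, -1.0 / k_post)
    mu_pre = float(effects.beta_hat[effects.prenatal].mean())
    mu_post = float(effects.beta_hat[~effects.prenatal].mean())
    delta = mu_pre - mu_post
    S = np.diag(effects.se)
    var = float(D @ S @ effects.R @ S @ D)
    if var <= 0:
        raise ValueError("degenerate contrast variance")
    se_delta = np.sqrt(var)
    z = delta / se_delta
    p = float(2 * stats.norm.sf(abs(z)))
    return ContrastResult(mu_pre_hat=mu_pre, mu_post_hat=mu_post, delta=delta,
                          se_delta=float(se_delta), z=float(z), p=max(p, 5e-324), D=D)


def temporal_contrast_pipeline(
    assoc: pd.DataFrame,
    raw: ExpressionMatrix,
    brain_genes: set | None = None,
    winsor_cap: float = 50.0,
    min_rpkm: float = 1.0,
):
    """Preprocess expression, fit every timepoint's gene-property regression,
    and run the pre/post-natal contrast.

    Returns ``(per_timepoint DataFrame, ContrastResult, ProcessedExpression)``.
    """
    expr = preprocess_expression(raw, brain_genes=brain_genes,
                                 winsor_cap=winsor_cap, min_rpkm=min_rpkm)
    rows = []
    for t in expr.timepoints:
        b, s, p1 = gene_property_regression(assoc, expr, t)
        rows.append({"timepoint": t, "prenatal": bool(expr.prenatal[expr.timepoints.index(t)]),
                     "beta": b, "se": s, "p_one_sided": p1})
    table = pd.DataFrame(rows)
    R = timepoint_correlation(expr)
    effects = TimepointEffects(
        beta_hat=table["beta"].to_numpy(),
        se=table["se"].to_numpy(),
        prenatal=table["prenatal"].to_numpy(),
        R=R,
        timepoints=expr.timepoints,
    )
    return table, prepost_contrast(effects), expr


def read_expression(matrix_path, samples_path) -> ExpressionMatrix:
    """Read a gene x sample matrix with a two-row header (sample id, age
    label) plus a ``sample_id age_label age_days prenatal`` metadata file."""
    with open(matrix_path) as fh:
        sample_ids = fh.readline().rstrip("\n").split("\t")[1:]
        age_row = fh.readline().rstrip("\n").split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", header=None)
    gene_ids = df.iloc[:, 0].tolist()
    rpkm = df.iloc[:, 1:].to_numpy(float)
    meta = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    meta = meta.set_index("sample_id").loc[sample_ids]
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        age_labels=[str(a) for a in age_row],
        prenatal=meta["prenatal"].to_numpy(int).astype(bool),
        rpkm=rpkm,
        age_days=meta["age_days"].to_numpy(float) if "age_days" in meta else None,
    )


def write_expression(raw: ExpressionMatrix, matrix_path, samples_path) -> None:
    with open(matrix_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(raw.sample_ids) + "\n")
        fh.write("age\t" + "\t".join(raw.age_labels) + "\n")
        for gid, row in zip(raw.gene_ids, raw.rpkm):
            fh.write(str(gid) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    pd.DataFrame({
        "sample_id": raw.sample_ids,
        "age_label": raw.age_labels,
        "age_days": raw.age_days if raw.age_days is not None else np.zeros(len(raw.sample_ids)),
        "prenatal": raw.prenatal.astype(int),
    }).to_csv(samples_path, sep="\t", index=False)
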