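"""Credible-set and posterior-inclusion-probability aggregation.

Consumes model posteriors from a Bayesian fine-mapping run — each "model" is
a candidate causal-SNP configuration with a posterior probability — and
aggregates them into 95% credible sets and per-SNP PIPs.  The stochastic
search that produces the posteriors is out of scope; only its output format
is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["FineMapPosterior", "credible_set", "pip", "read_posteriors"]


@dataclass
class FineMapPosterior:
    """Candidate causal configurations with posterior probabilities."""

    models: list[tuple[frozenset, float]]
    region_id: str = ""

    def __post_init__(self) -> None:
        self.models = [(frozenset(s), float(p)) for s, p in self.models]
        if any(p < 0 or p > 1 for _, p in self.models):
            raise ValueError("model posteriors must lie in [0, 1]")
        if sum(p for _, p in self.models) > 1 + 1e-6:
            raise ValueError("model posteriors sum above 1")


def credible_set(posterior: FineMapPosterior, mass: float = 0.95) -> set[str]:
    """Union of SNPs over the minimal prefix of descending-posterior models
    whose cumulative posterior reaches ``mass``.

    The model that crosses the threshold is included.  If the total posterior
    is below ``mass``, all models' union is returned with a warning.
    """
    if not posterior.models:
        raise ValueError("posterior has no models")
    ordered = sorted(posterior.models, key=lambda mp: -mp[1])
    total = sum(p for _, p in ordered)
    snps: set[str] = set()
    cum = 0.0
    for snp_set, p in ordered:
        snps |= snp_set
        cum += p
        if cum >= mass:
            return snps
    warnings.warn(
        f"total posterior {total:.4f} below requested mass {mass}; "
        "returning union of all models",
        stacklevel=2,
    )
    return snps


def pip(posterior: FineMapPosterior, threshold: float = 0.95):
    """Per-SNP posterior inclusion probabilities and the passing set.

    PIP(s) sums the posteriors of every model containing s; the passing set
    is {s : PIP(s) > threshold}.
    """
    if not posterior.models:
        raise ValueError("posterior has no models")
    pips: dict[str, float] = {}
    for snp_set, p in posterior.models:
        for s in snp_set:
            pips[s] = pips.get(s, 0.0) + p
    passing = {s for s, v in pips.items() if v > threshold}
    return pips, passing


def read_posteriors(path) -> dict[str, FineMapPosterior]:
    """Read a tab-separated ``region model_rank snp_ids posterior`` file
    (snp_ids comma-joined), one :class:`FineMapPosterior` per region."""
    df = pd.read_csv(path, sep="\t", dtype={"region": str, "snp_ids": str})
    need = {"region", "snp_ids", "posterior"}
    if not need.issubset(df.columns):
        raise ValueError(f"posterior file needs columns {sorted(need)}")
    out: dict[str, FineMapPosterior] = {}
    for region, sub in df.groupby("region", sort=False):
        models = [
            (frozenset(str(s).split(",")), float(p))
            for s, p in zip(sub["snp_ids"], sub["posterior"])
        ]
        out[str(region)] = FineMapPosterior(models=models, region_id=str(region))
    return out
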