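"""Resampling controls for cross-population risk comparisons.

Three controls guard the pooled risk contrast against artefacts:

* **bootstrap** — resample the risk-SNP set with replacement, recompute the
  fixed-model meta log OR per replicate, and z-test the replicate
  distribution against zero (robustness to outlier SNPs);
* **random SNP-set null** — draw size-matched SNP sets from a pool of
  disease-associated SNPs, build the null distribution of pooled log ORs,
  and standardize the observed value against it (systematic allele-frequency
  bias between the populations);
* **disease scan** — compute the population mean-PRS difference for many
  unrelated traits; a distribution centred away from zero indicates a
  systematic scoring bias.

z statistics: for the bootstrap and disease scan, ``z = mean/sd`` of the
replicate (per-trait) distribution; for the random-set null,
``z = (observed − mean(null)) / sd(null)``.  All p-values are two-sided
normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .catalog import RiskSNPSet
from .genio import GenotypeMatrix, align_risk_alleles, EmptyIntersectionError
from .riskstats import MetaResult, ORResult, polygenic_risk_score

__all__ = [
    "ZTestResult",
    "NullDistribution",
    "z_to_p",
    "bootstrap_meta",
    "random_snpset_null",
    "disease_scan",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZTestResult:
    """Standardized statistic with two-sided normal p-value."""

    z: float
    p: float
    n: int
    mean: float
    sd: float
    degenerate: bool = False


@dataclass
class NullDistribution:
    """Replicate statistics from one resampling control."""

    kind: str  # bootstrap | random_set | disease_scan
    values: np.ndarray
    n_replicates: int
    seed: int | None
    observed: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"statistic": self.values})

    def sidecar(self, z: ZTestResult) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "observed": self.observed,
            "z": z.z,
            "p": z.p,
            "degenerate": z.degenerate,
        }


def z_to_p(z: float) -> float:
    """Two-sided normal tail probability, ``2·(1 − Φ(|z|))``."""
    if not math.isfinite(z):
        return 0.0
    return 2.0 * float(norm.sf(abs(z)))


def _fixed_meta_rows(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise inverse-variance pooled estimates for index matrices."""
    return (w * y).sum(axis=1) / w.sum(axis=1)


def _summarize(values: np.ndarray, center: float | None = None) -> ZTestResult:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    # effectively-constant replicates (identical up to float round-off)
    if sd <= 1e-12 * max(1.0, abs(mean)):
        sd = 0.0
        stat = mean if center is None else center - mean
        z = math.inf if stat > 0 else (-math.inf if stat < 0 else 0.0)
        return ZTestResult(
            z=z, p=0.0 if stat != 0 else 1.0, n=values.size, mean=mean, sd=sd,
            degenerate=True,
        )
    z = mean / sd if center is None else (center - mean) / sd
    return ZTestResult(z=z, p=z_to_p(z), n=values.size, mean=mean, sd=sd)


def bootstrap_meta(
    or_results: list[ORResult],
    n_reps: int = 10_000,
    seed: int | None = None,
) -> tuple[NullDistribution, ZTestResult]:
    """Bootstrap the fixed-model meta log OR over the SNP set.

    Each replicate resamples the k SNPs with replacement and recomputes the
    inverse-variance pooled log OR; the replicate distribution is z-tested
    against zero (``z = mean/sd``).  If every replicate is identical the
    result is flagged degenerate with ``z = ±inf``.
    """
    if not or_results:
        raise ValueError("no OR results to bootstrap")
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    y = np.array([r.log_or for r in or_results])
    w = 1.0 / np.array([r.se**2 for r in or_results])
    k = y.size
    rng = np.random.default_rng(seed)
    observed = float((w * y).sum() / w.sum())
    reps = np.empty(n_reps)
    chunk = max(1, min(n_reps, 200_000 // max(k, 1)))
    done = 0
    while done < n_reps:
        size = min(chunk, n_reps - done)
        idx = rng.integers(0, k, size=(size, k))
        reps[done : done + size] = _fixed_meta_rows(y[idx], w[idx])
        done += size
    null = NullDistribution("bootstrap", reps, n_reps, seed, observed)
    return null, _summarize(reps)


def random_snpset_null(
    pool: list[ORResult],
    set_size: int,
    n_reps: int = 500_000,
    seed: int | None = None,
    observed: MetaResult | None = None,
) -> tuple[NullDistribution, ZTestResult]:
    """Null distribution of pooled log ORs from random size-matched SNP sets.

    Each replicate samples ``set_size`` SNPs *without* replacement from the
    pool of per-SNP OR results (SNP sets, not bags) and computes the
    fixed-model pooled log OR.  The observed pooled value is standardized
    against the null: ``z = (observed − mean) / sd``.
    """
    if observed is None:
        raise ValueError("an observed MetaResult is required")
    npool = len(pool)
    if npool < set_size:
        raise ValueError(
            f"pool of {npool} SNPs is smaller than set size {set_size}"
        )
    y = np.array([r.log_or for r in pool])
    w = 1.0 / np.array([r.se**2 for r in pool])
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    # vectorized sampling without replacement: per row, take the set_size
    # smallest of npool uniforms (a uniformly random subset)
    chunk = max(1, min(n_reps, 20_000_000 // max(npool, 1)))
    done = 0
    while done < n_reps:
        size = min(chunk, n_reps - done)
        u = rng.random((size, npool))
        idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
        reps[done : done + size] = _fixed_meta_rows(y[idx], w[idx])
        done += size
    obs = float(observed.pooled_log_or)
    null = NullDistribution("random_set", reps, n_reps, seed, obs)
    return null, _summarize(reps, center=obs)


def disease_scan(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    trait_sets: dict[str, RiskSNPSet],
) -> tuple[pd.DataFrame, ZTestResult]:
    """Mean-PRS differences (A − B) across many traits, z-tested against 0.

    Traits whose SNP set has no overlap with the genotype panels are
    excluded with a log entry.  Returns the per-trait table
    (trait, n_snps, mean_prs_A, mean_prs_B, difference) and the z-test
    (``z = mean/sd`` of the differences).
    """
    rows = []
    for trait, rs in trait_sets.items():
        try:
            sub_a = align_risk_alleles(gm_a, rs)
            sub_b = align_risk_alleles(gm_b, rs)
        except EmptyIntersectionError:
            log.warning("trait %r excluded: zero aligned SNPs", trait)
            continue
        prs_a = polygenic_risk_score(sub_a)
        prs_b = polygenic_risk_score(sub_b)
        mean_a = float(np.nanmean(prs_a.scores))
        mean_b = float(np.nanmean(prs_b.scores))
        rows.append(
            {
                "trait": trait,
                "n_snps": sub_a.n_variants,
                "mean_prs_A": mean_a,
                "mean_prs_B": mean_b,
                "difference": mean_a - mean_b,
            }
        )
    if len(rows) < 2:
        raise ValueError("disease scan requires at least 2 usable traits")
    table = pd.DataFrame(rows)
    diffs = table["difference"].to_numpy()
    return table, _summarize(diffs)
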