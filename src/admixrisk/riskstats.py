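"""Cross-population risk statistics.

Per-SNP risk-allele log odds ratios between two populations, fixed- and
random-effects (DerSimonian–Laird) meta-analysis of those log ORs, and the
unweighted, normalized polygenic risk score.

The per-SNP contrast for populations A and B is

    log OR = ln[ (RA_A / NRA_A) / (RA_B / NRA_B) ]

computed from allele counts, with the Haldane–Anscombe continuity
correction (add 0.5 to all four cells) whenever any count is zero, and
Woolf's standard error ``sqrt(1/a + 1/b + 1/c + 1/d)``.  Positive values
mean a higher risk-allele burden in population A.

The polygenic risk score per individual is the ratio of risk-allele dosage
summed over SNPs to the number of callable alleles (2 per non-missing SNP);
missing SNPs contribute to neither numerator nor denominator and effect
sizes are never used as weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import MISSING, GenotypeMatrix
from .popgen import AlleleFrequencyRecord, allele_frequency_records

__all__ = [
    "ORResult",
    "MetaResult",
    "PRSVector",
    "snp_log_or",
    "or_table",
    "meta_analyze",
    "polygenic_risk_score",
]

log = logging.getLogger(__name__)

Z_95 = 1.96  # multiplier for 95% Wald intervals


@dataclass(frozen=True)
class ORResult:
    """Per-SNP log odds ratio (population A vs B) with 95% Wald CI."""

    rsid: str
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool
    corrected: bool  # Haldane–Anscombe correction applied

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.log_or <= self.ci_high):
            raise ValueError(f"{self.rsid}: CI does not bracket the estimate")


@dataclass(frozen=True)
class MetaResult:
    """Pooled log odds ratio across SNPs."""

    model: str  # "fixed" | "random"
    pooled_log_or: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float  # between-SNP variance (0 under the fixed model)
    q: float  # Cochran heterogeneity statistic
    k: int  # number of SNPs pooled


@dataclass
class PRSVector:
    """Per-individual normalized risk scores in [0, 1].

    Individuals with zero called SNPs carry NaN and ``defined == False``.
    """

    samples: list[str]
    scores: np.ndarray
    n_called_alleles: np.ndarray
    populations: list[str] | None = None

    @property
    def defined(self) -> np.ndarray:
        return self.n_called_alleles > 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample": self.samples,
                "score": self.scores,
                "n_called_alleles": self.n_called_alleles,
            }
        )
        if self.populations is not None:
            df.insert(1, "population", self.populations)
        return df


def snp_log_or(
    rec_a: AlleleFrequencyRecord, rec_b: AlleleFrequencyRecord
) -> ORResult:
    """Log odds ratio of the risk allele, population A versus B.

    Both records must describe the same SNP.  Zero cells trigger the
    Haldane–Anscombe correction (0.5 added to all four counts) before the
    odds ratio and Woolf SE are computed; ``corrected`` records this.
    """
    if rec_a.rsid != rec_b.rsid:
        raise ValueError(f"records describe different SNPs: "
                         f"{rec_a.rsid} vs {rec_b.rsid}")
    if not (rec_a.defined and rec_b.defined):
        raise ValueError(f"{rec_a.rsid}: undefined allele counts")
    a = float(rec_a.risk_allele_count)
    b = float(rec_a.nonrisk_allele_count)
    c = float(rec_b.risk_allele_count)
    d = float(rec_b.nonrisk_allele_count)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    # grouped so that swapping the populations negates log_or and leaves se
    # bit-identical (IEEE subtraction/addition commutativity)
    log_or = math.log(a / b) - math.log(c / d)
    se = math.sqrt((1.0 / a + 1.0 / b) + (1.0 / c + 1.0 / d))
    ci_low = log_or - Z_95 * se
    ci_high = log_or + Z_95 * se
    return ORResult(
        rsid=rec_a.rsid,
        log_or=log_or,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=(ci_low > 0.0) or (ci_high < 0.0),
        corrected=corrected,
    )


def or_table(
    gm: GenotypeMatrix, pop_a: str, pop_b: str
) -> list[ORResult]:
    """Per-SNP log ORs (A vs B) from a risk-aligned genotype matrix.

    SNPs with undefined counts in either population are skipped with a log
    message, mirroring the frequency-record contract.
    """
    recs_a = allele_frequency_records(gm, pop_a)
    recs_b = allele_frequency_records(gm, pop_b)
    out: list[ORResult] = []
    n_skipped = 0
    for ra, rb in zip(recs_a, recs_b):
        if not (ra.defined and rb.defined):
            n_skipped += 1
            log.warning("SNP %s skipped: undefined counts in a population", ra.rsid)
            continue
        out.append(snp_log_or(ra, rb))
    if n_skipped:
        log.warning("or_table: skipped %d SNP(s) with undefined counts", n_skipped)
    return out


def _fixed_pool(y: np.ndarray, var: np.ndarray) -> tuple[float, float, float]:
    """Inverse-variance pooled estimate, its SE, and Cochran's Q."""
    w = 1.0 / var
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (y - pooled) ** 2))
    return pooled, se, q


def meta_analyze(results: list[ORResult], model: str = "fixed") -> MetaResult:
    """Pool per-SNP log ORs by inverse-variance meta-analysis.

    ``model="fixed"`` uses weights ``1/se²``; ``model="random"`` estimates
    the between-SNP variance tau² by DerSimonian–Laird,

        tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),

    then re-weights by ``1/(se² + tau²)``.  The p-value is two-sided normal
    for pooled/SE.
    """
    if len(results) < 2:
        raise ValueError("meta-analysis requires at least 2 SNP results")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    y = np.array([r.log_or for r in results])
    var = np.array([r.se**2 for r in results])
    k = len(results)
    pooled_f, se_f, q = _fixed_pool(y, var)
    tau2 = 0.0
    pooled, se = pooled_f, se_f
    if model == "random":
        w = 1.0 / var
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (var + tau2)
        pooled = float(np.sum(w_star * y) / np.sum(w_star))
        se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = pooled / se
    p = 2.0 * float(norm.sf(abs(z)))
    return MetaResult(
        model=model,
        pooled_log_or=pooled,
        se=se,
        ci_low=pooled - Z_95 * se,
        ci_high=pooled + Z_95 * se,
        p_value=p,
        tau2=tau2,
        q=q,
        k=k,
    )


def polygenic_risk_score(gm: GenotypeMatrix) -> PRSVector:
    """Unweighted normalized polygenic risk score per individual.

    Requires a matrix aligned so that the counted allele is the risk allele
    at every SNP.  Score = Σ risk-allele dosage / Σ callable alleles, with
    missing SNPs contributing to neither sum; scores lie in [0, 1].
    Individuals with zero called SNPs get NaN and are flagged.
    """
    called = gm.dosages != MISSING
    numer = np.where(called, gm.dosages, 0).sum(axis=1).astype(float)
    denom = (2 * called.sum(axis=1)).astype(float)
    undefined = denom == 0
    if undefined.any():
        log.warning(
            "%d individual(s) with zero called risk SNPs: undefined PRS",
            int(undefined.sum()),
        )
    scores = np.where(undefined, np.nan, numer / np.maximum(denom, 1.0))
    return PRSVector(
        samples=list(gm.samples),
        scores=scores,
        n_called_alleles=denom.astype(int),
        populations=list(gm.populations) if gm.populations else None,
    )


def or_results_to_frame(results: list[ORResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
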