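"""Trait-associated SNP extraction from a GWAS-catalog-style table.

Three filtering rules produce the risk-SNP set for a trait:

1. the association comes from a study with at least ``min_study_snps``
   genotyped SNPs;
2. the SNP has the strongest association seen for its genomic locus,
   implemented as greedy distance-based clumping within a configurable
   window (default 1 Mb);
3. the association p-value is below ``p_threshold`` (default 1e-5).

"Genomic locus" is implemented as a base-pair window around each accepted
lead SNP; no LD-panel clumping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genio import CatalogEntry

__all__ = [
    "RiskEntry",
    "RiskSNPSet",
    "FilterAudit",
    "filter_catalog",
    "multi_trait_split",
    "write_risk_set",
    "read_risk_set",
]

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1.0e-5
DEFAULT_MIN_STUDY_SNPS = 100_000
DEFAULT_CLUMP_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class RiskEntry:
    """One retained (SNP, risk allele) pair."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    p_value: float


@dataclass
class RiskSNPSet:
    """Filtered catalog of risk SNPs for one trait, sorted by (chrom, pos)."""

    trait: str
    entries: list[RiskEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    @property
    def is_empty(self) -> bool:
        return not self.entries


@dataclass
class FilterAudit:
    """Which rule removed each rejected catalog row."""

    rejected: list[tuple[str, str]] = field(default_factory=list)  # (rsid, rule)

    def add(self, rsid: str, rule: str) -> None:
        self.rejected.append((rsid, rule))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected, columns=["rsid", "rule"])


def _chrom_key(chrom: str):
    # numeric chromosomes sort numerically, others lexicographically after
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def filter_catalog(
    entries: Iterable[CatalogEntry],
    trait: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_study_snps: int = DEFAULT_MIN_STUDY_SNPS,
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    audit: FilterAudit | None = None,
) -> RiskSNPSet:
    """Apply the three-rule filter and return the trait's risk-SNP set.

    Clumping is greedy: survivors of the study-size and p-value rules are
    sorted by ascending p (ties broken by larger study, then rsid) and each
    SNP is accepted unless an already-accepted SNP lies on the same
    chromosome within ``clump_window_bp``.  The result is canonical — it does
    not depend on input row order — and is sorted by (chrom, pos).

    An empty result is returned as an explicit empty set (``is_empty``), not
    an error, so callers can distinguish "nothing survived" from failure.
    """
    if audit is None:
        audit = FilterAudit()
    survivors: list[CatalogEntry] = []
    seen: dict[str, CatalogEntry] = {}
    for e in entries:
        if e.trait != trait:
            continue
        if e.study_snp_count < min_study_snps:
            audit.add(e.rsid, "study_size")
            continue
        if not (e.p_value < p_threshold):
            audit.add(e.rsid, "p_threshold")
            continue
        # duplicate rsids: keep the strongest association
        prev = seen.get(e.rsid)
        if prev is None or e.p_value < prev.p_value:
            seen[e.rsid] = e
        else:
            audit.add(e.rsid, "duplicate_rsid")
    survivors = sorted(
        seen.values(), key=lambda e: (e.p_value, -e.study_snp_count, e.rsid)
    )

    accepted: list[CatalogEntry] = []
    for e in survivors:
        clumped = any(
            a.chrom == e.chrom and abs(a.pos - e.pos) <= clump_window_bp
            for a in accepted
        )
        if clumped:
            audit.add(e.rsid, "clumped")
        else:
            accepted.append(e)

    accepted.sort(key=lambda e: (_chrom_key(e.chrom), e.pos))
    result = RiskSNPSet(
        trait=trait,
        entries=[
            RiskEntry(e.rsid, e.chrom, e.pos, e.risk_allele, e.p_value)
            for e in accepted
        ],
    )
    if result.is_empty:
        log.warning("trait %r: no catalog entries survived filtering", trait)
    return result


def multi_trait_split(
    entries: Iterable[CatalogEntry],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_study_snps: int = DEFAULT_MIN_STUDY_SNPS,
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> dict[str, RiskSNPSet]:
    """Filter every trait independently; traits left empty are omitted."""
    entries = list(entries)
    traits = list(dict.fromkeys(e.trait for e in entries))
    out: dict[str, RiskSNPSet] = {}
    for trait in traits:
        rs = filter_catalog(
            entries, trait, p_threshold, min_study_snps, clump_window_bp
        )
        if rs.is_empty:
            log.info("trait %r omitted: empty after filtering", trait)
            continue
        out[trait] = rs
    return out


def write_risk_set(rs: RiskSNPSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [vars(e) for e in rs.entries],
        columns=["rsid", "chrom", "pos", "risk_allele", "p_value"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_risk_set(path: str | Path, trait: str = "") -> RiskSNPSet:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    entries = [
        RiskEntry(r.rsid, r.chrom, int(r.pos), r.risk_allele, float(r.p_value))
        for r in df.itertuples()
    ]
    return RiskSNPSet(trait=trait, entries=entries)
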