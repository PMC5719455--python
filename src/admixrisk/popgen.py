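"""Population-genetic primitives.

Allele-frequency tabulation, sliding-window LD pruning, allele-sharing
distances, classical multidimensional scaling, and supervised maximum-
likelihood ancestry-fraction estimation against reference allele
frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencyRecord",
    "DistanceMatrix",
    "AncestryFractions",
    "ReferenceFrequencies",
    "allele_frequencies",
    "allele_frequency_records",
    "ld_prune",
    "allele_sharing_distance",
    "project_mds",
    "estimate_ancestry_supervised",
]

log = logging.getLogger(__name__)

FREQ_CLIP = 1e-4  # keeps the ancestry log-likelihood finite


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """Risk-allele counts and frequency for one SNP in one population."""

    population: str
    rsid: str
    risk_allele_count: int
    nonrisk_allele_count: int

    @property
    def total(self) -> int:
        return self.risk_allele_count + self.nonrisk_allele_count

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def ra(self) -> float:
        """Risk-allele frequency."""
        if not self.defined:
            return float("nan")
        return self.risk_allele_count / self.total

    @property
    def nra(self) -> float:
        """Non-risk-allele frequency (1 − RA)."""
        return 1.0 - self.ra if self.defined else float("nan")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in [0, 1] with zero diagonal."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with samples")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class AncestryFractions:
    """Per-individual simplex weights over K ancestral populations."""

    samples: list[str]
    labels: tuple[str, ...]
    fractions: np.ndarray  # N×K
    converged: np.ndarray | None = None  # per-individual flags
    log_likelihood_path: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.fractions, dtype=float)
        if q.shape != (len(self.samples), len(self.labels)):
            raise ValueError("fractions shape inconsistent with samples/labels")
        if (q < -1e-12).any():
            raise ValueError("negative ancestry fraction")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ancestry fractions must sum to 1 per individual")
        self.fractions = q

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=list(self.labels))
        df.insert(0, "sample", self.samples)
        return df


@dataclass
class ReferenceFrequencies:
    """K×M counted-allele frequencies for the reference (ancestral) panels.

    Frequencies refer to the genotype matrix's counted allele at each SNP.
    """

    labels: tuple[str, ...]
    rsids: list[str]
    freqs: np.ndarray  # K×M

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (len(self.labels), len(self.rsids)):
            raise ValueError("frequency matrix shape inconsistent with labels/rsids")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("reference frequencies outside [0, 1]")
        self.freqs = f

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs.T, columns=list(self.labels))
        df.insert(0, "rsid", self.rsids)
        return df

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceFrequencies":
        df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
        labels = tuple(c for c in df.columns if c != "rsid")
        return cls(labels, df["rsid"].tolist(), df[list(labels)].to_numpy().T)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def _count_arrays(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(risk counts, total called alleles) per variant, summed over samples."""
    called = gm.dosages != MISSING
    risk = np.where(called, gm.dosages, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return risk.astype(int), total.astype(int)


def allele_frequencies(gm: GenotypeMatrix, by_population: bool = True) -> pd.DataFrame:
    """Tabulate counted-allele (risk-allele) frequencies.

    Missing calls contribute to neither numerator nor denominator.  SNPs with
    zero non-missing calls in a population are flagged ``defined == False``
    and logged; downstream consumers must exclude them.
    """
    groups: dict[str, GenotypeMatrix]
    if by_population and gm.populations is not None:
        groups = gm.by_population()
    else:
        groups = {"all": gm}
    frames = []
    for pop, sub in groups.items():
        risk, total = _count_arrays(sub)
        undefined = total == 0
        if undefined.any():
            log.warning(
                "population %r: %d SNP(s) with zero non-missing calls",
                pop, int(undefined.sum()),
            )
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "rsid": sub.variant_ids,
                    "risk_allele": [v.counted_allele for v in sub.variants],
                    "risk_allele_count": risk,
                    "nonrisk_allele_count": total - risk,
                    "risk_allele_freq": np.where(
                        undefined, np.nan, risk / np.maximum(total, 1)
                    ),
                    "defined": ~undefined,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def allele_frequency_records(
    gm: GenotypeMatrix, population: str
) -> list[AlleleFrequencyRecord]:
    """Typed per-SNP records for one population label (or 'all')."""
    if population == "all" or gm.populations is None:
        sub = gm
    else:
        sub = gm.by_population()[population]
    risk, total = _count_arrays(sub)
    return [
        AlleleFrequencyRecord(
            population=population,
            rsid=v.id,
            risk_allele_count=int(r),
            nonrisk_allele_count=int(t - r),
        )
        for v, r, t in zip(sub.variants, risk, total)
    ]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_snps: int = 50,
    step_snps: int = 5,
) -> list[str]:
    """Sliding-window LD pruning on squared genotype-dosage correlation.

    Within each window of ``window_snps`` variants (advancing by
    ``step_snps``), any pair with r² above the threshold loses its
    later-positioned member.  Missing calls are mean-imputed for the
    correlation only.  Monomorphic SNPs are retained untested (logged).
    Returns retained variant IDs in original order.
    """
    if gm.n_variants < 2:
        return gm.variant_ids
    d = gm.dosages.astype(float)
    miss = gm.dosages == MISSING
    col_n = np.maximum((~miss).sum(axis=0), 1)
    col_mean = np.where(miss, 0.0, d).sum(axis=0) / col_n
    d = np.where(miss, col_mean[None, :], d)
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    mono = sd == 0.0
    if mono.any():
        log.warning("%d monomorphic SNP(s) retained untested", int(mono.sum()))

    m = gm.n_variants
    kept = np.ones(m, dtype=bool)
    z = np.where(mono[None, :], 0.0, d / np.where(sd == 0, 1.0, sd)[None, :])
    n = gm.n_samples
    for start in range(0, max(m - 1, 1), step_snps):
        idx = np.arange(start, min(start + window_snps, m))
        idx = idx[kept[idx] & ~mono[idx]]
        if idx.size < 2:
            if start + window_snps >= m:
                break
            continue
        r = z[:, idx].T @ z[:, idx] / n
        r2 = r**2
        for a in range(idx.size):
            if not kept[idx[a]]:
                continue
            for b in range(a + 1, idx.size):
                if kept[idx[b]] and r2[a, b] > r2_threshold:
                    kept[idx[b]] = False
        if start + window_snps >= m:
            break
    return [v.id for v, k in zip(gm.variants, kept) if k]


# ---------------------------------------------------------------------------
# allele-sharing distance
# ---------------------------------------------------------------------------


def allele_sharing_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distances.

    Per pair, over loci called in both samples, similarity
    ``s = 1 − |d_i − d_j| / 2`` (identical genotypes 1, het vs hom 0.5,
    opposite homozygotes 0); distance is ``1 − mean(s)``.  A pair with zero
    jointly called loci is an error.
    """
    called = (gm.dosages != MISSING).astype(np.float64)
    joint = called @ called.T  # pairwise jointly-called locus counts
    if (joint == 0).any():
        i, j = np.argwhere(joint == 0)[0]
        raise ValueError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share zero "
            f"jointly-called loci"
        )
    # sum |d_i - d_j| via one-hot cross products: |g-h| weights
    g = [((gm.dosages == v) & (gm.dosages != MISSING)).astype(np.float64)
         for v in (0, 1, 2)]
    cross01 = g[0] @ g[1].T
    cross02 = g[0] @ g[2].T
    cross12 = g[1] @ g[2].T
    abs_diff = (cross01 + cross01.T) + 2.0 * (cross02 + cross02.T) + (
        cross12 + cross12.T
    )
    dist = (abs_diff / 2.0) / joint
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(gm.samples, dist)


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------


def project_mds(dm: DistanceMatrix, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers −½·D², takes the top ``n_dims`` eigenvectors scaled by
    √eigenvalue.  Dimensions with non-positive eigenvalues come back as zero
    coordinates with a warning.  Sign convention: each column's
    largest-magnitude loading is positive.
    """
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    coords = np.zeros((n, n_dims))
    for out_k, k in enumerate(order):
        if vals[k] <= 0:
            warnings.warn(
                f"MDS dimension {out_k}: non-positive eigenvalue "
                f"{vals[k]:.3g}; coordinates set to zero",
                stacklevel=2,
            )
            continue
        v = vecs[:, k] * np.sqrt(vals[k])
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, out_k] = v
    return coords


# ---------------------------------------------------------------------------
# supervised ancestry estimation
# ---------------------------------------------------------------------------


def estimate_ancestry_supervised(
    gm: GenotypeMatrix,
    reference: ReferenceFrequencies,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AncestryFractions:
    """Maximum-likelihood ancestry fractions against reference frequencies.

    For individual dosages ``d_m`` over shared SNPs, maximizes the binomial
    log-likelihood

        Σ_m [ d_m·ln(Σ_k q_k p_km) + (2−d_m)·ln(Σ_k q_k (1−p_km)) ]

    over the simplex via EM multiplicative updates from a uniform start
    (missing loci skipped).  Reference frequencies are clipped into
    [1e-4, 1−1e-4] so the likelihood stays finite.  The total log-likelihood
    is non-decreasing across iterations and is returned for inspection.

    Individuals still moving by more than ``tol`` (max absolute change in q)
    at ``max_iter`` are returned as-is with ``converged[i] = False``.
    """
    ref_index = {r: j for j, r in enumerate(reference.rsids)}
    gm_cols, ref_cols = [], []
    for j, v in enumerate(gm.variants):
        rj = ref_index.get(v.id)
        if rj is not None:
            gm_cols.append(j)
            ref_cols.append(rj)
    if not gm_cols:
        raise ValueError("no SNPs shared between genotypes and reference panel")
    p = np.clip(reference.freqs[:, ref_cols], FREQ_CLIP, 1.0 - FREQ_CLIP)  # K×M
    k = p.shape[0]
    if k > 1 and all(
        np.allclose(p[0], p[i], atol=1e-12) for i in range(1, k)
    ):
        warnings.warn(
            "reference populations have identical frequencies; ancestry "
            "fractions are non-identifiable, returning uniform weights",
            stacklevel=2,
        )
        n = gm.n_samples
        return AncestryFractions(
            gm.samples, reference.labels, np.full((n, k), 1.0 / k),
            converged=np.ones(n, dtype=bool),
            log_likelihood_path=np.array([]),
        )

    d = gm.dosages[:, gm_cols].astype(np.float64)
    w = (gm.dosages[:, gm_cols] != MISSING).astype(np.float64)
    d = np.where(w > 0, d, 0.0)
    two_m = 2.0 * w.sum(axis=1)  # callable alleles per individual
    if (two_m == 0).any():
        raise ValueError("an individual has zero called SNPs in the overlap")

    n = gm.n_samples
    q = np.full((n, k), 1.0 / k)
    pt = p.T  # M×K
    one_pt = 1.0 - pt
    ll_path = []
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        a = q @ p  # N×M mixture freq of counted allele
        b = q @ (1.0 - p)
        ll_path.append(float(np.sum(w * (d * np.log(a) + (2.0 - d) * np.log(b)))))
        t = ((d * w) / a) @ pt + (((2.0 - d) * w) / b) @ one_pt  # N×K
        q_new = q * t / two_m[:, None]
        q_new /= q_new.sum(axis=1, keepdims=True)
        delta = np.abs(q_new - q).max(axis=1)
        q = q_new
        converged = delta < tol
        if converged.all():
            break
    else:
        log.warning(
            "ancestry EM: %d individual(s) not converged after %d iterations",
            int((~converged).sum()), max_iter,
        )
    a = q @ p
    b = q @ (1.0 - p)
    ll_path.append(float(np.sum(w * (d * np.log(a) + (2.0 - d) * np.log(b)))))
    return AncestryFractions(
        gm.samples,
        reference.labels,
        q,
        converged=converged,
        log_likelihood_path=np.asarray(ll_path),
    )
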