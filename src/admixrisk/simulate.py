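"""Synthetic admixed-genotype generator with known ground truth.

Emulates a two-(or more-)cohort study of admixed individuals drawing
ancestry from K ancestral populations:

* ancestral allele frequencies follow the Balding–Nichols model — per SNP a
  shared ancestral frequency ``p0 ~ U[0.05, 0.95]`` and, for population k
  with drift parameter ``F_k``, a Beta draw with mean ``p0`` and variance
  ``F_k · p0 (1 − p0)``;
* each individual's ancestry fractions ``q`` are Dirichlet draws from its
  cohort profile; each of the two allele copies at a SNP picks an ancestry
  from ``q`` and then an allele Bernoulli(p_ancestry);
* a configurable subset of SNPs is designated as risk SNPs whose risk-allele
  frequency in one target ancestry is shifted by ``risk_shift_delta``,
  creating an ancestry-correlated risk pattern with known direction;
* a GWAS-catalog-style table is emitted containing one passing entry per
  truth risk SNP plus configurable decoys (weak p-values, small studies,
  same-locus shadow entries) so catalog filtering has a known right answer.

SNPs are statistically independent (no LD) except for an optional
duplicate-column mode that exists solely to exercise LD pruning.

All randomness flows from a single master seed through named independent
substreams (frequencies / fractions / genotypes / missingness / risk-SNP
choice / catalog), so changing one stage's parameters never perturbs the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import RiskEntry, RiskSNPSet
from .genio import MISSING, CatalogEntry, GenotypeMatrix, VariantRecord

__all__ = [
    "PopulationProfile",
    "SimulationConfig",
    "TruthSet",
    "SimulatedStudy",
    "draw_ancestral_frequencies",
    "designate_risk_snps",
    "draw_admixed_genotypes",
    "generate_catalog",
    "generate_disease_catalog",
    "simulate_study",
    "choco_like_config",
]

# substream indices off the master seed
_STREAMS = {
    "frequencies": 0,
    "fractions": 1,
    "genotypes": 2,
    "missingness": 3,
    "risk_snps": 4,
    "catalog": 5,
    "duplicates": 6,
}

#: Default continental labels (African / European / Native American-like).
DEFAULT_LABELS = ("AFR", "EUR", "NAM")

#: Default Balding–Nichols drift per ancestral population.  Values reflect
#: typical continental differentiation from a common ancestor, with the
#: American branch the most drifted.
DEFAULT_FST = (0.10, 0.14, 0.25)

_CHROMS = 22
_POS_STEP = 2_000_000  # wide spacing keeps truth SNPs outside clump windows

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "T"), ("G", "A")]


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PopulationProfile:
    """One simulated cohort: label, size, and Dirichlet ancestry profile."""

    label: str
    n_individuals: int
    dirichlet_alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError(f"{self.label}: n_individuals must be >= 1")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigurationError(
                f"{self.label}: every dirichlet_alpha entry must be > 0"
            )


def _default_profiles() -> tuple[PopulationProfile, ...]:
    # Afro-Colombian-like (mean 76/13/11 AFR/EUR/NAM) vs Mestizo-like
    # (7/75/18); concentration 15 gives realistic within-cohort spread
    # (sd of the major fraction ~ 0.10).
    return (
        PopulationProfile("choco_like", 94, (15 * 0.76, 15 * 0.13, 15 * 0.11)),
        PopulationProfile("antioquia_like", 94, (15 * 0.07, 15 * 0.75, 15 * 0.18)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic study.

    Identical config + seed reproduces every output bit-for-bit.
    """

    n_ancestral_pops: int = 3
    fst_per_pop: tuple[float, ...] = DEFAULT_FST
    n_snps: int = 2_000
    pop_profiles: tuple[PopulationProfile, ...] = field(
        default_factory=_default_profiles
    )
    n_risk_snps: int = 165
    risk_shift_delta: float = 0.15
    shift_target_ancestry: int = 0
    missing_rate: float = 0.01
    seed: int = 0
    ancestry_labels: tuple[str, ...] = DEFAULT_LABELS
    n_duplicate_snps: int = 0  # extra duplicated columns, for LD-prune tests

    def __post_init__(self) -> None:
        k = self.n_ancestral_pops
        if k < 2:
            raise ConfigurationError("need at least 2 ancestral populations")
        if len(self.fst_per_pop) != k:
            raise ConfigurationError("fst_per_pop length must equal K")
        if any(not (0.0 < f < 1.0) for f in self.fst_per_pop):
            raise ConfigurationError("every Fst must be strictly in (0, 1)")
        if any(len(p.dirichlet_alpha) != k for p in self.pop_profiles):
            raise ConfigurationError("every dirichlet_alpha must have length K")
        if self.n_risk_snps > self.n_snps:
            raise ConfigurationError("n_risk_snps cannot exceed n_snps")
        if not (-0.5 <= self.risk_shift_delta <= 0.5):
            raise ConfigurationError("risk_shift_delta must lie in [-0.5, 0.5]")
        if not (0 <= self.shift_target_ancestry < k):
            raise ConfigurationError("shift_target_ancestry out of range")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if len(self.ancestry_labels) != k:
            raise ConfigurationError("ancestry_labels length must equal K")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named substream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    @property
    def n_individuals(self) -> int:
        return sum(p.n_individuals for p in self.pop_profiles)


@dataclass
class TruthSet:
    """Ground truth behind a simulated study."""

    ancestral_freqs: np.ndarray  # K×M risk/alt-allele frequencies
    ancestry_fractions: np.ndarray  # N×K simplex rows
    risk_snp_ids: list[str]
    risk_alleles: list[str]
    ancestry_labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if ((self.ancestral_freqs < 0) | (self.ancestral_freqs > 1)).any():
            raise ValueError("ancestral frequencies outside [0, 1]")
        rows = self.ancestry_fractions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("ancestry fraction rows must sum to 1")


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    truth: TruthSet
    risk_set: RiskSNPSet
    catalog: list[CatalogEntry]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _variant_meta(config: SimulationConfig) -> list[VariantRecord]:
    """Deterministic variant identities: 22 contiguous chromosome blocks,
    positions 2 Mb apart so designated risk SNPs never clump each other."""
    m = config.n_snps
    per_chrom = -(-m // _CHROMS)  # ceil
    out = []
    for i in range(m):
        chrom = str(1 + i // per_chrom)
        pos = 1_000_000 + _POS_STEP * (i % per_chrom)
        ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        out.append(VariantRecord(f"rs{i + 1}", chrom, pos, ref, alt))
    return out


def draw_ancestral_frequencies(config: SimulationConfig) -> np.ndarray:
    """Draw the K×M Balding–Nichols frequency matrix.

    Per SNP, a common ancestral frequency ``p0 ~ U[0.05, 0.95]``; population
    k draws Beta(p0·(1−F_k)/F_k, (1−p0)·(1−F_k)/F_k), which has mean ``p0``
    and variance ``F_k · p0 (1 − p0)``.
    """
    rng = config.rng("frequencies")
    p0 = rng.uniform(0.05, 0.95, size=config.n_snps)
    freqs = np.empty((config.n_ancestral_pops, config.n_snps))
    for k, f in enumerate(config.fst_per_pop):
        a = p0 * (1.0 - f) / f
        b = (1.0 - p0) * (1.0 - f) / f
        freqs[k] = rng.beta(a, b)
    return freqs


def designate_risk_snps(
    config: SimulationConfig, freqs: np.ndarray
) -> tuple[np.ndarray, RiskSNPSet]:
    """Pick risk SNPs and shift their frequency in the target ancestry.

    Selects ``n_risk_snps`` SNPs without replacement, designates the
    alternate allele as the risk allele, and adds ``risk_shift_delta`` to its
    frequency in ``shift_target_ancestry``, clamped to [0.01, 0.99].  Returns
    the modified copy of ``freqs`` and the truth risk-SNP set.
    """
    rng = config.rng("risk_snps")
    variants = _variant_meta(config)
    idx = np.sort(rng.choice(config.n_snps, size=config.n_risk_snps, replace=False))
    freqs = freqs.copy()
    if config.risk_shift_delta != 0.0:
        freqs[config.shift_target_ancestry, idx] = np.clip(
            freqs[config.shift_target_ancestry, idx] + config.risk_shift_delta,
            0.01,
            0.99,
        )
    p_values = 10.0 ** rng.uniform(-30, -8, size=config.n_risk_snps)
    entries = [
        RiskEntry(
            rsid=variants[i].id,
            chrom=variants[i].chrom,
            pos=variants[i].pos,
            risk_allele=variants[i].alt_allele,
            p_value=float(p),
        )
        for i, p in zip(idx, p_values)
    ]
    return freqs, RiskSNPSet(trait="trait_of_interest", entries=entries)


def draw_admixed_genotypes(
    config: SimulationConfig, freqs: np.ndarray
) -> tuple[GenotypeMatrix, TruthSet]:
    """Draw admixed genotypes given ancestral frequencies.

    Per individual: ``q ~ Dirichlet(alpha)`` of its cohort profile; per
    allele copy and SNP, an ancestry drawn categorically from ``q`` and an
    allele Bernoulli(p_ancestry); genotype = sum of the two copies.  Missing
    calls are injected at ``missing_rate`` afterwards.
    """
    k, m = freqs.shape
    if (k, m) != (config.n_ancestral_pops, config.n_snps):
        raise ConfigurationError(
            f"frequency matrix shape {freqs.shape} does not match config "
            f"({config.n_ancestral_pops}, {config.n_snps})"
        )
    rng_q = config.rng("fractions")
    rng_g = config.rng("genotypes")

    q_rows = []
    labels: list[str] = []
    samples: list[str] = []
    for prof in config.pop_profiles:
        draws = rng_q.dirichlet(prof.dirichlet_alpha, size=prof.n_individuals)
        # guard against degenerate gamma underflow at extreme alphas
        draws = draws / draws.sum(axis=1, keepdims=True)
        q_rows.append(draws)
        labels.extend([prof.label] * prof.n_individuals)
        samples.extend(
            f"{prof.label}_{i + 1:04d}" for i in range(prof.n_individuals)
        )
    q = np.vstack(q_rows)  # N×K
    n = q.shape[0]

    cum_q = np.cumsum(q, axis=1)  # N×K
    dosages = np.zeros((n, m), dtype=np.int16)
    for _copy in range(2):
        u = rng_g.random((n, m))
        anc = (u[:, :, None] > cum_q[:, None, :]).sum(axis=2)  # N×M in [0,K)
        p = freqs[anc, np.arange(m)[None, :]]
        dosages += (rng_g.random((n, m)) < p).astype(np.int16)

    if config.missing_rate > 0:
        rng_m = config.rng("missingness")
        mask = rng_m.random((n, m)) < config.missing_rate
        dosages[mask] = MISSING

    variants = _variant_meta(config)
    if config.n_duplicate_snps > 0:
        # duplicated columns exist solely to exercise LD pruning
        dup_rng = config.rng("duplicates")
        dup_idx = dup_rng.choice(m, size=config.n_duplicate_snps, replace=False)
        dup_cols = dosages[:, dup_idx]
        dup_vars = [
            VariantRecord(
                f"{variants[j].id}_dup",
                variants[j].chrom,
                variants[j].pos + 1,
                variants[j].ref_allele,
                variants[j].alt_allele,
            )
            for j in dup_idx
        ]
        dosages = np.hstack([dosages, dup_cols])
        variants = variants + dup_vars

    gm = GenotypeMatrix(samples, variants, dosages, labels)
    truth = TruthSet(
        ancestral_freqs=freqs,
        ancestry_fractions=q,
        risk_snp_ids=[],
        risk_alleles=[],
        ancestry_labels=config.ancestry_labels,
    )
    return gm, truth


def generate_catalog(
    truth_risk_set: RiskSNPSet,
    config: SimulationConfig,
    n_weak_p: int = 10,
    n_small_study: int = 5,
    n_shadow: int = 20,
    trait: str | None = None,
) -> list[CatalogEntry]:
    """Emit catalog rows: one passing entry per truth risk SNP plus decoys.

    Decoys are rows a correct three-rule filter must remove: entries with
    p ≥ 1e-5 (``n_weak_p``), entries from studies with < 100,000 SNPs
    (``n_small_study``), and weaker same-locus *shadow* entries placed within
    the clump window of a truth SNP (``n_shadow``).
    """
    rng = config.rng("catalog")
    trait = trait or truth_risk_set.trait
    rows: list[CatalogEntry] = []
    for e in truth_risk_set.entries:
        rows.append(
            CatalogEntry(
                rsid=e.rsid,
                chrom=e.chrom,
                pos=e.pos,
                trait=trait,
                risk_allele=e.risk_allele,
                p_value=e.p_value,
                study_snp_count=int(rng.integers(100_000, 2_500_000)),
                study_id=f"GCST{rng.integers(1, 10_000):06d}",
            )
        )
    k = len(truth_risk_set.entries)
    counter = 0

    def _decoy_id() -> str:
        nonlocal counter
        counter += 1
        return f"rsdecoy{counter}"

    for _ in range(n_weak_p):
        host = truth_risk_set.entries[rng.integers(0, k)]
        rows.append(
            CatalogEntry(
                rsid=_decoy_id(),
                chrom=host.chrom,
                pos=host.pos + int(rng.integers(1_200_000, 1_800_000)),
                trait=trait,
                risk_allele="A",
                p_value=float(10.0 ** rng.uniform(-5, -1)),
                study_snp_count=int(rng.integers(100_000, 2_500_000)),
                study_id=f"GCST{rng.integers(1, 10_000):06d}",
            )
        )
    for _ in range(n_small_study):
        host = truth_risk_set.entries[rng.integers(0, k)]
        rows.append(
            CatalogEntry(
                rsid=_decoy_id(),
                chrom=host.chrom,
                pos=host.pos + int(rng.integers(1_200_000, 1_800_000)),
                trait=trait,
                risk_allele="G",
                p_value=float(10.0 ** rng.uniform(-12, -8)),
                study_snp_count=int(rng.integers(1_000, 99_999)),
                study_id=f"GCST{rng.integers(1, 10_000):06d}",
            )
        )
    for _ in range(n_shadow):
        host = truth_risk_set.entries[rng.integers(0, k)]
        # weaker p than every truth entry at the locus, inside the window
        rows.append(
            CatalogEntry(
                rsid=_decoy_id(),
                chrom=host.chrom,
                pos=host.pos + int(rng.integers(1_000, 900_000)),
                trait=trait,
                risk_allele="C",
                p_value=float(host.p_value * 10.0 ** rng.uniform(0.5, 2.0)),
                study_snp_count=int(rng.integers(100_000, 2_500_000)),
                study_id=f"GCST{rng.integers(1, 10_000):06d}",
            )
        )
    order = rng.permutation(len(rows))
    return [rows[i] for i in order]


def generate_disease_catalog(
    config: SimulationConfig,
    exclude_rsids: Sequence[str],
    n_traits: int = 40,
    snps_per_trait: int = 30,
) -> list[CatalogEntry]:
    """Catalog rows for decoy diseases drawn from the non-risk SNP panel.

    Each trait receives ``snps_per_trait`` SNPs sampled without replacement
    from the simulated panel minus ``exclude_rsids``; traits may share SNPs
    with each other (the real catalog does too).  All rows pass the
    three-rule filter by construction: positions 2 Mb apart never clump.
    """
    rng = config.rng("catalog")
    rng.integers(0, 2**31)  # offset from generate_catalog's draws
    variants = _variant_meta(config)
    excluded = set(exclude_rsids)
    pool = [v for v in variants if v.id not in excluded]
    if snps_per_trait > len(pool):
        raise ConfigurationError("snps_per_trait exceeds available non-risk SNPs")
    rows: list[CatalogEntry] = []
    for t in range(n_traits):
        idx = rng.choice(len(pool), size=snps_per_trait, replace=False)
        for i in idx:
            v = pool[i]
            rows.append(
                CatalogEntry(
                    rsid=v.id,
                    chrom=v.chrom,
                    pos=v.pos,
                    trait=f"disease_{t + 1:03d}",
                    risk_allele=v.alt_allele,
                    p_value=float(10.0 ** rng.uniform(-20, -6)),
                    study_snp_count=int(rng.integers(100_000, 2_500_000)),
                    study_id=f"GCST{rng.integers(1, 10_000):06d}",
                )
            )
    return rows


def simulate_study(
    config: SimulationConfig,
    n_weak_p: int = 10,
    n_small_study: int = 5,
    n_shadow: int = 20,
) -> SimulatedStudy:
    """Run all stages: frequencies → risk designation → genotypes → catalog."""
    freqs = draw_ancestral_frequencies(config)
    freqs, risk_set = designate_risk_snps(config, freqs)
    gm, truth = draw_admixed_genotypes(config, freqs)
    truth.risk_snp_ids = risk_set.rsids
    truth.risk_alleles = [e.risk_allele for e in risk_set.entries]
    cat = generate_catalog(
        risk_set, config, n_weak_p=n_weak_p, n_small_study=n_small_study,
        n_shadow=n_shadow,
    )
    return SimulatedStudy(config, gm, truth, risk_set, cat)


def choco_like_config(**overrides) -> SimulationConfig:
    """The default two-cohort study configuration (94 + 94 individuals,
    165 risk SNPs, +0.15 risk-allele shift toward African-like ancestry)."""
    return SimulationConfig(**overrides)


def write_truth_files(truth: TruthSet, gm: GenotypeMatrix, outdir) -> None:
    """Write truth TSVs: ancestry fractions, ancestral frequencies, risk SNPs."""
    from pathlib import Path

    outdir = Path(outdir)
    k = truth.ancestral_freqs.shape[0]
    frac = pd.DataFrame(
        truth.ancestry_fractions, columns=list(truth.ancestry_labels)
    )
    frac.insert(0, "sample", gm.samples)
    frac.to_csv(outdir / "truth_ancestry_fractions.tsv", sep="\t", index=False)
    freq = pd.DataFrame(
        truth.ancestral_freqs.T, columns=list(truth.ancestry_labels)
    )
    freq.insert(0, "rsid", [v.id for v in gm.variants[: truth.ancestral_freqs.shape[1]]])
    freq.to_csv(outdir / "truth_ancestral_freqs.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"rsid": truth.risk_snp_ids, "risk_allele": truth.risk_alleles}
    ).to_csv(outdir / "truth_risk_snps.tsv", sep="\t", index=False)
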