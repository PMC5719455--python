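"""Genotype and catalog I/O.

In-memory containers for biallelic genotype dosages and GWAS-catalog-style
association tables, plus readers/writers for the plain-text formats the
pipeline touches: VCF v4.2 (GT only), PLINK-text ``.ped``/``.map``, and
tab-separated catalog / frequency tables.

Dosages count copies of a designated *counted allele* per sample and take
values in ``{0, 1, 2}``; missing calls are stored as :data:`MISSING` (−1).
Coordinates are 1-based throughout (VCF convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ParseError",
    "SchemaError",
    "EmptyIntersectionError",
    "VariantRecord",
    "GenotypeMatrix",
    "CatalogEntry",
    "read_vcf",
    "write_vcf",
    "read_plink_text",
    "write_plink_text",
    "read_catalog",
    "write_catalog",
    "align_risk_alleles",
]

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in a dosage matrix.
MISSING = -1

CATALOG_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "trait",
    "risk_allele",
    "p_value",
    "study_snp_count",
    "study_id",
]


class ParseError(ValueError):
    """A genotype file could not be parsed."""


class SchemaError(ValueError):
    """A tabular input does not carry the required columns."""


class EmptyIntersectionError(ValueError):
    """No variants shared between a genotype matrix and a SNP set."""


@dataclass(frozen=True)
class VariantRecord:
    """Identity of one biallelic variant.

    ``counted_allele`` names which of ref/alt the dosage counts; it defaults
    to the alternate allele (the VCF alt-dosage convention).
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    counted_allele: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.counted_allele is None:
            object.__setattr__(self, "counted_allele", self.alt_allele)
        elif self.counted_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError(
                f"{self.id}: counted allele {self.counted_allele!r} is neither "
                f"ref nor alt"
            )

    @property
    def other_allele(self) -> str:
        """The allele that is *not* counted."""
        return self.ref_allele if self.counted_allele == self.alt_allele else self.alt_allele


class GenotypeMatrix:
    """Samples × variants dosage matrix with sample/variant metadata.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers (length N).
    variants
        Ordered :class:`VariantRecord` list (length M) with unique ids.
    dosages
        N×M integer array with entries in ``{0, 1, 2, MISSING}``.
    populations
        Optional per-sample population labels (length N).
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[VariantRecord],
        dosages: np.ndarray,
        populations: Sequence[str] | None = None,
    ) -> None:
        self.samples = list(samples)
        self.variants = list(variants)
        self.dosages = np.asarray(dosages, dtype=np.int16)
        self.populations = list(populations) if populations is not None else None
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.samples), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{n} samples × {m} variants"
            )
        if len(set(self.samples)) != n:
            raise ValueError("sample IDs are not unique")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise ValueError("variant IDs are not unique")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("population labels inconsistent with sample count")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages contain entries outside {0,1,2,missing}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def missing_mask(self) -> np.ndarray:
        """Boolean N×M array, True where the call is missing."""
        return self.dosages == MISSING

    # -- subsetting ----------------------------------------------------------

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            self.samples,
            [self.variants[i] for i in idx],
            self.dosages[:, idx].copy(),
            self.populations,
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.variants,
            self.dosages[idx, :].copy(),
            [self.populations[i] for i in idx] if self.populations else None,
        )

    def by_population(self) -> dict[str, "GenotypeMatrix"]:
        """Split into one matrix per population label, preserving order."""
        if self.populations is None:
            raise ValueError("genotype matrix carries no population labels")
        out: dict[str, GenotypeMatrix] = {}
        for pop in dict.fromkeys(self.populations):
            idx = [i for i, p in enumerate(self.populations) if p == pop]
            out[pop] = self.subset_samples(idx)
        return out

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two matrices with identical variant panels."""
        if self.variant_ids != other.variant_ids:
            raise ValueError("variant panels differ; cannot concatenate samples")
        pops = None
        if self.populations is not None and other.populations is not None:
            pops = self.populations + other.populations
        return GenotypeMatrix(
            self.samples + other.samples,
            self.variants,
            np.vstack([self.dosages, other.dosages]),
            pops,
        )


@dataclass(frozen=True)
class CatalogEntry:
    """One GWAS-catalog-style association row."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    risk_allele: str
    p_value: float
    study_snp_count: int
    study_id: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.rsid}: p_value {self.p_value} outside (0, 1]")
        if self.study_snp_count < 0:
            raise ValueError(f"{self.rsid}: negative study_snp_count")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _prescan_vcf(path: str | Path) -> None:
    """Cheap structural check so malformed headers fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.rstrip("\n").split("\t")
                if fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed #CHROM header line"
                    )
                return
            raise ParseError(
                f"{path}: line {lineno}: expected VCF header, found data line"
            )
    raise ParseError(f"{path}: no #CHROM header line found")


def read_vcf(
    path: str | Path,
    populations: Mapping[str, str] | None = None,
    multiallelic: str = "skip",
) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of the alternate allele; ``./.`` becomes missing.
    Multi-allelic records are skipped with a logged warning by default, or
    rejected when ``multiallelic="error"``.
    """
    from cyvcf2 import VCF

    _prescan_vcf(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - htslib failure paths
        raise ParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise ParseError(
                    f"{path}: multi-allelic record {rec.ID or rec.POS} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt-allele count, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING
        rows.append(gt)
        variants.append(
            VariantRecord(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref_allele=str(rec.REF),
                alt_allele=str(rec.ALT[0]),
            )
        )
    if n_skipped:
        log.warning("%s: skipped %d multi-allelic record(s)", path, n_skipped)
    dosages = (
        np.column_stack(rows) if rows else np.zeros((len(samples), 0), dtype=np.int16)
    )
    pops = [populations[s] for s in samples] if populations is not None else None
    return GenotypeMatrix(samples, variants, dosages, pops)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT fields only.

    Dosages are emitted relative to the alt allele; a matrix whose counted
    allele is ref at some variant is flipped on output so that the file's
    alt-dosage convention round-trips.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in gm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            d = gm.dosages[:, j]
            if v.counted_allele != v.alt_allele:
                d = np.where(d == MISSING, MISSING, 2 - d)
            gts = "\t".join(_GT_STRINGS[int(x)] for x in d)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    counted_alleles: Sequence[str] | None = None,
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read PLINK-text ``.ped``/``.map`` files.

    The counted allele at each variant is the first non-missing allele
    observed in the ``.ped`` file unless ``counted_alleles`` overrides it.
    An allele pair ``0 0`` is a missing call.
    """
    variants_meta: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{map_path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, rsid, _cm, pos = fields
            variants_meta.append((rsid, chrom, int(pos)))
    m = len(variants_meta)

    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"for {m} variants, got {len(fields)}"
                )
            samples.append(fields[1])
            pairs = [
                (fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(m)
            ]
            allele_rows.append(pairs)

    if counted_alleles is not None and len(counted_alleles) != m:
        raise ValueError("counted_alleles length inconsistent with .map")

    variants: list[VariantRecord] = []
    dosages = np.full((len(samples), m), MISSING, dtype=np.int16)
    for j, (rsid, chrom, pos) in enumerate(variants_meta):
        observed: list[str] = []
        for pairs in allele_rows:
            for a in pairs[j]:
                if a != "0" and a not in observed:
                    observed.append(a)
        if len(observed) > 2:
            raise ParseError(f"{ped_path}: variant {rsid} has >2 alleles")
        if not observed:
            observed = ["A", "G"]  # fully missing column; placeholder identity
        counted = counted_alleles[j] if counted_alleles is not None else observed[0]
        other = next((a for a in observed if a != counted), None)
        if other is None:
            other = "A" if counted != "A" else "G"  # monomorphic column
        if counted not in observed and counted_alleles is not None:
            observed.append(counted)
        for i, pairs in enumerate(allele_rows):
            a1, a2 = pairs[j]
            if a1 == "0" or a2 == "0":
                continue
            for a in (a1, a2):
                if a not in (counted, other):
                    raise ParseError(
                        f"{ped_path}: sample {samples[i]} variant {rsid}: "
                        f"unexpected allele {a!r}"
                    )
            dosages[i, j] = (a1 == counted) + (a2 == counted)
        variants.append(
            VariantRecord(
                id=rsid,
                chrom=chrom,
                pos=pos,
                ref_allele=other,
                alt_allele=counted,
                counted_allele=counted,
            )
        )
    pops = [populations[s] for s in samples] if populations is not None else None
    return GenotypeMatrix(samples, variants, dosages, pops)


def write_plink_text(
    gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write ``.ped``/``.map``; dosage counts the matrix's counted allele."""
    with open(map_path, "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, v in enumerate(gm.variants):
                d = int(gm.dosages[i, j])
                c, o = v.counted_allele, v.other_allele
                pair = {0: (o, o), 1: (c, o), 2: (c, c), MISSING: ("0", "0")}[d]
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Catalog TSV
# ---------------------------------------------------------------------------


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read a catalog TSV into typed entries.

    Rows with unparseable p-values or absent risk alleles are dropped with
    a logged warning; missing required columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")
    entries: list[CatalogEntry] = []
    n_dropped = 0
    for _, row in df.iterrows():
        risk_allele = row["risk_allele"]
        if not isinstance(risk_allele, str) or not risk_allele.strip():
            n_dropped += 1
            continue
        try:
            p = float(row["p_value"])
            entry = CatalogEntry(
                rsid=str(row["rsid"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                trait=str(row["trait"]),
                risk_allele=risk_allele.strip(),
                p_value=p,
                study_snp_count=int(float(row["study_snp_count"])),
                study_id=str(row["study_id"]),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        entries.append(entry)
    if n_dropped:
        log.warning("%s: dropped %d unparseable catalog row(s)", path, n_dropped)
    return entries


def write_catalog(entries: Iterable[CatalogEntry], path: str | Path) -> None:
    df = pd.DataFrame([vars(e) for e in entries], columns=CATALOG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Risk-allele alignment
# ---------------------------------------------------------------------------


def align_risk_alleles(gm: GenotypeMatrix, risk_set) -> GenotypeMatrix:
    """Restrict ``gm`` to a risk-SNP set with the risk allele counted.

    For each risk SNP present in ``gm`` (matched by rsID): if the risk allele
    equals the counted allele the column is kept as is; if it equals the other
    allele the dosage is flipped ``d -> 2 - d`` (missing stays missing); if it
    matches neither allele the SNP is dropped with a warning.  Output column
    order follows the risk set.

    Raises
    ------
    EmptyIntersectionError
        If no risk SNP could be matched.
    """
    index = {v.id: j for j, v in enumerate(gm.variants)}
    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    n_mismatched = 0
    for entry in risk_set.entries:
        j = index.get(entry.rsid)
        if j is None:
            continue
        v = gm.variants[j]
        d = gm.dosages[:, j]
        if entry.risk_allele == v.counted_allele:
            pass
        elif entry.risk_allele == v.other_allele:
            d = np.where(d == MISSING, MISSING, 2 - d).astype(np.int16)
        else:
            n_mismatched += 1
            log.warning(
                "risk allele %r at %s matches neither %r nor %r; SNP dropped",
                entry.risk_allele, entry.rsid, v.ref_allele, v.alt_allele,
            )
            continue
        cols.append(d)
        variants.append(replace(v, counted_allele=entry.risk_allele))
    if not cols:
        raise EmptyIntersectionError(
            "no risk SNPs could be matched against the genotype matrix"
        )
    if n_mismatched:
        log.warning("dropped %d SNP(s) with unmatched risk alleles", n_mismatched)
    return GenotypeMatrix(
        gm.samples, variants, np.column_stack(cols), gm.populations
    )
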