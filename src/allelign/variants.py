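"""Single-nucleotide variants, genotypes and variant catalogs.

A :class:`VariantCatalog` carries the variant information available for a
run at one of three levels:

``complete``
    every sample genotype is known (e.g. from genomic sequencing);
``partial``
    a subset of genotypes, typically imputed, each with an imputation
    quality score (Rsq) used as a strict inclusion filter;
``none``
    no sample genotypes at all — only population variants with allele
    frequencies, of which the common ones (minor allele frequency > 0.05)
    stand in for the unknown genotype.

Coordinates are 1-based in VCF files and 0-based half-open in memory;
conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

import pysam

log = logging.getLogger(__name__)

BASES = frozenset("ACGT")

__all__ = [
    "Variant",
    "Zygosity",
    "GenotypeCall",
    "VariantCatalog",
    "load_variants",
    "write_variants",
    "filter_by_rsq",
    "derive_common_variants",
]


class VariantError(ValueError):
    """Raised for malformed or inconsistent variant input."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV.

    ``pos`` is 0-based. ``af`` is the population frequency of the ALT
    allele (VCF INFO/AF); the minor allele frequency is derived from it.
    ``rsq`` is the imputation quality in [0, 1] when the variant comes
    from an imputed (partial) catalog.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    af: Optional[float] = None
    rsq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise VariantError(
                f"{self.contig}:{self.position}: alleles must be single bases "
                f"A/C/G/T, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise VariantError(f"{self.contig}:{self.position}: ref == alt ({self.ref})")
        if self.pos < 0:
            raise VariantError(f"negative position {self.pos}")
        for name, value in (("af", self.af), ("rsq", self.rsq)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise VariantError(f"{self.contig}:{self.position}: {name}={value} outside [0,1]")

    @property
    def position(self) -> int:
        """1-based position as printed in files."""
        return self.pos + 1

    @property
    def maf(self) -> Optional[float]:
        """Minor allele frequency, min(af, 1 - af)."""
        if self.af is None:
            return None
        return min(self.af, 1.0 - self.af)

    @property
    def major_allele(self) -> str:
        """Population major allele; exact 0.5/0.5 ties keep the reference base."""
        if self.af is None:
            raise VariantError(f"{self.contig}:{self.position}: no allele frequency")
        return self.alt if self.af > 0.5 else self.ref

    @property
    def minor_allele(self) -> str:
        return self.ref if self.major_allele == self.alt else self.alt


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HOM_ALT = "hom_alt"
    HET = "het"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenotypeCall:
    variant: Variant
    zygosity: Zygosity


@dataclass
class VariantCatalog:
    """Collection of genotype calls keyed by (contig, 0-based position)."""

    level: str
    records: dict[tuple[str, int], GenotypeCall] = field(default_factory=dict)
    n_skipped: int = 0

    LEVELS = ("complete", "partial", "none")

    def __post_init__(self) -> None:
        if self.level not in self.LEVELS:
            raise VariantError(f"unknown information level {self.level!r}")

    def add(self, call: GenotypeCall) -> None:
        key = (call.variant.contig, call.variant.pos)
        if key in self.records:
            raise VariantError(
                f"duplicate record at {call.variant.contig}:{call.variant.position}"
            )
        self.records[key] = call

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenotypeCall]:
        return iter(self.sorted_calls())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.records

    def get(self, contig: str, pos: int) -> Optional[GenotypeCall]:
        return self.records.get((contig, pos))

    def sorted_calls(self) -> list[GenotypeCall]:
        return [self.records[k] for k in sorted(self.records)]

    def het_sites(self) -> set[tuple[str, int]]:
        return {
            k for k, c in self.records.items() if c.zygosity is Zygosity.HET
        }


def _zygosity_from_gt(gt: tuple) -> Zygosity:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Zygosity.UNKNOWN
    if all(a == 0 for a in alleles):
        return Zygosity.HOM_REF
    if all(a == 1 for a in alleles):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def load_variants(path: str | Path, level: str) -> VariantCatalog:
    """Read a VCF into a catalog at the given information level.

    Biallelic SNVs only: multiallelic records and indels are skipped and
    counted on ``catalog.n_skipped``. ``level="none"`` requires INFO/AF on
    every record and strips genotypes to unknown; complete/partial read
    FORMAT/GT of the single sample. INFO/RSQ (or R2) is read when present.
    """
    catalog = VariantCatalog(level=level)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                catalog.n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                catalog.n_skipped += 1
                continue
            def _info(*keys):
                # rec.info.get raises on keys absent from the header
                for key in keys:
                    if key in rec.info:
                        value = rec.info[key]
                        return value[0] if isinstance(value, tuple) else value
                return None

            af = _info("AF")
            rsq = _info("RSQ", "R2")
            if level == "none":
                if af is None:
                    raise VariantError(
                        f"{rec.chrom}:{rec.pos}: level 'none' requires INFO/AF"
                    )
                zyg = Zygosity.UNKNOWN
            else:
                if not rec.samples:
                    raise VariantError(
                        f"{rec.chrom}:{rec.pos}: level {level!r} requires a GT sample column"
                    )
                sample = rec.samples[0]
                zyg = _zygosity_from_gt(sample.get("GT") or ())
            variant = Variant(
                contig=rec.chrom,
                pos=rec.pos - 1,
                ref=ref,
                alt=alt,
                af=None if af is None else float(af),
                rsq=None if rsq is None else float(rsq),
            )
            catalog.add(GenotypeCall(variant, zyg))
    if catalog.n_skipped:
        log.info("skipped %d non-biallelic-SNV records in %s", catalog.n_skipped, path)
    return catalog


_GT_STRING = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.HET: "0/1",
    Zygosity.UNKNOWN: "./.",
}


def write_variants(catalog: VariantCatalog, path: str | Path, sample: str = "sample") -> None:
    """Write the catalog as a minimal single-sample VCF (AF/RSQ in INFO)."""
    calls = catalog.sorted_calls()
    contigs = sorted({c.variant.contig for c in calls})
    with_gt = catalog.level != "none"
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">')
    lines.append('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Imputation quality">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if with_gt:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        header += f"\tFORMAT\t{sample}"
    lines.append(header)
    for call in calls:
        v = call.variant
        info = []
        if v.af is not None:
            info.append(f"AF={v.af:.6g}")
        if v.rsq is not None:
            info.append(f"RSQ={v.rsq:.6g}")
        row = [v.contig, str(v.position), ".", v.ref, v.alt, ".", ".", ";".join(info) or "."]
        if with_gt:
            row += ["GT", _GT_STRING[call.zygosity]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def filter_by_rsq(catalog: VariantCatalog, threshold: float = 0.3) -> VariantCatalog:
    """Keep imputed records with Rsq strictly above ``threshold``.

    Records lacking an Rsq are dropped. Only meaningful for partial
    (imputed) catalogs.
    """
    if catalog.level != "partial":
        raise VariantError(f"Rsq filtering applies to partial catalogs, not {catalog.level!r}")
    if not 0.0 <= threshold <= 1.0:
        raise VariantError(f"Rsq threshold {threshold} outside [0,1]")
    out = VariantCatalog(level="partial")
    for call in catalog:
        rsq = call.variant.rsq
        if rsq is not None and rsq > threshold:
            out.add(call)
    return out


def derive_common_variants(
    population_catalog: VariantCatalog, maf_threshold: float = 0.05
) -> VariantCatalog:
    """Select common variants (MAF strictly above ``maf_threshold``).

    Returns a level-``none`` catalog with genotypes stripped to unknown —
    the variant set used when no sample genotypes are available.
    """
    out = VariantCatalog(level="none")
    for call in population_catalog:
        v = call.variant
        if v.maf is None:
            raise VariantError(f"{v.contig}:{v.position}: missing allele frequency")
        if v.maf > maf_threshold:
            out.add(GenotypeCall(v, Zygosity.UNKNOWN))
    return out
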