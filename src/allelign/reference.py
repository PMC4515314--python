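"""Custom reference genomes with an alternate-allele sidecar.

A custom reference is an ordinary FASTA genome in which known variant
positions carry one chosen allele, paired with a *sidecar* table mapping
each heterozygous/common site to the allele not present in the genome.
An allele-aware aligner treats either allele at a sidecar site as a
match, which removes the mismatch penalty that otherwise biases mapping
toward the allele embedded in the reference.

Construction proceeds in stages:

1. :func:`build_population_reference` — substitute the population major
   allele at every common variant (sidecar = minor allele);
2. :func:`customize_for_sample` — overwrite with sample genotypes where
   known (hom sites fix the genome base and leave the sidecar; het sites
   keep one allele in the genome and the other in the sidecar);
3. :func:`build_complement_reference` — swap genome/sidecar alleles at
   every site, used to verify that both alleles are handled symmetrically;
4. :func:`update_reference_with_predicted` — fold newly predicted
   heterozygous sites in before a second alignment round.

All operations are SNV substitutions: contig lengths never change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import BASES, VariantCatalog, VariantError, Zygosity

log = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "CustomReference",
    "build_population_reference",
    "customize_for_sample",
    "build_complement_reference",
    "update_reference_with_predicted",
    "read_fasta",
    "write_fasta",
    "read_sidecar",
    "write_sidecar",
]


@dataclass
class GenomeSequence:
    """Ordered mapping contig name -> uppercase sequence over A/C/G/T/N."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, seq in self.contigs.items():
            s = seq.upper()
            if not s:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGTN bases {sorted(bad)}")
            clean[name] = s
        self.contigs = clean

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSequence) and self.contigs == other.contigs

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class CustomReference:
    """Genome plus sidecar of alternate alleles at variant sites.

    ``alternate`` maps (contig, 0-based position) to the single base that
    is *not* in the genome at that position.
    """

    genome: GenomeSequence
    alternate: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (contig, pos), base in self.alternate.items():
            if base not in BASES:
                raise ValueError(f"sidecar base {base!r} at {contig}:{pos + 1} is not A/C/G/T")
            if self.genome[contig][pos] == base:
                raise ValueError(
                    f"sidecar allele at {contig}:{pos + 1} equals the genome base {base}"
                )

    def base_at(self, contig: str, pos: int) -> str:
        return self.genome[contig][pos]

    def alleles_at(self, contig: str, pos: int) -> tuple[str, str]:
        """(genome allele, sidecar allele) at a sidecar site."""
        return self.genome[contig][pos], self.alternate[(contig, pos)]

    def copy(self) -> "CustomReference":
        return CustomReference(
            GenomeSequence(dict(self.genome.contigs)), dict(self.alternate)
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CustomReference)
            and self.genome == other.genome
            and self.alternate == other.alternate
        )


def _substitute(contigs: dict[str, list[str]], contig: str, pos: int, base: str) -> None:
    contigs[contig][pos] = base


def _mutable(genome: GenomeSequence) -> dict[str, list[str]]:
    return {name: list(seq) for name, seq in genome.contigs.items()}


def _freeze(contigs: dict[str, list[str]]) -> GenomeSequence:
    return GenomeSequence({name: "".join(chars) for name, chars in contigs.items()})


def build_population_reference(
    genome: GenomeSequence, common: VariantCatalog
) -> CustomReference:
    """Replace the genome base with the population major allele at every
    common variant; the sidecar records the minor allele.

    The catalog must be level ``none`` with allele frequencies present.
    A variant whose REF allele disagrees with the genome base is an
    input inconsistency and raises (an ``N`` genome base is overridden).
    """
    if common.level != "none":
        raise VariantError("population reference expects a level 'none' catalog")
    contigs = _mutable(genome)
    sidecar: dict[tuple[str, int], str] = {}
    for call in common:
        v = call.variant
        if v.contig not in genome:
            raise VariantError(f"variant contig {v.contig!r} absent from genome")
        current = genome[v.contig][v.pos]
        if current != v.ref and current != "N":
            raise VariantError(
                f"{v.contig}:{v.position}: catalog ref {v.ref} disagrees with genome base {current}"
            )
        major, minor = v.major_allele, v.minor_allele
        _substitute(contigs, v.contig, v.pos, major)
        sidecar[(v.contig, v.pos)] = minor
    return CustomReference(_freeze(contigs), sidecar)


def customize_for_sample(
    ref: CustomReference, genotypes: VariantCatalog
) -> CustomReference:
    """Overwrite the reference with sample genotypes where known.

    Homozygous sites end up with the sample allele in the genome and no
    sidecar entry; heterozygous sites keep the pre-existing genome base
    when it is one of the two sample alleles (the other goes to the
    sidecar), so runs at different information levels stay comparable.
    Sites absent from the genotype catalog are left as they were.
    """
    if genotypes.level not in ("complete", "partial"):
        raise VariantError("sample customization expects a complete or partial catalog")
    contigs = _mutable(ref.genome)
    sidecar = dict(ref.alternate)
    for call in genotypes:
        v = call.variant
        if v.contig not in ref.genome:
            raise VariantError(f"variant contig {v.contig!r} absent from genome")
        key = (v.contig, v.pos)
        if call.zygosity is Zygosity.UNKNOWN:
            continue
        if call.zygosity is Zygosity.HOM_REF:
            _substitute(contigs, v.contig, v.pos, v.ref)
            sidecar.pop(key, None)
        elif call.zygosity is Zygosity.HOM_ALT:
            _substitute(contigs, v.contig, v.pos, v.alt)
            sidecar.pop(key, None)
        else:  # het
            current = contigs[v.contig][v.pos]
            if current == v.ref:
                other = v.alt
            elif current == v.alt:
                other = v.ref
            else:
                _substitute(contigs, v.contig, v.pos, v.ref)
                other = v.alt
            sidecar[key] = other
    return CustomReference(_freeze(contigs), sidecar)


def build_complement_reference(ref: CustomReference) -> CustomReference:
    """Exchange genome and sidecar alleles at every sidecar site.

    An involution: applying it twice returns the input bit-exactly. Used
    to verify allele-aware alignment treats the two alleles symmetrically.
    """
    contigs = _mutable(ref.genome)
    sidecar: dict[tuple[str, int], str] = {}
    for (contig, pos), alt_base in ref.alternate.items():
        sidecar[(contig, pos)] = contigs[contig][pos]
        _substitute(contigs, contig, pos, alt_base)
    return CustomReference(_freeze(contigs), sidecar)


def update_reference_with_predicted(
    ref: CustomReference,
    predicted: Iterable[tuple[str, int, str, str]],
) -> CustomReference:
    """Fold predicted heterozygous sites (contig, pos, allele1, allele2)
    into the reference before a second alignment round.

    If the genome already carries one predicted allele it is kept and the
    other goes to the sidecar; otherwise allele1 replaces the genome base
    and allele2 goes to the sidecar. A site already in the sidecar with
    different alleles keeps its existing entry (with a warning).
    """
    contigs = _mutable(ref.genome)
    sidecar = dict(ref.alternate)
    for contig, pos, a1, a2 in sorted(predicted):
        key = (contig, pos)
        if key in sidecar:
            existing = {contigs[contig][pos], sidecar[key]}
            if existing != {a1, a2}:
                warnings.warn(
                    f"predicted alleles {a1}/{a2} at {contig}:{pos + 1} conflict with "
                    f"existing sidecar entry; keeping the existing alleles",
                    stacklevel=2,
                )
            continue
        current = contigs[contig][pos]
        if current == a1:
            sidecar[key] = a2
        elif current == a2:
            sidecar[key] = a1
        else:
            _substitute(contigs, contig, pos, a1)
            sidecar[key] = a2
    return CustomReference(_freeze(contigs), sidecar)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> GenomeSequence:
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    """Deterministic FASTA writer: input contig order, 60-column wrap."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_sidecar(path: str | Path) -> dict[tuple[str, int], str]:
    """Read the alternate-allele table (contig, 1-based pos, genome allele,
    alternate allele). The genome-allele column is informational on read."""
    sidecar: dict[tuple[str, int], str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{i}: expected 4 tab-separated fields")
        contig, pos1, _genome_allele, alt = fields
        sidecar[(contig, int(pos1) - 1)] = alt
    return sidecar


def write_sidecar(ref: CustomReference, path: str | Path) -> None:
    lines = ["#contig\tposition\tgenome_allele\talternate_allele"]
    for (contig, pos) in sorted(
        ref.alternate, key=lambda k: (list(ref.genome.contigs).index(k[0]), k[1])
    ):
        lines.append(
            f"{contig}\t{pos + 1}\t{ref.genome[contig][pos]}\t{ref.alternate[(contig, pos)]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
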