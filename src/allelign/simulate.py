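"""Synthetic diploid fixtures for the pipeline.

The generator emulates a diploid sample sequenced at a set of regulatory
sites: a random genome (optionally with duplicated segments that create
multi-mapping), SNVs with population allele frequencies, sample
genotypes with two consistent haplotypes, and reads drawn around each
heterozygous site with a controllable per-site allelic ratio, substitution
errors, and PCR duplicates. Variant catalogs are emitted at the three
information levels (complete genotypes, an imputed-style partial subset
with Rsq scores, and a genotype-free common-variant set), together with
a per-site truth table of allelic ratios.

Everything is a pure function of the configuration, whose ``seed``
drives a single NumPy generator with per-stage substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .counting import AlleleCount
from .reads import Read, revcomp
from .reference import GenomeSequence
from .variants import (
    GenotypeCall,
    Variant,
    VariantCatalog,
    Zygosity,
    derive_common_variants,
)

__all__ = [
    "SimulationConfig",
    "TruthSite",
    "SimulatedTruth",
    "simulate_truth",
    "simulate_reads",
    "simulate_overdispersed_counts",
    "write_truth_table",
    "read_truth_table",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic run.

    Defaults describe the standard desk-scale fixture: a 20 kb contig
    with 200 heterozygous SNVs (10 per kb), mean depth 60 at each site,
    50 bp reads with a 1% substitution error rate (errored bases emitted
    at Q20, under the Q>30 counting gate), 10% PCR duplicates, 30% of
    het sites truly imbalanced at ratio 0.8, and a partial catalog
    covering 80% of sites with imputation quality above the 0.3 filter.
    """

    genome_length: int = 20_000
    n_contigs: int = 1
    repeat_spec: tuple[int, int] = (0, 0)  # (n_repeats, repeat_length)
    variant_density: float = 10.0  # variants per kb
    het_fraction: float = 1.0
    maf_distribution: tuple = ("uniform", 0.05, 0.95)  # alt-allele frequency
    depth: float = 60.0
    read_length: int = 50
    error_rate: float = 0.01
    duplicate_rate: float = 0.10
    imbalanced_fraction: float = 0.30
    imbalance_ratio: float = 0.80
    partial_coverage: float = 0.80
    rsq_distribution: tuple = ("uniform", 0.4, 1.0)
    background_depth: float = 0.0
    base_quality: int = 40
    error_quality: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "het_fraction", "error_rate", "duplicate_rate", "imbalanced_fraction",
            "imbalance_ratio", "partial_coverage",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0,1]")


@dataclass(frozen=True)
class TruthSite:
    """One heterozygous site's ground truth.

    ``ratio_hap1`` is the probability that a read covering the site
    originates from haplotype 1 (the one carrying ``hap1_allele``).
    """

    contig: str
    pos: int
    hap1_allele: str
    hap2_allele: str
    ratio_hap1: float
    imbalanced: bool


@dataclass
class SimulatedTruth:
    genome: GenomeSequence
    complete: VariantCatalog
    partial: VariantCatalog
    common: VariantCatalog
    truth: list[TruthSite]
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def truth_by_site(self) -> dict[tuple[str, int], TruthSite]:
        return {(t.contig, t.pos): t for t in self.truth}

    def imbalanced_sites(self) -> set[tuple[str, int]]:
        return {(t.contig, t.pos) for t in self.truth if t.imbalanced}


def _draw(rng: np.random.Generator, spec: tuple) -> float:
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "beta":
        return float(rng.beta(spec[1], spec[2]))
    if kind == "fixed":
        return float(spec[1])
    raise ValueError(f"unknown distribution spec {spec!r}")


def simulate_truth(config: SimulationConfig) -> SimulatedTruth:
    """Generate genome, variant catalogs at all three levels, and the
    imbalance truth table."""
    rng = np.random.default_rng(config.seed)
    margin = config.read_length

    contig_len = config.genome_length // config.n_contigs
    contigs: dict[str, str] = {}
    repeat_intervals: list[tuple[str, int, int]] = []
    for i in range(config.n_contigs):
        name = f"contig{i + 1}"
        seq = rng.choice(_BASES, size=contig_len)
        n_rep, rep_len = config.repeat_spec
        blocked: list[tuple[int, int]] = []
        for _ in range(n_rep):
            if rep_len <= 0 or 4 * rep_len > contig_len:
                raise ValueError("repeat length incompatible with contig length")
            for _attempt in range(1000):
                src = int(rng.integers(0, contig_len - rep_len))
                dst = int(rng.integers(0, contig_len - rep_len))
                spans = [(src, src + rep_len), (dst, dst + rep_len)]
                if spans[0][1] > spans[1][0] and spans[1][1] > spans[0][0]:
                    continue
                if any(a < e and b > s for a, b in spans for s, e in blocked):
                    continue
                break
            else:
                raise ValueError("could not place repeats")
            seq[dst : dst + rep_len] = seq[src : src + rep_len]
            blocked += spans
            repeat_intervals += [(name, s, e) for s, e in spans]
        contigs[name] = "".join(seq)

    n_variants = round(config.variant_density * config.genome_length / 1000)
    if n_variants < 1:
        raise ValueError("variant density and genome length yield no variants")
    per_contig = [n_variants // config.n_contigs] * config.n_contigs
    per_contig[0] += n_variants - sum(per_contig)

    complete = VariantCatalog("complete")
    partial = VariantCatalog("partial")
    population = VariantCatalog("none")
    truth: list[TruthSite] = []
    for (name, seq), n_here in zip(contigs.items(), per_contig):
        allowed = np.ones(len(seq), dtype=bool)
        allowed[:margin] = allowed[-margin:] = False
        for c, s, e in repeat_intervals:
            if c == name:
                allowed[max(0, s - margin) : e + margin] = False
        candidates = np.flatnonzero(allowed)
        if len(candidates) < n_here:
            raise ValueError("not enough variant-eligible positions")
        positions = np.sort(rng.choice(candidates, size=n_here, replace=False))
        for pos in positions.tolist():
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            af = _draw(rng, config.maf_distribution)
            is_het = rng.random() < config.het_fraction
            if is_het:
                zyg = Zygosity.HET
            else:
                zyg = Zygosity.HOM_ALT if rng.random() < 0.5 else Zygosity.HOM_REF
            variant = Variant(name, pos, ref, alt, af=af)
            complete.add(GenotypeCall(variant, zyg))
            population.add(GenotypeCall(variant, Zygosity.UNKNOWN))
            if rng.random() < config.partial_coverage:
                rsq = _draw(rng, config.rsq_distribution)
                partial.add(
                    GenotypeCall(replace(variant, rsq=rsq), zyg)
                )
            if is_het:
                hap1 = ref if rng.random() < 0.5 else alt
                hap2 = alt if hap1 == ref else ref
                if rng.random() < config.imbalanced_fraction:
                    ratio = (
                        config.imbalance_ratio
                        if rng.random() < 0.5
                        else 1.0 - config.imbalance_ratio
                    )
                    imb = True
                else:
                    ratio, imb = 0.5, False
                truth.append(TruthSite(name, pos, hap1, hap2, ratio, imb))

    common = derive_common_variants(population, maf_threshold=0.05)
    return SimulatedTruth(
        genome=GenomeSequence(contigs),
        complete=complete,
        partial=partial,
        common=common,
        truth=truth,
        repeat_intervals=repeat_intervals,
    )


def _haplotypes(
    genome: GenomeSequence, complete: VariantCatalog, truth: list[TruthSite]
) -> tuple[dict[str, str], dict[str, str]]:
    hap1 = {name: list(seq) for name, seq in genome.contigs.items()}
    hap2 = {name: list(seq) for name, seq in genome.contigs.items()}
    for call in complete:
        v = call.variant
        if call.zygosity is Zygosity.HOM_ALT:
            hap1[v.contig][v.pos] = hap2[v.contig][v.pos] = v.alt
    for t in truth:
        hap1[t.contig][t.pos] = t.hap1_allele
        hap2[t.contig][t.pos] = t.hap2_allele
    return (
        {n: "".join(c) for n, c in hap1.items()},
        {n: "".join(c) for n, c in hap2.items()},
    )


def simulate_reads(
    genome: GenomeSequence,
    complete: VariantCatalog,
    truth: list[TruthSite],
    config: SimulationConfig,
) -> list[Read]:
    """Draw reads from the two haplotypes.

    Each heterozygous site receives Poisson(depth) reads whose start is
    uniform among positions covering the site and whose haplotype of
    origin is Bernoulli(ratio_hap1). Optional background reads cover the
    genome uniformly. Substitution errors are applied per base at
    ``error_rate`` (errored bases get ``error_quality``); a
    ``duplicate_rate`` fraction of reads is then re-emitted as exact
    copies to exercise duplicate removal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    hap1, hap2 = _haplotypes(genome, complete, truth)
    L = config.read_length
    reads: list[Read] = []

    def emit(contig: str, start: int, from_hap1: bool, read_id: str) -> None:
        source = hap1 if from_hap1 else hap2
        seq = list(source[contig][start : start + L])
        quals = [config.base_quality] * L
        err = np.flatnonzero(rng.random(L) < config.error_rate)
        for i in err.tolist():
            seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            quals[i] = config.error_quality
        s = "".join(seq)
        if rng.random() < 0.5:
            s = revcomp(s)
            quals = quals[::-1]
        reads.append(Read(read_id, s, tuple(quals)))

    for i, t in enumerate(truth):
        contig_len = len(genome[t.contig])
        n = int(rng.poisson(config.depth))
        lo = max(0, t.pos - L + 1)
        hi = min(t.pos, contig_len - L)
        for j in range(n):
            start = int(rng.integers(lo, hi + 1))
            emit(t.contig, start, rng.random() < t.ratio_hap1, f"site{i}_read{j}")

    if config.background_depth > 0:
        total = genome.total_length()
        n_bg = round(config.background_depth * total / L)
        names = list(genome.contigs)
        lengths = np.array([len(genome[n]) for n in names], dtype=float)
        for j in range(n_bg):
            contig = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
            start = int(rng.integers(0, len(genome[contig]) - L + 1))
            emit(contig, start, rng.random() < 0.5, f"bg_read{j}")

    duplicated: list[Read] = []
    for r in reads:
        duplicated.append(r)
        if rng.random() < config.duplicate_rate:
            duplicated.append(Read(r.id + "_dup", r.seq, r.quals))
    return duplicated


def simulate_overdispersed_counts(
    n_sites: int, depth: int, alpha: float, seed: int
) -> list[AlleleCount]:
    """Beta-binomial allele-count tables for the statistics: per site,
    p ~ Beta(alpha, alpha) (p = 0.5 exactly when alpha is infinite) and
    n1 ~ Binomial(depth, p)."""
    if not (alpha > 0):
        raise ValueError("alpha must be positive (math.inf for pure binomial)")
    rng = np.random.default_rng(seed)
    ps = (
        np.full(n_sites, 0.5)
        if math.isinf(alpha)
        else rng.beta(alpha, alpha, size=n_sites)
    )
    n1s = rng.binomial(depth, ps)
    return [
        AlleleCount(
            site=("sim", i),
            allele1="A",
            allele2="G",
            n1=int(n1),
            n2=depth - int(n1),
            n_other=0,
            site_class="known_het",
        )
        for i, n1 in enumerate(n1s)
    ]


def write_truth_table(truth: list[TruthSite], path: str | Path) -> None:
    lines = ["#contig\tposition\thap1_allele\thap2_allele\tratio_hap1\timbalanced"]
    for t in truth:
        lines.append(
            f"{t.contig}\t{t.pos + 1}\t{t.hap1_allele}\t{t.hap2_allele}"
            f"\t{t.ratio_hap1:.6g}\t{int(t.imbalanced)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_table(path: str | Path) -> list[TruthSite]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        contig, pos1, a1, a2, ratio, imb = line.split("\t")
        out.append(
            TruthSite(contig, int(pos1) - 1, a1, a2, float(ratio), bool(int(imb)))
        )
    return out
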