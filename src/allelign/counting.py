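"""Per-site allele counts with quality and mappability filtering.

Counts at a variant site split quality-passing read observations into
allele1 (the genome allele), allele2 (the sidecar allele) and any other
base. Only bases with Phred quality strictly greater than 30 (default)
contribute. Before counting, the allele-swap mappability filter drops
reads whose placement is not robust to which allele they carry: the
variant base in the read is swapped to the other allele and re-aligned,
and the read is kept only if every swapped version still maps uniquely
to the same locus. Without this, loci where one allele creates a repeat
elsewhere in the genome produce artificial imbalance.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from .align import AlleleAwareAligner
from .reads import AlignedRead
from .reference import CustomReference

log = logging.getLogger(__name__)

__all__ = [
    "Site",
    "AlleleCount",
    "pileup_alleles",
    "mappability_filter",
    "write_counts",
    "read_counts",
]

SITE_CLASSES = ("known_het", "common_variant", "predicted_het")


class Site(NamedTuple):
    """A variant site to count over: allele1 is the genome allele."""

    contig: str
    pos: int  # 0-based
    allele1: str
    allele2: str
    site_class: str


@dataclass(frozen=True)
class AlleleCount:
    site: tuple[str, int]
    allele1: str
    allele2: str
    n1: int
    n2: int
    n_other: int
    site_class: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError(f"site {self.site}: identical alleles {self.allele1}")
        if min(self.n1, self.n2, self.n_other) < 0:
            raise ValueError(f"site {self.site}: negative count")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")

    @property
    def total(self) -> int:
        """Reads informative for the two alleles (third alleles excluded)."""
        return self.n1 + self.n2


def _sites_by_contig(sites: Iterable[Site]) -> dict[str, list[Site]]:
    by_contig: dict[str, list[Site]] = defaultdict(list)
    for s in sites:
        by_contig[s.contig].append(s)
    for lst in by_contig.values():
        lst.sort(key=lambda s: s.pos)
    return by_contig


def pileup_alleles(
    alignments: Iterable[AlignedRead],
    sites: Sequence[Site],
    min_base_quality: int = 30,
) -> list[AlleleCount]:
    """Count quality-passing allele observations at each site.

    A base contributes only when its quality is strictly greater than
    ``min_base_quality``. Expects alignments already de-duplicated and
    filtered for unique placement.
    """
    for s in sites:
        if s.allele1 == s.allele2:
            raise ValueError(f"site {s.contig}:{s.pos + 1} has identical alleles")
    by_contig = _sites_by_contig(sites)
    tallies: dict[tuple[str, int], list[int]] = {
        (s.contig, s.pos): [0, 0, 0] for s in sites
    }
    for aln in alignments:
        if aln.status != "unique":
            continue
        contig_sites = by_contig.get(aln.contig)
        if not contig_sites:
            continue
        positions = [s.pos for s in contig_sites]
        lo = bisect_left(positions, aln.start)
        hi = bisect_left(positions, aln.end)
        for s in contig_sites[lo:hi]:
            obs = aln.base_at(s.pos)
            if obs is None:
                continue
            base, qual = obs
            if qual <= min_base_quality:
                continue
            t = tallies[(s.contig, s.pos)]
            if base == s.allele1:
                t[0] += 1
            elif base == s.allele2:
                t[1] += 1
            else:
                t[2] += 1
    return [
        AlleleCount(
            site=(s.contig, s.pos),
            allele1=s.allele1,
            allele2=s.allele2,
            n1=tallies[(s.contig, s.pos)][0],
            n2=tallies[(s.contig, s.pos)][1],
            n_other=tallies[(s.contig, s.pos)][2],
            site_class=s.site_class,
        )
        for s in sites
    ]


def mappability_filter(
    alignments: Iterable[AlignedRead],
    sites: Sequence[Site],
    ref: CustomReference,
    max_mismatch: int = 1,
    aligner: Optional[AlleleAwareAligner] = None,
) -> list[AlignedRead]:
    """Keep reads that map uniquely to the same locus regardless of which
    allele they carry.

    For each variant site a read covers, the read's base at that site is
    swapped to the site's other allele and re-aligned allele-aware; the
    read survives only if every swapped version is again unique at the
    original (contig, start). Reads covering no variant site, or showing
    a third allele at a site, pass unconditionally for that site.
    """
    if aligner is None:
        aligner = AlleleAwareAligner(ref, allele_aware=True, max_mismatch=max_mismatch)
    by_contig = _sites_by_contig(sites)
    kept: list[AlignedRead] = []
    n_removed = 0
    for aln in alignments:
        if aln.status != "unique":
            raise ValueError("mappability filter expects uniquely mapped reads")
        contig_sites = by_contig.get(aln.contig, [])
        positions = [s.pos for s in contig_sites]
        lo = bisect_left(positions, aln.start)
        hi = bisect_left(positions, aln.end)
        ok = True
        for s in contig_sites[lo:hi]:
            obs = aln.base_at(s.pos)
            if obs is None:
                continue
            base, _ = obs
            if base == s.allele1:
                other = s.allele2
            elif base == s.allele2:
                other = s.allele1
            else:
                continue  # third allele: no defined swap
            if aln.pos_map is not None:
                idx = aln.pos_map[s.pos]
            else:
                idx = s.pos - aln.start
            swapped = aln.seq[:idx] + other + aln.seq[idx + 1 :]
            pls = aligner.placements(swapped)
            if not pls:
                ok = False
                break
            best = min(p.mismatches for p in pls)
            hits = [p for p in pls if p.mismatches == best]
            if len(hits) != 1 or (hits[0].contig, hits[0].pos) != (aln.contig, aln.start):
                ok = False
                break
        if ok:
            kept.append(aln)
        else:
            n_removed += 1
    if n_removed:
        log.info("mappability filter removed %d reads", n_removed)
    return kept


_COUNT_FIELDS = ["contig", "position", "allele1", "allele2", "n1", "n2", "n_other", "site_class"]


def write_counts(counts: Iterable[AlleleCount], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COUNT_FIELDS)
        for c in sorted(counts, key=lambda c: c.site):
            writer.writerow(
                [c.site[0], c.site[1] + 1, c.allele1, c.allele2, c.n1, c.n2, c.n_other, c.site_class]
            )


def read_counts(path: str | Path) -> list[AlleleCount]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                AlleleCount(
                    site=(row["contig"], int(row["position"]) - 1),
                    allele1=row["allele1"],
                    allele2=row["allele2"],
                    n1=int(row["n1"]),
                    n2=int(row["n2"]),
                    n_other=int(row["n_other"]),
                    site_class=row["site_class"],
                )
            )
    return out
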