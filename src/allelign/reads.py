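"""Short reads, read QC, alignment records and post-alignment filters.

QC mirrors common fastx-style preprocessing: trim each read to a fixed
length, then keep it only if a minimum fraction of bases meets a quality
floor. Post-alignment filters drop multi-mapping reads, reads in
blacklisted regions, and PCR duplicates (one representative per
(contig, 5' position, strand) key).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "Read",
    "AlignedRead",
    "BlacklistRegions",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "qc_reads",
    "filter_alignments",
    "remove_duplicates",
    "ingest_sam",
    "write_sam",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignedRead:
    """A read placed on the reference (or a mapping-failure record).

    For mapped records the stored sequence and qualities are in forward
    genome orientation (reverse-strand reads are stored reverse
    complemented), so ``base_at`` indexes directly into genome coordinates.
    ``pos_map`` is set only for externally aligned reads whose CIGAR
    contains indels or clips; it maps reference position -> query index.
    """

    read_id: str
    status: str  # unique | multimapped | unmapped
    contig: Optional[str] = None
    start: Optional[int] = None  # 0-based
    strand: Optional[str] = None
    mismatches: Optional[int] = None
    seq: str = ""
    quals: tuple[int, ...] = ()
    pos_map: Optional[dict[int, int]] = None

    @property
    def end(self) -> int:
        if self.pos_map:
            return max(self.pos_map) + 1
        return self.start + len(self.seq)

    @property
    def five_prime(self) -> int:
        """5' position of the original read on its strand (duplicate key)."""
        return self.start if self.strand == "+" else self.end - 1

    def base_at(self, pos: int) -> Optional[tuple[str, int]]:
        """(base, quality) observed at reference position ``pos``, or None
        if the read does not cover it (e.g. a deletion in the CIGAR)."""
        if self.pos_map is not None:
            idx = self.pos_map.get(pos)
            if idx is None:
                return None
        else:
            if self.start is None or not self.start <= pos < self.start + len(self.seq):
                return None
            idx = pos - self.start
        return self.seq[idx], self.quals[idx]

    def overlaps(self, pos: int) -> bool:
        return self.base_at(pos) is not None


@dataclass
class BlacklistRegions:
    """Half-open genomic intervals to exclude (e.g. signal-artifact regions)."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "BlacklistRegions":
        trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValueError(f"malformed interval {contig}:{start}-{end}")
            trees.setdefault(contig, IntervalTree()).addi(start, end)
        return cls(trees)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        tree = self.trees.get(contig)
        return bool(tree is not None and tree.overlap(start, end))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def read_bed(path: str | Path) -> BlacklistRegions:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return BlacklistRegions.from_intervals(intervals)


def read_fastq(path: str | Path) -> list[Read]:
    return [
        Read(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{''.join(chr(q + 33) for q in r.quals)}\n")


def qc_reads(
    reads: Iterable[Read],
    trim_to: Optional[int] = None,
    min_q: int = 20,
    min_fraction: float = 0.90,
) -> list[Read]:
    """Trim reads to ``trim_to`` bases, then keep a read iff at least
    ``min_fraction`` of its (trimmed) bases have quality >= ``min_q``."""
    if trim_to is not None and trim_to < 1:
        raise ValueError("trim_to must be >= 1")
    out = []
    for r in reads:
        if trim_to is not None and len(r) > trim_to:
            r = Read(r.id, r.seq[:trim_to], r.quals[:trim_to])
        n_good = sum(1 for q in r.quals if q >= min_q)
        if n_good >= min_fraction * len(r):
            out.append(r)
    return out


def filter_alignments(
    alignments: Iterable[AlignedRead],
    blacklist: Optional[BlacklistRegions] = None,
) -> list[AlignedRead]:
    """Keep uniquely mapped reads outside the blacklist."""
    out = []
    for a in alignments:
        if a.status != "unique":
            continue
        if blacklist is not None and blacklist.overlaps(a.contig, a.start, a.end):
            continue
        out.append(a)
    return out


def remove_duplicates(alignments: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Keep one read per (contig, 5' position, strand): the one with the
    highest base-quality sum, ties broken by smallest read id."""
    best: dict[tuple, AlignedRead] = {}
    for a in alignments:
        if a.status != "unique":
            raise ValueError("duplicate removal expects uniquely mapped reads")
        key = (a.contig, a.five_prime, a.strand)
        rank = (-sum(a.quals), a.read_id)
        incumbent = best.get(key)
        if incumbent is None or rank < (-sum(incumbent.quals), incumbent.read_id):
            best[key] = a
    return sorted(best.values(), key=lambda a: (a.contig, a.start, a.strand, a.read_id))


def ingest_sam(path: str | Path, ref=None) -> list[AlignedRead]:
    """Read externally produced SAM alignments.

    Secondary/supplementary records become ``multimapped``; the NM tag
    supplies the mismatch count. Reads whose CIGAR contains indels or
    clips get a reference->query position map so allele observations can
    skip deleted sites.
    """
    out: list[AlignedRead] = []
    n_gapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                out.append(AlignedRead(rec.query_name, "unmapped"))
                continue
            status = (
                "multimapped" if (rec.is_secondary or rec.is_supplementary) else "unique"
            )
            seq = (rec.query_sequence or "").upper()
            quals = tuple(rec.query_qualities) if rec.query_qualities is not None else (0,) * len(seq)
            pos_map = None
            cigar_ops = {op for op, _ in (rec.cigartuples or [])}
            if cigar_ops - {0, 7, 8}:  # anything beyond aligned matches
                n_gapped += 1
                pos_map = {
                    rpos: qpos
                    for qpos, rpos in rec.get_aligned_pairs(matches_only=True)
                }
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    status=status,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(nm),
                    seq=seq,
                    quals=quals,
                    pos_map=pos_map,
                )
            )
    if n_gapped:
        log.info("%d SAM records with indels/clips; deleted sites will be skipped", n_gapped)
    return out


def write_sam(alignments: Sequence[AlignedRead], genome_lengths: dict[str, int], path: str | Path) -> None:
    """Write alignments as minimal SAM (mapped/secondary/unmapped records,
    NM tag on mapped records)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for a in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            if a.status == "unmapped" or a.contig is None:
                rec.flag = 4
                rec.query_sequence = a.seq or None
                sam.write(rec)
                continue
            rec.flag = (16 if a.strand == "-" else 0) | (
                0x100 if a.status == "multimapped" else 0
            )
            rec.reference_id = list(genome_lengths).index(a.contig)
            rec.reference_start = a.start
            rec.mapping_quality = 60 if a.status == "unique" else 0
            rec.cigartuples = [(0, len(a.seq))]
            rec.query_sequence = a.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in a.quals)
            )
            rec.set_tag("NM", a.mismatches or 0)
            sam.write(rec)
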