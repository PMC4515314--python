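"""Allele-aware ungapped micro-aligner for desk-scale genomes.

The aligner scores every candidate placement (position x strand) by its
mismatch count. At sidecar (variant) sites, a read base counts as a
match if it equals the genome base OR — in allele-aware mode — the
recorded alternate allele. This removes the reference-mapping bias in
which reads carrying the non-reference allele pay an extra mismatch and
preferentially fail to map.

A read is ``unique`` when exactly one placement attains the minimum
mismatch count among placements within the allowed budget, ``multimapped``
when several do, and ``unmapped`` when no placement fits the budget.

Candidate generation uses pigeonhole seeding: a read with at most *m*
mismatches, split into *m*+1 equal chunks, must match the reference
exactly over at least one chunk, so exact k-mer lookups on chunk
prefixes enumerate every qualifying placement. Index k-mers overlapping
sidecar sites are expanded to both alleles in allele-aware mode, keeping
the seeding exhaustive. Reads too short to seed fall back to a full
scan. Correctness (agreement with a brute-force scan over every
position and strand) is the contract; throughput on mammalian genomes
is explicitly not — use an external allele-aware aligner and
``ingest_sam`` for that.
"""

from __future__ import annotations

from collections import defaultdict
from bisect import bisect_left, bisect_right
from itertools import product
from typing import Iterable, NamedTuple

from .reads import AlignedRead, Read, revcomp
from .reference import CustomReference

__all__ = ["Placement", "AlleleAwareAligner", "align_read"]

_SEED_CAP = 16  # longest seed k-mer indexed
_MIN_SEED = 6  # below this chunk size, scan instead of seeding


class Placement(NamedTuple):
    contig: str
    pos: int
    strand: str
    mismatches: int


class AlleleAwareAligner:
    """Aligns reads against a :class:`CustomReference`.

    Parameters
    ----------
    ref:
        Reference genome with its alternate-allele sidecar.
    allele_aware:
        When True (default), either allele at a sidecar site matches.
        When False the sidecar is ignored — the biased behaviour the
        pipeline exists to avoid, kept for demonstration and testing.
    max_mismatch:
        Mismatch budget per placement (indels are never allowed).
    """

    def __init__(
        self,
        ref: CustomReference,
        allele_aware: bool = True,
        max_mismatch: int = 1,
    ) -> None:
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.ref = ref
        self.allele_aware = allele_aware
        self.max_mismatch = max_mismatch
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._alt_positions: dict[str, list[int]] = defaultdict(list)
        for contig, pos in sorted(ref.alternate):
            self._alt_positions[contig].append(pos)

    # -- index ------------------------------------------------------------

    def _index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indexes:
            self._indexes[k] = self._build_index(k)
        return self._indexes[k]

    def _build_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in self.ref.genome.contigs.items():
            for i in range(len(seq) - k + 1):
                idx[seq[i : i + k]].append((contig, i))
            if not self.allele_aware:
                continue
            # expand k-mers spanning sidecar sites to every allele combination
            alts = self._alt_positions.get(contig, [])
            starts_done = set()
            for site in alts:
                lo = max(0, site - k + 1)
                hi = min(site, len(seq) - k)
                for start in range(lo, hi + 1):
                    if start in starts_done:
                        continue
                    starts_done.add(start)
                    inside = alts[
                        bisect_left(alts, start) : bisect_right(alts, start + k - 1)
                    ]
                    options = [
                        (seq[p], self.ref.alternate[(contig, p)]) for p in inside
                    ]
                    window = list(seq[start : start + k])
                    for combo in product(*options):
                        if all(c == o[0] for c, o in zip(combo, options)):
                            continue  # all-genome k-mer already indexed
                        for p, base in zip(inside, combo):
                            window[p - start] = base
                        idx["".join(window)].append((contig, start))
        return dict(idx)

    # -- scoring ----------------------------------------------------------

    def _mismatches(self, seq: str, contig: str, pos: int, budget: int) -> int:
        """Mismatch count of ``seq`` placed at (contig, pos); returns
        budget+1 as soon as the budget is exceeded."""
        genome = self.ref.genome[contig]
        if seq == genome[pos : pos + len(seq)]:
            return 0
        mm = 0
        alternate = self.ref.alternate
        aware = self.allele_aware
        for offset, base in enumerate(seq):
            g = genome[pos + offset]
            if base == g:
                continue
            if aware and alternate.get((contig, pos + offset)) == base:
                continue
            mm += 1
            if mm > budget:
                return mm
        return mm

    def placements(self, seq: str) -> list[Placement]:
        """Every placement of ``seq`` (both strands) within the mismatch
        budget, exhaustively."""
        m = self.max_mismatch
        results: list[Placement] = []
        length = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            chunk = length // (m + 1)
            if chunk < _MIN_SEED:
                candidates = {
                    (contig, p)
                    for contig, cseq in self.ref.genome.contigs.items()
                    for p in range(len(cseq) - length + 1)
                }
            else:
                k = min(chunk, _SEED_CAP)
                idx = self._index(k)
                candidates = set()
                for i in range(m + 1):
                    off = i * chunk
                    for contig, p in idx.get(s[off : off + k], ()):
                        candidates.add((contig, p - off))
            for contig, p in candidates:
                if p < 0 or p + length > len(self.ref.genome[contig]):
                    continue
                mm = self._mismatches(s, contig, p, m)
                if mm <= m:
                    results.append(Placement(contig, p, strand, mm))
        return results

    # -- alignment --------------------------------------------------------

    def align(self, read: Read) -> AlignedRead:
        """Place a read; see module docstring for status semantics."""
        pls = self.placements(read.seq)
        if not pls:
            return AlignedRead(read.id, "unmapped", seq=read.seq, quals=read.quals)
        best = min(p.mismatches for p in pls)
        hits = [p for p in pls if p.mismatches == best]
        representative = min(hits)
        status = "unique" if len(hits) == 1 else "multimapped"
        if representative.strand == "+":
            seq, quals = read.seq, read.quals
        else:
            seq, quals = revcomp(read.seq), tuple(reversed(read.quals))
        return AlignedRead(
            read_id=read.id,
            status=status,
            contig=representative.contig,
            start=representative.pos,
            strand=representative.strand,
            mismatches=best,
            seq=seq,
            quals=quals,
        )

    def align_all(self, reads: Iterable[Read]) -> list[AlignedRead]:
        return [self.align(r) for r in reads]

    def allele_observations(
        self, aln: AlignedRead
    ) -> dict[tuple[str, int], tuple[str, int]]:
        """Observed (base, quality) at every sidecar site the read covers."""
        if aln.status != "unique":
            return {}
        out = {}
        alts = self._alt_positions.get(aln.contig, [])
        for pos in alts[
            bisect_left(alts, aln.start) : bisect_left(alts, aln.end)
        ]:
            obs = aln.base_at(pos)
            if obs is not None:
                out[(aln.contig, pos)] = obs
        return out


def align_read(
    read: Read,
    ref: CustomReference,
    max_mismatch: int = 1,
    allele_aware: bool = True,
) -> AlignedRead:
    """One-shot convenience wrapper; build an :class:`AlleleAwareAligner`
    directly when aligning many reads against the same reference."""
    return AlleleAwareAligner(ref, allele_aware, max_mismatch).align(read)
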