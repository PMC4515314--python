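"""Micro-aligner correctness: brute-force oracle equivalence, allele
awareness, multi-mapping, and the reference-bias mechanism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allelign as al
from allelign.reads import revcomp


def brute_force_placements(seq, ref, allele_aware, max_mismatch):
    """Independent oracle: scan every position x strand, counting a read
    base as matching iff it equals the genome base or (allele-aware) the
    sidecar base."""
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for contig, cseq in ref.genome.contigs.items():
            for pos in range(len(cseq) - len(s) + 1):
                mm = 0
                for off, base in enumerate(s):
                    if base == cseq[pos + off]:
                        continue
                    if allele_aware and ref.alternate.get((contig, pos + off)) == base:
                        continue
                    mm += 1
                if mm <= max_mismatch:
                    out.append((contig, pos, strand, mm))
    return sorted(out)


class TestAlignerBasics:
    def test_exact_unique_match(self, tiny_ref):
        read = al.Read("r", tiny_ref.genome["chr1"][10:40], (40,) * 30)
        aln = al.align_read(read, tiny_ref)
        assert (aln.status, aln.contig, aln.start, aln.strand, aln.mismatches) == (
            "unique", "chr1", 10, "+", 0,
        )

    def test_reverse_strand_stored_forward_oriented(self, tiny_ref):
        segment = tiny_ref.genome["chr1"][10:40]
        aln = al.align_read(al.Read("r", revcomp(segment), (40,) * 30), tiny_ref)
        assert aln.strand == "-"
        assert aln.seq == segment
        assert aln.base_at(25) == (segment[15], 40)

    def test_sidecar_allele_matches_only_when_aware(self, tiny_ref):
        """A read carrying the non-genome allele at the het site maps
        cleanly allele-aware but is lost with zero mismatch budget when
        allele-awareness is off — the reference-bias mechanism."""
        segment = list(tiny_ref.genome["chr1"][10:40])
        segment[15] = "G"  # sidecar allele at position 25
        read = al.Read("r", "".join(segment), (40,) * 30)
        aware = al.align_read(read, tiny_ref, max_mismatch=0, allele_aware=True)
        assert (aware.status, aware.mismatches) == ("unique", 0)
        naive = al.align_read(read, tiny_ref, max_mismatch=0, allele_aware=False)
        assert naive.status == "unmapped"

    def test_repeat_copies_give_multimapped(self):
        unit = "ACGTTGCAGCTAGGATCCAG"
        genome = al.GenomeSequence({"chr1": unit + "TTTTTTTTTT" + unit})
        ref = al.CustomReference(genome, {})
        aln = al.align_read(al.Read("r", unit, (40,) * len(unit)), ref)
        assert aln.status == "multimapped"

    def test_read_longer_than_genome_unmapped(self, tiny_ref):
        read = al.Read("r", "A" * 100, (40,) * 100)
        assert al.align_read(read, tiny_ref).status == "unmapped"

    def test_allele_observations_at_covered_sidecar_sites(self, tiny_ref):
        aligner = al.AlleleAwareAligner(tiny_ref)
        read = al.Read("r", tiny_ref.genome["chr1"][10:40], (40,) * 30)
        obs = aligner.allele_observations(aligner.align(read))
        assert obs == {("chr1", 25): ("A", 40)}


@given(st.data())
@settings(deadline=None, max_examples=60, derandomize=True)
def test_oracle_equivalence_on_random_genomes(data):
    """The seeded aligner finds exactly the placements a brute-force scan
    over every position and strand finds."""
    rng_seq = data.draw(st.text(alphabet="ACGT", min_size=60, max_size=300))
    genome = al.GenomeSequence({"c": rng_seq})
    n_sites = data.draw(st.integers(0, 4))
    sidecar = {}
    positions = data.draw(
        st.lists(st.integers(0, len(rng_seq) - 1), min_size=n_sites, max_size=n_sites, unique=True)
    )
    for pos in positions:
        sidecar[("c", pos)] = data.draw(
            st.sampled_from([b for b in "ACGT" if b != rng_seq[pos]])
        )
    ref = al.CustomReference(genome, sidecar)
    max_mismatch = data.draw(st.integers(0, 2))
    aware = data.draw(st.booleans())
    # read drawn from the genome with a few mutations, or random
    if data.draw(st.booleans()):
        start = data.draw(st.integers(0, len(rng_seq) - 30))
        read_seq = list(rng_seq[start : start + 30])
        for _ in range(data.draw(st.integers(0, 2))):
            i = data.draw(st.integers(0, 29))
            read_seq[i] = data.draw(st.sampled_from("ACGT"))
        read_seq = "".join(read_seq)
        if data.draw(st.booleans()):
            read_seq = revcomp(read_seq)
    else:
        read_seq = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=30))
    aligner = al.AlleleAwareAligner(ref, allele_aware=aware, max_mismatch=max_mismatch)
    got = sorted(aligner.placements(read_seq))
    assert got == brute_force_placements(read_seq, ref, aware, max_mismatch)


@pytest.fixture(scope="module")
def het_reads():
    """Reads drawn 50/50 from both alleles of every het site."""
    cfg = al.SimulationConfig(seed=5, imbalanced_fraction=0.0, genome_length=8000,
                              variant_density=5, depth=40)
    sim = al.simulate_truth(cfg)
    reads = al.simulate_reads(sim.genome, sim.complete, sim.truth, cfg)
    ref, _ = al.build_reference(sim.genome, sample_catalog=sim.complete)
    return sim, reads, ref


class TestBiasProperty:
    def _pooled_fraction(self, sim, reads, ref, aware):
        aligner = al.AlleleAwareAligner(ref, allele_aware=aware)
        alns = al.filter_alignments(aligner.align_all(reads))
        n_genome = n_other_allele = 0
        for aln in alns:
            for (contig, pos), (base, qual) in aligner.allele_observations(aln).items():
                if base == ref.genome[contig][pos]:
                    n_genome += 1
                elif base == ref.alternate[(contig, pos)]:
                    n_other_allele += 1
        return n_genome, n_other_allele

    def test_naive_alignment_biases_toward_genome_allele(self, het_reads):
        sim, reads, ref = het_reads
        n_g, n_a = self._pooled_fraction(sim, reads, ref, aware=False)
        frac = n_g / (n_g + n_a)
        assert frac > 0.55

    def test_allele_aware_alignment_is_unbiased(self, het_reads):
        sim, reads, ref = het_reads
        n_g, n_a = self._pooled_fraction(sim, reads, ref, aware=True)
        total = n_g + n_a
        frac = n_g / total
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / total)


def test_complement_reference_gives_identical_unique_placements(std_sim, std_reads):
    """Allele-aware alignment is symmetric in which allele sits in the
    genome: the complement reference yields the same unique placements."""
    ref, _ = al.build_reference(std_sim.genome, sample_catalog=std_sim.complete)
    comp = al.build_complement_reference(ref)
    sample = std_reads[:2000]
    a = {
        (x.read_id, x.contig, x.start, x.strand)
        for x in al.AlleleAwareAligner(ref).align_all(sample)
        if x.status == "unique"
    }
    b = {
        (x.read_id, x.contig, x.start, x.strand)
        for x in al.AlleleAwareAligner(comp).align_all(sample)
        if x.status == "unique"
    }
    assert a == b
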