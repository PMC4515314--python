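"""Custom-reference construction: population major alleles, sample
customization, complement swap, predicted-site updates, and I/O."""

import pytest
from hypothesis import given, settings, strategies as st

import allelign as al
from allelign.reference import (
    read_fasta,
    read_sidecar,
    write_fasta,
    write_sidecar,
)
from allelign.variants import GenotypeCall, Variant, VariantCatalog, VariantError, Zygosity


def _genome(seq="ACGTACGTACGTACGTACGT"):
    return al.GenomeSequence({"chr1": seq})


def _common(*entries):
    cat = VariantCatalog("none")
    for pos, ref, alt, af in entries:
        cat.add(GenotypeCall(Variant("chr1", pos, ref, alt, af=af), Zygosity.UNKNOWN))
    return cat


def _sample(level, *entries):
    cat = VariantCatalog(level)
    for pos, ref, alt, zyg in entries:
        cat.add(GenotypeCall(Variant("chr1", pos, ref, alt), zyg))
    return cat


class TestPopulationReference:
    def test_minor_reference_allele_replaced_by_major(self):
        ref = al.build_population_reference(_genome(), _common((0, "A", "G", 0.7)))
        assert ref.genome["chr1"][0] == "G"
        assert ref.alternate[("chr1", 0)] == "A"

    def test_major_reference_allele_unchanged(self):
        ref = al.build_population_reference(_genome(), _common((0, "A", "G", 0.1)))
        assert ref.genome["chr1"][0] == "A"
        assert ref.alternate[("chr1", 0)] == "G"

    def test_empty_catalog_is_identity(self):
        genome = _genome()
        ref = al.build_population_reference(genome, VariantCatalog("none"))
        assert ref.genome == genome
        assert ref.alternate == {}

    def test_genome_mismatch_raises(self):
        with pytest.raises(VariantError, match="disagrees"):
            al.build_population_reference(_genome(), _common((0, "C", "G", 0.7)))

    def test_n_base_overridden(self):
        ref = al.build_population_reference(
            al.GenomeSequence({"chr1": "NCGT"}), _common((0, "A", "G", 0.7))
        )
        assert ref.genome["chr1"][0] == "G"


class TestCustomizeForSample:
    def test_het_keeps_genome_base_and_records_other(self):
        base = al.CustomReference(_genome(), {})
        ref = al.customize_for_sample(base, _sample("complete", (0, "A", "G", Zygosity.HET)))
        assert ref.genome["chr1"][0] == "A"
        assert ref.alternate[("chr1", 0)] == "G"

    def test_hom_alt_replaces_base_no_sidecar(self):
        base = al.CustomReference(_genome(), {})
        ref = al.customize_for_sample(base, _sample("complete", (0, "A", "G", Zygosity.HOM_ALT)))
        assert ref.genome["chr1"][0] == "G"
        assert ("chr1", 0) not in ref.alternate

    def test_hom_ref_removes_stale_sidecar(self):
        base = al.CustomReference(_genome(), {("chr1", 0): "G"})
        ref = al.customize_for_sample(base, _sample("complete", (0, "A", "G", Zygosity.HOM_REF)))
        assert ref.genome["chr1"][0] == "A"
        assert ("chr1", 0) not in ref.alternate

    def test_het_on_population_major_keeps_major_in_genome(self):
        """After the population stage put the alt in the genome, a het
        genotype keeps it there and sidecars the other sample allele."""
        pop = al.build_population_reference(_genome(), _common((0, "A", "G", 0.9)))
        assert pop.genome["chr1"][0] == "G"
        ref = al.customize_for_sample(pop, _sample("complete", (0, "A", "G", Zygosity.HET)))
        assert ref.genome["chr1"][0] == "G"
        assert ref.alternate[("chr1", 0)] == "A"

    def test_exactly_one_allele_in_genome_per_het_site(self, std_sim):
        ref, _ = al.build_reference(std_sim.genome, sample_catalog=std_sim.complete)
        for key in std_sim.complete.het_sites():
            call = std_sim.complete.records[key]
            genome_base = ref.genome[key[0]][key[1]]
            sidecar_base = ref.alternate[key]
            assert {genome_base, sidecar_base} == {call.variant.ref, call.variant.alt}


class TestComplementReference:
    def test_swap(self):
        ref = al.CustomReference(_genome(), {("chr1", 0): "G"})
        comp = al.build_complement_reference(ref)
        assert comp.genome["chr1"][0] == "G"
        assert comp.alternate[("chr1", 0)] == "A"

    def test_involution_bit_exact(self, std_sim):
        ref, _ = al.build_reference(std_sim.genome, sample_catalog=std_sim.complete)
        assert al.build_complement_reference(al.build_complement_reference(ref)) == ref

    def test_empty_sidecar_identity(self):
        ref = al.CustomReference(_genome(), {})
        assert al.build_complement_reference(ref) == ref


class TestUpdateWithPredicted:
    def test_genome_allele_kept_other_sidecared(self):
        ref = al.CustomReference(al.GenomeSequence({"chr1": "CCGT"}), {})
        out = al.update_reference_with_predicted(ref, [("chr1", 0, "C", "T")])
        assert out.genome["chr1"][0] == "C"
        assert out.alternate[("chr1", 0)] == "T"

    def test_novel_alleles_replace_genome_base(self):
        ref = al.CustomReference(al.GenomeSequence({"chr1": "GCGT"}), {})
        out = al.update_reference_with_predicted(ref, [("chr1", 0, "C", "T")])
        assert out.genome["chr1"][0] == "C"
        assert out.alternate[("chr1", 0)] == "T"

    def test_empty_predicted_identity(self):
        ref = al.CustomReference(_genome(), {("chr1", 2): "C"})
        assert al.update_reference_with_predicted(ref, []) == ref

    def test_conflicting_entry_kept_with_warning(self):
        ref = al.CustomReference(_genome(), {("chr1", 0): "G"})
        with pytest.warns(UserWarning, match="conflict"):
            out = al.update_reference_with_predicted(ref, [("chr1", 0, "C", "T")])
        assert out.alternate[("chr1", 0)] == "G"
        assert out.genome["chr1"][0] == "A"


@given(st.data())
@settings(deadline=None, max_examples=30, derandomize=True)
def test_all_operations_preserve_contig_lengths(data):
    """SNV-only contract: no stage ever changes a contig's length."""
    seq = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=60))
    genome = al.GenomeSequence({"c": seq})
    n_sites = data.draw(st.integers(0, min(5, len(seq))))
    positions = data.draw(
        st.lists(st.integers(0, len(seq) - 1), min_size=n_sites, max_size=n_sites, unique=True)
    )
    common = VariantCatalog("none")
    for pos in positions:
        ref_base = seq[pos]
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_base]))
        af = data.draw(st.floats(0.06, 0.94))
        common.add(GenotypeCall(Variant("c", pos, ref_base, alt, af=af), Zygosity.UNKNOWN))
    ref = al.build_population_reference(genome, common)
    comp = al.build_complement_reference(ref)
    for r in (ref, comp):
        assert r.genome.lengths() == genome.lengths()


class TestReferenceIO:
    def test_fasta_round_trip_wrapped(self, tmp_path, std_sim):
        path = tmp_path / "g.fa"
        write_fasta(std_sim.genome, path)
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) <= 60
        assert read_fasta(path) == std_sim.genome

    def test_sidecar_round_trip(self, tmp_path, std_sim):
        ref, _ = al.build_reference(std_sim.genome, sample_catalog=std_sim.complete)
        path = tmp_path / "ref.sidecar.tsv"
        write_sidecar(ref, path)
        assert read_sidecar(path) == ref.alternate
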