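"""Shared fixtures: a tiny handcrafted reference and the standard
simulated fixture (20 kb genome, 200 het sites, depth 60), built once
per session."""

import pytest

import allelign as al

STD_SEED = 11


@pytest.fixture(scope="session")
def std_config():
    return al.SimulationConfig(seed=STD_SEED)


@pytest.fixture(scope="session")
def std_sim(std_config):
    return al.simulate_truth(std_config)


@pytest.fixture(scope="session")
def std_reads(std_sim, std_config):
    return al.simulate_reads(std_sim.genome, std_sim.complete, std_sim.truth, std_config)


@pytest.fixture(scope="session")
def complete_run(std_sim, std_reads):
    """Complete-genotype pipeline run: the truth standard for evaluation."""
    return al.run_pipeline(std_sim.genome, std_reads, sample_catalog=std_sim.complete)


@pytest.fixture(scope="session")
def partial_run(std_sim, std_reads):
    """Partial-genotype run with het-site prediction and a second round."""
    return al.run_pipeline(
        std_sim.genome,
        std_reads,
        sample_catalog=std_sim.partial,
        params=al.PipelineParams(second_alignment=True),
    )


@pytest.fixture()
def tiny_ref():
    """60 bp genome with one het site at position 25 (genome A / sidecar G)."""
    seq = (
        "ACGTTGCAGCTAGGATCCAGTTGCA"  # 0-24
        "A"  # 25: het site
        "GGCCTTAGACCGTATGCCAGATTGCA"  # 26-51
        "TTGACCGT"  # 52-59
    )
    genome = al.GenomeSequence({"chr1": seq})
    return al.CustomReference(genome, {("chr1", 25): "G"})
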