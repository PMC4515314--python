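"""Demonstrate reference-mapping bias and its removal.

Simulates a diploid sample with perfectly balanced alleles at every
heterozygous site, then aligns the same reads with and without allele
awareness. Without it, reads carrying the non-genome allele spend their
mismatch budget on the variant itself, so any sequencing error loses
the read — inflating the genome-allele fraction above 0.5.
"""

import math

import allelign as al

cfg = al.SimulationConfig(seed=7, imbalanced_fraction=0.0, genome_length=10_000,
                          variant_density=6, depth=50)
sim = al.simulate_truth(cfg)
reads = al.simulate_reads(sim.genome, sim.complete, sim.truth, cfg)
print(f"simulated {len(sim.truth)} balanced het sites, {len(reads)} reads")

for aware in (False, True):
    run = al.run_pipeline(
        sim.genome, reads, sample_catalog=sim.complete,
        params=al.PipelineParams(allele_aware=aware),
    )
    n1 = sum(c.n1 for c in run.counts)
    n2 = sum(c.n2 for c in run.counts)
    frac = n1 / (n1 + n2)
    sd = math.sqrt(0.25 / (n1 + n2))
    label = "allele-aware" if aware else "naive       "
    print(f"{label}: genome-allele fraction {frac:.3f} "
          f"({(frac - 0.5) / sd:+.1f} binomial SDs from 0.5, n={n1 + n2})")

print(
    "Every site is truly balanced, so the expected fraction is 0.5: the naive\n"
    "run sits far above it (spurious imbalance favoring the reference), the\n"
    "allele-aware run within sampling noise."
)
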