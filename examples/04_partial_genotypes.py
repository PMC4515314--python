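"""Evaluate imbalance detection with incomplete genotype information.

The complete-genotype run defines truth. A partial (imputed-style)
catalog covering ~80% of het sites is Rsq-filtered, missing het sites
are predicted from the reads (>=5 reads per allele), and a second
alignment round re-tests them with bias removed. Sensitivity and
precision are reported per stratum.
"""

import allelign as al

cfg = al.SimulationConfig(seed=31)
sim = al.simulate_truth(cfg)
reads = al.simulate_reads(sim.genome, sim.complete, sim.truth, cfg)

complete = al.run_pipeline(sim.genome, reads, sample_catalog=sim.complete)
partial = al.run_pipeline(
    sim.genome, reads, sample_catalog=sim.partial,
    params=al.PipelineParams(second_alignment=True),
)
r1, r2 = partial.rounds
print(f"partial catalog: {len(sim.partial)} of {len(sim.complete)} variants")
print(f"round 1 predicted {len(r1.predicted)} novel het sites; "
      f"round 2 tested {r2.stats['sites_tested']} sites\n")

print(f"{'stratum':24} {'tp':>4} {'fp':>4} {'fn':>4} {'sens':>6} {'prec':>6}")
for r in al.stratified_evaluation(partial.calls, complete.calls):
    sens = "  n/a" if r.sensitivity is None else f"{r.sensitivity:6.1%}"
    prec = "  n/a" if r.precision is None else f"{r.precision:6.1%}"
    print(f"{r.stratum:24} {r.tp:>4} {r.fp:>4} {r.fn:>4} {sens} {prec}")

print(
    "\n'all_restricted_truth' confines truth to sites the partial run tested,\n"
    "separating statistical misses from sites it could never see; the\n"
    "known/predicted strata show that catalogued sites are called with higher\n"
    "confidence than read-predicted ones."
)
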