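"""End-to-end orchestration: reference construction, alignment, filtering,
counting, imbalance calling, and the optional second alignment round.

The pipeline mirrors the standard workflow for allelic-imbalance
detection with reference-bias removal:

1. build a custom reference — population major alleles at common
   variants, overwritten by sample genotypes where available — with an
   alternate-allele sidecar for the allele-aware aligner;
2. QC and align reads allele-aware, keep unique placements outside the
   blacklist, remove PCR duplicates, and apply the allele-swap
   mappability filter;
3. count quality-passing allele observations at catalogued sites and
   test for imbalance; optionally predict novel heterozygous sites from
   the read data;
4. optionally fold the predicted sites into the reference and repeat
   steps 2-3 (the second alignment round), which lets predicted rare
   variants be tested with bias removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import AlleleAwareAligner
from .calling import ImbalanceCall, call_imbalance, predict_het_sites
from .counting import AlleleCount, Site, mappability_filter, pileup_alleles
from .reads import AlignedRead, BlacklistRegions, Read, filter_alignments, qc_reads, remove_duplicates
from .reference import (
    CustomReference,
    GenomeSequence,
    build_population_reference,
    customize_for_sample,
    update_reference_with_predicted,
)
from .variants import VariantCatalog, filter_by_rsq

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "RoundResult", "PipelineState", "run_pipeline", "run_second_alignment", "build_reference"]


@dataclass(frozen=True)
class PipelineParams:
    """Analysis parameters; defaults are the pipeline's standard settings
    (1 mismatch, Q>30 bases, >=5 reads per allele, p<0.01, Rsq>0.3,
    MAF>0.05)."""

    max_mismatch: int = 1
    allele_aware: bool = True
    min_base_quality: int = 30
    min_reads_per_allele: int = 5
    p_threshold: float = 0.01
    test: str = "binomial"
    allow_complete: bool = False
    rsq_threshold: float = 0.3
    maf_threshold: float = 0.05
    predict: bool = True
    second_alignment: bool = False
    trim_to: Optional[int] = None
    min_q: int = 20
    min_fraction: float = 0.90
    apply_qc: bool = True


@dataclass
class RoundResult:
    round: int
    reference: CustomReference
    alignments: list[AlignedRead]
    sites: list[Site]
    counts: list[AlleleCount]
    calls: list[ImbalanceCall]
    predicted: set[tuple[str, int, str, str]]
    stats: dict[str, int]


@dataclass
class PipelineState:
    """Everything needed to run (or re-run) a round."""

    reads: list[Read]
    reference: CustomReference
    sample_catalog: Optional[VariantCatalog]
    common_catalog: Optional[VariantCatalog]
    blacklist: Optional[BlacklistRegions]
    params: PipelineParams
    rounds: list[RoundResult] = field(default_factory=list)

    @property
    def calls(self) -> list[ImbalanceCall]:
        return self.rounds[-1].calls if self.rounds else []

    @property
    def counts(self) -> list[AlleleCount]:
        return self.rounds[-1].counts if self.rounds else []


def build_reference(
    genome: GenomeSequence,
    sample_catalog: Optional[VariantCatalog] = None,
    common_catalog: Optional[VariantCatalog] = None,
    params: PipelineParams = PipelineParams(),
) -> tuple[CustomReference, Optional[VariantCatalog]]:
    """Construct the run's custom reference from whatever information is
    available; returns the reference and the (possibly Rsq-filtered)
    sample catalog actually applied."""
    ref = CustomReference(genome, {})
    if common_catalog is not None:
        ref = build_population_reference(genome, common_catalog)
    applied = sample_catalog
    if sample_catalog is not None:
        if sample_catalog.level == "partial":
            applied = filter_by_rsq(sample_catalog, params.rsq_threshold)
        ref = customize_for_sample(ref, applied)
    return ref, applied


def _catalog_sites(
    ref: CustomReference,
    sample_catalog: Optional[VariantCatalog],
) -> list[Site]:
    """Sites to count over, classed by how they became known."""
    het = sample_catalog.het_sites() if sample_catalog is not None else set()
    sites = []
    for (contig, pos), alt in sorted(ref.alternate.items()):
        cls = "known_het" if (contig, pos) in het else "common_variant"
        sites.append(Site(contig, pos, ref.genome[contig][pos], alt, cls))
    return sites


def _run_round(
    state: PipelineState,
    reference: CustomReference,
    extra_sites: Sequence[Site] = (),
    round_no: int = 1,
) -> RoundResult:
    p = state.params
    aligner = AlleleAwareAligner(reference, p.allele_aware, p.max_mismatch)
    aligned = aligner.align_all(state.reads)
    stats = {
        "reads": len(aligned),
        "unique": sum(a.status == "unique" for a in aligned),
        "multimapped": sum(a.status == "multimapped" for a in aligned),
        "unmapped": sum(a.status == "unmapped" for a in aligned),
    }
    kept = filter_alignments(aligned, state.blacklist)
    stats["blacklisted"] = stats["unique"] - len(kept)
    deduped = remove_duplicates(kept)
    stats["duplicates_removed"] = len(kept) - len(deduped)

    extra_keys = {(s.contig, s.pos) for s in extra_sites}
    sites = [
        s
        for s in _catalog_sites(reference, state.sample_catalog)
        if (s.contig, s.pos) not in extra_keys
    ] + list(extra_sites)
    # the swap re-alignment is always allele-aware, whatever the main
    # alignment mode, since it asks whether placement survives either allele
    swap_aligner = (
        aligner
        if p.allele_aware
        else AlleleAwareAligner(reference, True, p.max_mismatch)
    )
    passed = mappability_filter(deduped, sites, reference, p.max_mismatch, swap_aligner)
    stats["mappability_removed"] = len(deduped) - len(passed)

    counts = pileup_alleles(passed, sites, p.min_base_quality)
    predicted = (
        predict_het_sites(passed, reference, p.min_reads_per_allele, p.min_base_quality)
        if p.predict
        else set()
    )
    calls = call_imbalance(
        counts,
        test=p.test,
        p_threshold=p.p_threshold,
        min_reads_per_allele=p.min_reads_per_allele,
        allow_complete=p.allow_complete,
        round=round_no,
    )
    stats["sites_tested"] = len(calls)
    stats["sites_imbalanced"] = sum(c.imbalanced for c in calls)
    stats["predicted_het"] = len(predicted)
    log.info("round %d: %s", round_no, stats)
    return RoundResult(
        round=round_no,
        reference=reference,
        alignments=passed,
        sites=sites,
        counts=counts,
        calls=calls,
        predicted=predicted,
        stats=stats,
    )


def run_pipeline(
    genome: GenomeSequence,
    reads: Sequence[Read],
    sample_catalog: Optional[VariantCatalog] = None,
    common_catalog: Optional[VariantCatalog] = None,
    blacklist: Optional[BlacklistRegions] = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineState:
    """Run the full pipeline at whichever genotype-information level the
    supplied catalogs imply; with ``params.second_alignment`` the
    predicted heterozygous sites feed an updated reference and a second
    round."""
    ref, applied = build_reference(genome, sample_catalog, common_catalog, params)
    processed = (
        qc_reads(reads, params.trim_to, params.min_q, params.min_fraction)
        if params.apply_qc
        else list(reads)
    )
    state = PipelineState(
        reads=processed,
        reference=ref,
        sample_catalog=applied,
        common_catalog=common_catalog,
        blacklist=blacklist,
        params=params,
    )
    state.rounds.append(_run_round(state, ref))
    if params.second_alignment:
        run_second_alignment(state)
    return state


def run_second_alignment(state: PipelineState) -> PipelineState:
    """Update the reference with round-1 predicted heterozygous sites and
    re-run alignment, filtering, counting and calling.

    With no predicted sites the reference is unchanged and round 2
    reproduces round 1 exactly. Predicted sites are counted and tested
    in round 2 as the lower-confidence ``predicted_het`` class.
    """
    if not state.rounds:
        raise ValueError("second alignment requires a completed first round")
    first = state.rounds[-1]
    updated = update_reference_with_predicted(first.reference, first.predicted)
    extra = []
    for contig, pos, a1, a2 in sorted(first.predicted):
        genome_base = updated.genome[contig][pos]
        other = updated.alternate.get((contig, pos))
        if other is None:  # conflicting prediction was dropped with a warning
            continue
        extra.append(Site(contig, pos, genome_base, other, "predicted_het"))
    state.rounds.append(
        _run_round(state, updated, extra_sites=extra, round_no=first.round + 1)
    )
    return state
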