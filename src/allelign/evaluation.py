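"""Sensitivity/precision evaluation of imbalance calls against a
complete-genotype truth run.

Calls made with complete genotype information define the truth set.
A site is a true positive when both runs flag it imbalanced, a false
positive when only the evaluated run does, and a false negative when
only the truth run does. Sensitivity is TP/(TP+FN) and precision
(positive predictive value) TP/(TP+FP). Matching is by position;
direction agreement (same favored allele) is optional.

Results are stratified by how the evaluated run knew about each site
(catalogued vs predicted), and a restricted-truth variant confines the
truth set to sites the evaluated run actually tested — separating
"missed because untested" from "tested but missed".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .calling import ImbalanceCall
from .variants import VariantCatalog

__all__ = [
    "EvaluationResult",
    "classify_calls",
    "stratified_evaluation",
    "write_evaluation",
    "read_evaluation",
]

SiteKey = tuple[str, int]


@dataclass(frozen=True)
class EvaluationResult:
    stratum: str
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


def _imbalanced_sites(calls: Iterable[ImbalanceCall]) -> dict[SiteKey, ImbalanceCall]:
    return {c.site: c for c in calls if c.imbalanced}


def classify_calls(
    calls: Sequence[ImbalanceCall],
    truth: Sequence[ImbalanceCall],
    strict_direction: bool = False,
) -> tuple[set[SiteKey], set[SiteKey], set[SiteKey]]:
    """Partition imbalanced sites into (tp, fp, fn) sets by position.

    With ``strict_direction`` a match additionally requires the same
    favored allele in both runs; direction-discordant overlaps count as
    both a false positive and a false negative.
    """
    called = _imbalanced_sites(calls)
    truthy = _imbalanced_sites(truth)
    overlap = set(called) & set(truthy)
    if strict_direction:
        tp = {
            s
            for s in overlap
            if called[s].favored_allele is not None
            and called[s].favored_allele == truthy[s].favored_allele
        }
    else:
        tp = overlap
    fp = set(called) - tp
    fn = set(truthy) - tp
    return tp, fp, fn


def stratified_evaluation(
    calls: Sequence[ImbalanceCall],
    truth: Sequence[ImbalanceCall],
    catalog: Optional[VariantCatalog] = None,
    strict_direction: bool = False,
) -> list[EvaluationResult]:
    """Evaluate per stratum: all sites, known/common-variant sites,
    predicted sites, and all sites with the truth restricted to those
    the evaluated run tested.

    Stratum membership comes from the evaluated run's site classes
    (supplemented by the catalog, when given, for truth-only sites).
    """
    tp, fp, fn = classify_calls(calls, truth, strict_direction)
    site_class: dict[SiteKey, str] = {c.site: c.site_class for c in calls}
    if catalog is not None:
        for key in catalog.records:
            site_class.setdefault(key, "known_het")

    def known(s: SiteKey) -> bool:
        return site_class.get(s) in ("known_het", "common_variant")

    def predicted(s: SiteKey) -> bool:
        return site_class.get(s) == "predicted_het"

    tested = {c.site for c in calls}
    results = [
        EvaluationResult("all", len(tp), len(fp), len(fn)),
        EvaluationResult(
            "known_variants",
            sum(known(s) for s in tp),
            sum(known(s) for s in fp),
            sum(known(s) for s in fn),
        ),
        EvaluationResult(
            "predicted_variants",
            sum(predicted(s) for s in tp),
            sum(predicted(s) for s in fp),
            sum(predicted(s) for s in fn),
        ),
        EvaluationResult(
            "all_restricted_truth",
            len(tp),
            len(fp),
            len({s for s in fn if s in tested}),
        ),
    ]
    return results


def write_evaluation(results: Iterable[EvaluationResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["stratum", "tp", "fp", "fn", "sensitivity", "precision"])
        for r in results:
            writer.writerow(
                [
                    r.stratum, r.tp, r.fp, r.fn,
                    "" if r.sensitivity is None else f"{r.sensitivity:.6g}",
                    "" if r.precision is None else f"{r.precision:.6g}",
                ]
            )


def read_evaluation(path: str | Path) -> list[EvaluationResult]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                EvaluationResult(
                    stratum=row["stratum"],
                    tp=int(row["tp"]),
                    fp=int(row["fp"]),
                    fn=int(row["fn"]),
                )
            )
    return out
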