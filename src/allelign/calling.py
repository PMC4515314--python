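"""Allelic-imbalance statistics and heterozygous-site prediction.

Two significance tests are provided for the null of balanced allele
sampling (each read drawn from either allele with probability 0.5):

* an exact two-sided binomial test, b(a1; n, 0.5), where a1 is the
  count for allele1 and n = n1 + n2;
* a beta-binomial Z test that absorbs site-to-site overdispersion
  through a symmetric Beta(alpha, alpha) mixing distribution:

      Z = (P̂ - 0.5) / sqrt((2*alpha + N) / (4*N*(2*alpha + 1)))

  with P̂ = a1/N. The denominator is the standard deviation of P̂ under
  the compound model; as alpha -> infinity it collapses to the plain
  binomial sqrt(1/(4N)). alpha is estimated from the data by the method
  of moments on the squared centered allele proportions.

Sites qualify for testing when each allele has at least
``min_reads_per_allele`` supporting reads (default 5); optionally,
known heterozygous sites where only one allele was ever observed can be
tested too (complete imbalance). Significance uses an uncorrected
p-value threshold (default 0.01); a Benjamini-Hochberg FDR option is
available but off by default.

Heterozygous sites absent from the variant catalog are predicted from
the read data: a position is called heterozygous when at least
``min_reads_per_allele`` quality-passing reads carry the genome base
and at least as many carry one single specific other base.
"""

from __future__ import annotations

import csv
import math
from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom, norm

from .counting import AlleleCount
from .reads import AlignedRead
from .reference import CustomReference

__all__ = [
    "ImbalanceCall",
    "BetaBinomialModel",
    "binomial_pvalue",
    "estimate_alpha",
    "beta_binomial_test",
    "predict_het_sites",
    "call_imbalance",
    "write_calls",
    "read_calls",
    "write_three_tier",
]

_EXACT_N_LIMIT = 1000  # above this, tails via scipy instead of big-integer sums


@dataclass(frozen=True)
class BetaBinomialModel:
    """Symmetric Beta(alpha, alpha) overdispersion model.

    ``alpha = math.inf`` is the no-overdispersion sentinel (pure binomial).
    """

    alpha: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    def proportion_sd(self, n: int) -> float:
        """Standard deviation of the allele-1 proportion at depth n."""
        if math.isinf(self.alpha):
            return math.sqrt(1.0 / (4.0 * n))
        a = self.alpha
        return math.sqrt((2 * a + n) / (4.0 * n * (2 * a + 1)))


@dataclass(frozen=True)
class ImbalanceCall:
    site: tuple[str, int]
    allele1: str
    allele2: str
    n1: int
    n2: int
    p_value: float
    statistic: Optional[float]
    test: str
    site_class: str
    imbalanced: bool
    round: int = 1

    @property
    def favored_allele(self) -> Optional[str]:
        if self.n1 > self.n2:
            return self.allele1
        if self.n2 > self.n1:
            return self.allele2
        return None


def binomial_pvalue(a1: int, n: int) -> float:
    """Exact two-sided binomial tail probability at p = 0.5.

    P(|X - n/2| >= |a1 - n/2|) for X ~ Binomial(n, 0.5); at p = 0.5 this
    equals doubling the smaller one-sided tail, capped at 1. Computed
    with exact integer arithmetic for moderate n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= a1 <= n:
        raise ValueError(f"a1={a1} outside [0, {n}]")
    d2 = abs(2 * a1 - n)  # twice the distance from n/2
    if d2 == 0:
        return 1.0
    if n <= _EXACT_N_LIMIT:
        num = sum(math.comb(n, k) for k in range(n + 1) if abs(2 * k - n) >= d2)
        return min(1.0, num / (1 << n))
    lo = (n - d2) // 2
    hi = (n + d2 + 1) // 2
    return min(1.0, float(binom.cdf(lo, n, 0.5) + binom.sf(hi - 1, n, 0.5)))


def estimate_alpha(
    counts: Iterable[AlleleCount], sentinel_z: float = 3.0
) -> BetaBinomialModel:
    """Method-of-moments fit of the symmetric beta-binomial alpha.

    Solves  mean_i[(2a + N_i) / (4 N_i (2a + 1))] = mean_i[(p̂_i - 0.5)^2]
    over sites with at least one informative read, where p̂_i is the
    allele-1 proportion. When the empirical dispersion is not above the
    pure-binomial floor mean_i[1/(4 N_i)] by more than ``sentinel_z``
    standard errors, returns the infinite-alpha (no overdispersion)
    sentinel; the margin keeps the decision stable under sampling noise
    of the moment itself.
    """
    usable = [(c.n1, c.total) for c in counts if c.total >= 1]
    if len(usable) < 2:
        raise ValueError("alpha estimation needs at least 2 sites with reads")
    ns = np.array([n for _, n in usable], dtype=float)
    sq = np.array([(a / n - 0.5) ** 2 for a, n in usable])
    v = float(sq.mean())
    floor = float(np.mean(1.0 / (4.0 * ns)))
    se = float(sq.std(ddof=1) / math.sqrt(len(sq)))
    if v <= floor + sentinel_z * se:
        return BetaBinomialModel(math.inf)

    def moment_gap(a: float) -> float:
        return float(np.mean((2 * a + ns) / (4 * ns * (2 * a + 1)))) - v

    lo = 1e-9
    if moment_gap(lo) <= 0:  # dispersion at/above the alpha->0 ceiling of 1/4
        return BetaBinomialModel(lo)
    return BetaBinomialModel(float(brentq(moment_gap, lo, 1e12)))


def beta_binomial_test(
    a1: int, n: int, model: BetaBinomialModel
) -> tuple[float, float]:
    """Beta-binomial Z statistic and two-sided normal-tail p-value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= a1 <= n:
        raise ValueError(f"a1={a1} outside [0, {n}]")
    z = (a1 / n - 0.5) / model.proportion_sd(n)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(1.0, p)


def predict_het_sites(
    alignments: Iterable[AlignedRead],
    ref: CustomReference,
    min_reads_per_allele: int = 5,
    min_base_quality: int = 30,
) -> set[tuple[str, int, str, str]]:
    """Predict heterozygous sites absent from the variant catalog.

    Returns (contig, pos, genome_allele, alternate_allele) for positions
    not in the sidecar where the genome base and one single other base
    each have at least ``min_reads_per_allele`` quality-passing reads.
    The alternate is the most frequent non-genome base (largest count,
    alphabetical tie-break).
    """
    alignments = [a for a in alignments if a.status == "unique"]
    genome = ref.genome
    sidecar = ref.alternate
    # pass 1: positions where any read shows a quality non-genome base
    candidates: set[tuple[str, int]] = set()
    for aln in alignments:
        contig_seq = genome[aln.contig]
        if aln.pos_map is None and aln.seq == contig_seq[aln.start : aln.end]:
            continue
        span = aln.pos_map.keys() if aln.pos_map is not None else range(aln.start, aln.end)
        for pos in span:
            base, qual = aln.base_at(pos)
            if (
                qual > min_base_quality
                and base != contig_seq[pos]
                and base != "N"
                and (aln.contig, pos) not in sidecar
            ):
                candidates.add((aln.contig, pos))
    if not candidates:
        return set()
    # pass 2: full base tallies at candidate positions
    by_contig: dict[str, list[int]] = defaultdict(list)
    for contig, pos in candidates:
        by_contig[contig].append(pos)
    for lst in by_contig.values():
        lst.sort()
    tallies: dict[tuple[str, int], Counter] = {key: Counter() for key in candidates}
    for aln in alignments:
        positions = by_contig.get(aln.contig)
        if not positions:
            continue
        for pos in positions[
            bisect_left(positions, aln.start) : bisect_left(positions, aln.end)
        ]:
            obs = aln.base_at(pos)
            if obs is not None and obs[1] > min_base_quality:
                tallies[(aln.contig, pos)][obs[0]] += 1
    predicted = set()
    for (contig, pos), tally in tallies.items():
        g = genome[contig][pos]
        if tally[g] < min_reads_per_allele:
            continue
        others = [(cnt, b) for b, cnt in tally.items() if b not in (g, "N")]
        if not others:
            continue
        best_count, best_base = max(others, key=lambda t: (t[0], t[1]))
        if best_count >= min_reads_per_allele:
            predicted.add((contig, pos, g, best_base))
    return predicted


def call_imbalance(
    counts: Sequence[AlleleCount],
    test: str = "binomial",
    p_threshold: float = 0.01,
    min_reads_per_allele: int = 5,
    allow_complete: bool = False,
    model: Optional[BetaBinomialModel] = None,
    fdr: Optional[float] = None,
    round: int = 1,
) -> list[ImbalanceCall]:
    """Test qualifying sites for allelic imbalance.

    A site is tested when min(n1, n2) >= ``min_reads_per_allele``; with
    ``allow_complete``, known heterozygous and common-variant sites with
    min(n1, n2) = 0 but n1 + n2 >= 2 * min_reads_per_allele are also
    tested (complete imbalance: only one allele observed). All tested
    sites are reported; ``imbalanced`` flags p < ``p_threshold`` (or a
    Benjamini-Hochberg pass when ``fdr`` is set). Equal counts are never
    flagged imbalanced.
    """
    if test not in ("binomial", "beta_binomial"):
        raise ValueError(f"unknown test {test!r}")
    tested = []
    for c in counts:
        if min(c.n1, c.n2) >= min_reads_per_allele:
            tested.append(c)
        elif (
            allow_complete
            and c.site_class in ("known_het", "common_variant")
            and min(c.n1, c.n2) == 0
            and c.total >= 2 * min_reads_per_allele
        ):
            tested.append(c)
    if test == "beta_binomial" and model is None:
        model = estimate_alpha(tested) if len(tested) >= 2 else BetaBinomialModel(math.inf)
    calls = []
    for c in tested:
        if test == "binomial":
            p = binomial_pvalue(c.n1, c.total)
            stat = None
        else:
            stat, p = beta_binomial_test(c.n1, c.total, model)
        calls.append(
            ImbalanceCall(
                site=c.site,
                allele1=c.allele1,
                allele2=c.allele2,
                n1=c.n1,
                n2=c.n2,
                p_value=p,
                statistic=stat,
                test=test,
                site_class=c.site_class,
                imbalanced=p < p_threshold and c.n1 != c.n2,
                round=round,
            )
        )
    if fdr is not None and calls:
        flags = _bh_reject([c.p_value for c in calls], fdr)
        calls = [
            ImbalanceCall(
                **{**c.__dict__, "imbalanced": bool(keep) and c.n1 != c.n2}
            )
            for c, keep in zip(calls, flags)
        ]
    return sorted(calls, key=lambda c: c.site)


def _bh_reject(pvalues: Sequence[float], q: float) -> np.ndarray:
    p = np.asarray(pvalues)
    m = len(p)
    order = np.argsort(p)
    thresholds = q * (np.arange(1, m + 1)) / m
    passing = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if passing.any():
        cutoff = np.max(np.nonzero(passing)[0])
        reject[order[: cutoff + 1]] = True
    return reject


_CALL_FIELDS = [
    "contig", "position", "allele1", "allele2", "n1", "n2",
    "p_value", "statistic", "test", "site_class", "imbalanced", "round",
]


def write_calls(calls: Iterable[ImbalanceCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_FIELDS)
        for c in sorted(calls, key=lambda c: c.site):
            writer.writerow(
                [
                    c.site[0], c.site[1] + 1, c.allele1, c.allele2, c.n1, c.n2,
                    f"{c.p_value:.6g}",
                    "" if c.statistic is None else f"{c.statistic:.6g}",
                    c.test, c.site_class, int(c.imbalanced), c.round,
                ]
            )


def read_calls(path: str | Path) -> list[ImbalanceCall]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ImbalanceCall(
                    site=(row["contig"], int(row["position"]) - 1),
                    allele1=row["allele1"],
                    allele2=row["allele2"],
                    n1=int(row["n1"]),
                    n2=int(row["n2"]),
                    p_value=float(row["p_value"]),
                    statistic=float(row["statistic"]) if row["statistic"] else None,
                    test=row["test"],
                    site_class=row["site_class"],
                    imbalanced=bool(int(row["imbalanced"])),
                    round=int(row["round"]),
                )
            )
    return out


def write_three_tier(calls: Sequence[ImbalanceCall], prefix: str | Path) -> dict[str, Path]:
    """Write the three confidence tiers: all calls, calls at known or
    common variants (higher confidence), calls at predicted variants
    (lower confidence)."""
    prefix = Path(prefix)
    tiers = {
        "all": list(calls),
        "known": [c for c in calls if c.site_class in ("known_het", "common_variant")],
        "predicted": [c for c in calls if c.site_class == "predicted_het"],
    }
    paths = {}
    for name, subset in tiers.items():
        path = prefix.with_name(prefix.name + f".{name}.tsv")
        write_calls(subset, path)
        paths[name] = path
    return paths
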