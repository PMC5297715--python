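"""Cohort-level descriptive statistics and group comparisons.

Covers per-patient/per-gene/per-chromosome event counts, gene recurrence
across patients, SNP-vs-indel gene overlap, two-sided Fisher exact
comparisons of mutation burden between clinical groups, and degree
ranking of a score-thresholded gene interaction network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping

from scipy.stats import fisher_exact

from .records import CohortTable, normalize_gene

__all__ = [
    "CohortSummary",
    "GroupComparison",
    "NetworkEdge",
    "summarize",
    "gene_set_overlap",
    "fisher_group_test",
    "network_hub_summary",
]


@dataclass
class CohortSummary:
    per_patient_counts: dict[str, int]
    per_gene_events: dict[str, int]
    per_chromosome_counts: dict[str, int]
    recurrence: dict[str, float]
    zygosity_counts: dict[str, int]

    @property
    def total_events(self) -> int:
        return sum(self.per_patient_counts.values())


@dataclass(frozen=True)
class GroupComparison:
    grouping: Mapping[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]
    construction: str
    p_value: float


@dataclass(frozen=True)
class NetworkEdge:
    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if normalize_gene(self.gene_a) == normalize_gene(self.gene_b):
            raise ValueError(f"self edge on {self.gene_a}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("edge score must lie in [0, 1]")


def summarize(cohort: CohortTable) -> CohortSummary:
    """Count events per patient, gene and chromosome; gene recurrence is
    the fraction of cohort patients carrying at least one event in the
    gene (denominator = all patients in the cohort table)."""
    per_patient = Counter({p.patient_id: 0 for p in cohort.patients})
    per_gene: Counter = Counter()
    per_chrom: Counter = Counter()
    zygosity = Counter({"het": 0, "hom": 0})
    carriers: dict[str, set[str]] = {}
    for v in cohort.variants:
        per_patient[v.patient_id] += 1
        gene = normalize_gene(v.gene)
        per_gene[gene] += 1
        per_chrom[v.chromosome] += 1
        zygosity[v.zygosity] += 1
        carriers.setdefault(gene, set()).add(v.patient_id)
    n_patients = len(per_patient)
    recurrence = {g: len(c) / n_patients for g, c in carriers.items()} if n_patients else {}
    return CohortSummary(
        per_patient_counts=dict(per_patient),
        per_gene_events=dict(per_gene),
        per_chromosome_counts=dict(per_chrom),
        recurrence=recurrence,
        zygosity_counts=dict(zygosity),
    )


def gene_set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> set[str]:
    """Symbol-normalized exact intersection of two gene sets."""
    return {normalize_gene(g) for g in set_a} & {normalize_gene(g) for g in set_b}


def _check_margins(table) -> None:
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("empty margin in 2x2 table")


def fisher_group_test(
    summary: CohortSummary,
    grouping: Mapping[str, str],
    construction: str = "median_dichotomy",
) -> GroupComparison:
    """Two-sided Fisher exact comparison of mutation burden between two
    patient groups.

    ``median_dichotomy`` dichotomises patients at the cohort median event
    count (> median = high burden) and crosses that with the grouping;
    ``pooled_events`` crosses total event counts against patient counts
    per group. The two-sided p sums the probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    """
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise ValueError(f"grouping must define exactly 2 groups, got {labels}")
    g1, g2 = labels
    counts = summary.per_patient_counts
    unknown = set(grouping) - set(counts)
    if unknown:
        raise ValueError(f"grouping names unknown patients: {sorted(unknown)}")
    members = {g: [p for p in counts if grouping.get(p) == g] for g in labels}
    if not members[g1] or not members[g2]:
        raise ValueError("both groups must be non-empty")

    if construction == "median_dichotomy":
        med = median(counts[p] for p in grouping)
        table = (
            (
                sum(counts[p] > med for p in members[g1]),
                sum(counts[p] > med for p in members[g2]),
            ),
            (
                sum(counts[p] <= med for p in members[g1]),
                sum(counts[p] <= med for p in members[g2]),
            ),
        )
    elif construction == "pooled_events":
        table = (
            (
                sum(counts[p] for p in members[g1]),
                sum(counts[p] for p in members[g2]),
            ),
            (len(members[g1]), len(members[g2])),
        )
    else:
        raise ValueError(f"unknown construction {construction!r}")
    _check_margins(table)
    _, p = fisher_exact(table, alternative="two-sided")
    return GroupComparison(dict(grouping), table, construction, float(p))


def network_hub_summary(
    edges: Iterable[NetworkEdge], min_score: float = 0.7
) -> list[tuple[str, int]]:
    """Drop edges scoring <= ``min_score`` (strict threshold) and rank
    genes by degree, ties broken alphabetically."""
    degree: Counter = Counter()
    for e in edges:
        if e.score > min_score:
            degree[normalize_gene(e.gene_a)] += 1
            degree[normalize_gene(e.gene_b)] += 1
    return sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
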