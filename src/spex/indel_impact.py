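"""Functional classification of coding indels.

Categories follow the standard exome-annotation scheme:

========  ==========================================  ========
category  meaning                                     impact
========  ==========================================  ========
FS        frameshift (net length change not % 3)      High
SSD/SSA   splice donor / acceptor dinucleotide hit    High
CI        in-frame codon insertion at codon boundary  Moderate
CD        in-frame deletion of whole codons           Moderate
C&I       in-frame insertion splitting a codon        Moderate
C&D       in-frame deletion breaking codon alignment  Moderate
noncoding outside CDS and splice windows              Low
========  ==========================================  ========

Alleles are VCF-style anchored: the first base of ref/alt is a shared
anchor, a deletion removes positions ``pos+1 .. pos+len(ref)-1`` and an
insertion falls between ``pos`` and ``pos+1``. Reading frames accumulate
across CDS intervals, strand-aware. Splice classification takes
precedence over CDS classification: a splice-disrupting indel is High
impact irrespective of its frame.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import VariantRecord, normalize_chromosome

__all__ = [
    "TranscriptModel",
    "IndelClassification",
    "classify_indel",
    "impact_summary",
    "fixture_classifications",
    "read_transcript_model",
    "CATEGORY_IMPACT",
]

#: Impact tier implied by each functional category.
CATEGORY_IMPACT = {
    "FS": "High",
    "SSD": "High",
    "SSA": "High",
    "CD": "Moderate",
    "CI": "Moderate",
    "C&D": "Moderate",
    "C&I": "Moderate",
    "noncoding": "Low",
}


@dataclass(frozen=True)
class IndelClassification:
    category: str
    impact: str
    net_length_change: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_IMPACT:
            raise ValueError(f"unknown category {self.category!r}")
        if self.impact != CATEGORY_IMPACT[self.category]:
            raise ValueError(
                f"impact {self.impact!r} inconsistent with category {self.category!r}"
            )

    @classmethod
    def of(cls, category: str, net: int) -> "IndelClassification":
        return cls(category, CATEGORY_IMPACT[category], net)


@dataclass(frozen=True)
class TranscriptModel:
    """CDS intervals of one transcript, with derived splice windows.

    ``cds_intervals`` are 1-based inclusive, sorted by genomic start and
    non-overlapping. Splice donor/acceptor windows are the canonical two
    intronic bases (GT/AG) flanking each internal exon boundary; which
    side is donor vs acceptor depends on the strand.
    """

    transcript_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        ivs = tuple((int(a), int(b)) for a, b in self.cds_intervals)
        if not ivs:
            raise ValueError("transcript has no CDS intervals")
        for a, b in ivs:
            if a > b:
                raise ValueError(f"interval {a}-{b} reversed")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
        if sum(b - a + 1 for a, b in ivs) < 3:
            raise ValueError("total CDS length must be >= 3")
        object.__setattr__(self, "cds_intervals", ivs)

    @property
    def splice_donor_sites(self) -> tuple[tuple[int, int], ...]:
        return self._splice_windows()[0]

    @property
    def splice_acceptor_sites(self) -> tuple[tuple[int, int], ...]:
        return self._splice_windows()[1]

    def _splice_windows(self):
        donors, acceptors = [], []
        for (a1, b1), (a2, b2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if a2 - b1 - 1 < 2:  # intron too short for both dinucleotides
                continue
            left = (b1 + 1, b1 + 2)
            right = (a2 - 2, a2 - 1)
            if self.strand == "+":
                donors.append(left)
                acceptors.append(right)
            else:
                donors.append(right)
                acceptors.append(left)
        return tuple(donors), tuple(acceptors)

    # -- coordinate helpers -------------------------------------------------

    def contains(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.cds_intervals)

    def coding_offset(self, pos: int) -> int:
        """0-based index of the coding base at ``pos`` in transcription
        order (``pos`` must lie inside the CDS)."""
        intervals = self.cds_intervals if self.strand == "+" else tuple(reversed(self.cds_intervals))
        before = 0
        for a, b in intervals:
            if a <= pos <= b:
                return before + ((pos - a) if self.strand == "+" else (b - pos))
            before += b - a + 1
        raise ValueError(f"position {pos} outside CDS")


def _intersects(span: tuple[int, int], window: tuple[int, int]) -> bool:
    return span[0] <= window[1] and window[0] <= span[1]


def classify_indel(variant: VariantRecord, model: TranscriptModel) -> IndelClassification:
    """Assign the functional category and impact tier of one indel against
    a transcript model (see module docstring for the decision order)."""
    ref, alt, pos = variant.ref_allele, variant.alt_allele, variant.position
    if len(ref) == 1 and len(alt) == 1:
        raise ValueError("not an indel: both alleles are single bases")
    if variant.chromosome != model.chromosome:
        raise ValueError(
            f"variant on {variant.chromosome} does not match transcript "
            f"chromosome {model.chromosome}"
        )
    net = len(alt) - len(ref)
    is_deletion_like = len(ref) > 1
    is_pure_insertion = len(ref) == 1 and len(alt) > 1
    is_pure_deletion = len(alt) == 1 and len(ref) > 1
    deleted_span = (pos + 1, pos + len(ref) - 1) if is_deletion_like else None

    # 1. splice windows take precedence
    for windows, category in (
        (model.splice_donor_sites, "SSD"),
        (model.splice_acceptor_sites, "SSA"),
    ):
        for w in windows:
            if deleted_span is not None and _intersects(deleted_span, w):
                return IndelClassification.of(category, net)
            if is_pure_insertion and w[0] <= pos < w[1]:
                return IndelClassification.of(category, net)

    # 2. CDS
    if is_deletion_like:
        touched = [p for p in range(deleted_span[0], deleted_span[1] + 1) if model.contains(p)]
        in_cds = bool(touched)
    else:
        # insertion between two coding bases of the same interval
        in_cds = any(a <= pos and pos + 1 <= b for a, b in model.cds_intervals)
    if not in_cds:
        return IndelClassification.of("noncoding", net)
    if net % 3 != 0:
        return IndelClassification.of("FS", net)

    if is_pure_insertion:
        # downstream-in-transcript neighbour of the insertion point
        nbr = pos + 1 if model.strand == "+" else pos
        at_codon_boundary = model.coding_offset(nbr) % 3 == 0
        return IndelClassification.of("CI" if at_codon_boundary else "C&I", net)
    if is_pure_deletion:
        n_del = deleted_span[1] - deleted_span[0] + 1
        whole_codons = (
            len(touched) == n_del
            and n_del % 3 == 0
            and min(model.coding_offset(p) for p in touched) % 3 == 0
        )
        return IndelClassification.of("CD" if whole_codons else "C&D", net)
    # complex (both alleles > 1 base): in-frame change plus net gain/loss
    return IndelClassification.of("C&D" if net < 0 else "C&I", net)


def impact_summary(classifications: Iterable[IndelClassification]) -> dict:
    """Histogram the functional categories and impact tiers.

    Returns ``{"by_category": Counter, "by_impact": Counter}``; chromosome
    breakdowns are computed by :func:`impact_by_chromosome` which needs
    the records themselves.
    """
    by_category: Counter = Counter()
    by_impact: Counter = Counter()
    for c in classifications:
        by_category[c.category] += 1
        by_impact[c.impact] += 1
    return {"by_category": dict(by_category), "by_impact": dict(by_impact)}


def impact_by_chromosome(
    records: Sequence[VariantRecord],
    classifications: Sequence[IndelClassification],
) -> dict[str, dict[str, int]]:
    """Per-chromosome impact-tier counts (records and classifications
    aligned by index)."""
    out: dict[str, Counter] = {}
    for rec, cls in zip(records, classifications, strict=True):
        out.setdefault(rec.chromosome, Counter())[cls.impact] += 1
    return {chrom: dict(c) for chrom, c in out.items()}


def fixture_classifications(cohort) -> list[IndelClassification]:
    """Build classifications for fixture indel records that carry their
    printed category in ``extras`` (the printed tables omit coordinates,
    so they cannot be re-derived from a transcript model)."""
    out = []
    for v in cohort.variants:
        category = v.extras.get("category")
        if category is None:
            raise ValueError(f"record {v.gene} has no printed category")
        out.append(IndelClassification.of(category, v.net_length_change))
    return out


def read_transcript_model(path, transcript_id: str | None = None) -> TranscriptModel:
    """Read one transcript's CDS intervals from a minimal GFF3 (CDS
    features only) or a BED12 line."""
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12(path, transcript_id)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype=str,
    )
    cds = df[df["type"] == "CDS"].copy()
    if transcript_id is not None:
        cds = cds[cds["attributes"].str.contains(transcript_id, regex=False)]
    if cds.empty:
        raise ValueError(f"no CDS features found in {path}")
    ivs = sorted((int(r.start), int(r.end)) for r in cds.itertuples())
    strand = cds["strand"].iloc[0]
    tid = transcript_id or "transcript"
    return TranscriptModel(tid, normalize_chromosome(cds["seqid"].iloc[0]), strand, tuple(ivs))


def _read_bed12(path: str, transcript_id: str | None) -> TranscriptModel:
    for line in open(path):
        if line.startswith(("#", "track", "browser")) or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        name = f[3]
        if transcript_id is not None and name != transcript_id:
            continue
        chrom_start = int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        thick_start, thick_end = int(f[6]), int(f[7])  # CDS bounds, 0-based half-open
        ivs = []
        for size, start in zip(sizes, starts):
            a = chrom_start + start
            b = a + size  # half-open
            a, b = max(a, thick_start), min(b, thick_end)
            if a < b:
                ivs.append((a + 1, b))  # to 1-based inclusive
        return TranscriptModel(name, normalize_chromosome(f[0]), f[5], tuple(ivs))
    raise ValueError(f"transcript {transcript_id!r} not found in {path}")
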