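"""Somatic variant filtering for paired tumor/normal exomes.

The cascade keeps a tumor call when it is (1) absent from the matched
normal tissue at the same locus and allele, (2) consequence-relevant
(non-synonymous, coding), and (3) rare in population databases
(frequency <= 0.5% or unreported). Each stage is a pure predicate over
one record, so the retained set is order-independent; the removal
*attribution* in the report follows the fixed stage order
normal-subtraction -> consequence -> frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .records import VariantRecord

__all__ = [
    "FilterParameters",
    "FilterReport",
    "subtract_matched_normal",
    "apply_consequence_filter",
    "apply_frequency_filter",
    "run_filter_pipeline",
]


@dataclass(frozen=True)
class FilterParameters:
    """Thresholds for the somatic filtering cascade.

    max_population_freq:
        Records with a known population frequency strictly above this
        fraction are removed (default 0.005, i.e. >0.5% removed, =0.5%
        kept). Unknown frequency counts as rare.
    drop_consequences:
        Consequence classes removed outright.
    match_keys:
        Record fields defining tumor-vs-normal identity.
    """

    max_population_freq: float = 0.005
    drop_consequences: frozenset[str] = frozenset({"synonymous", "noncoding"})
    match_keys: tuple[str, ...] = ("chromosome", "position", "ref_allele", "alt_allele")

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_population_freq <= 1.0:
            raise ValueError("max_population_freq must lie in [0, 1]")
        object.__setattr__(self, "drop_consequences", frozenset(self.drop_consequences))

    def record_key(self, v: VariantRecord) -> tuple:
        return tuple(getattr(v, k) for k in self.match_keys)


@dataclass
class FilterReport:
    """Per-stage removal attribution; counts partition the input."""

    input_count: int
    removed_by_normal: int
    removed_by_consequence: int
    removed_by_frequency: int
    retained: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.removed_by_normal
            + self.removed_by_consequence
            + self.removed_by_frequency
            + len(self.retained)
        )
        if total != self.input_count:
            raise ValueError("stage counts do not partition the input")


def _check_single_patient(*collections: Sequence[VariantRecord]) -> None:
    ids = {v.patient_id for coll in collections for v in coll}
    if len(ids) > 1:
        raise ValueError(f"records from multiple patients: {sorted(ids)}")


def subtract_matched_normal(
    tumor: Sequence[VariantRecord],
    normal: Sequence[VariantRecord],
    params: FilterParameters = FilterParameters(),
) -> list[VariantRecord]:
    """Keep tumor records whose locus/allele identity is absent from the
    matched normal sample (order preserved)."""
    _check_single_patient(tumor, normal)
    normal_keys = {params.record_key(v) for v in normal}
    return [v for v in tumor if params.record_key(v) not in normal_keys]


def apply_consequence_filter(
    variants: Sequence[VariantRecord],
    params: FilterParameters = FilterParameters(),
) -> list[VariantRecord]:
    """Drop synonymous and non-coding calls (or any configured set)."""
    return [v for v in variants if v.consequence not in params.drop_consequences]


def apply_frequency_filter(
    variants: Sequence[VariantRecord],
    params: FilterParameters = FilterParameters(),
) -> list[VariantRecord]:
    """Drop calls with known population frequency strictly above the
    threshold; unknown frequency is treated as rare (novel allele)."""
    return [
        v
        for v in variants
        if v.population_freq is None or v.population_freq <= params.max_population_freq
    ]


def run_filter_pipeline(
    tumor: Sequence[VariantRecord],
    normal: Sequence[VariantRecord],
    params: FilterParameters = FilterParameters(),
) -> FilterReport:
    """Run the full cascade and attribute each removal to the first stage
    that rejects the record."""
    _check_single_patient(tumor, normal)
    stage1 = subtract_matched_normal(tumor, normal, params)
    stage2 = apply_consequence_filter(stage1, params)
    stage3 = apply_frequency_filter(stage2, params)
    return FilterReport(
        input_count=len(tumor),
        removed_by_normal=len(tumor) - len(stage1),
        removed_by_consequence=len(stage1) - len(stage2),
        removed_by_frequency=len(stage2) - len(stage3),
        retained=stage3,
    )
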