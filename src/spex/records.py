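"""Core domain records for paired tumor/normal exome variant analysis.

A :class:`VariantRecord` is one called variant event in one patient; a
:class:`CohortTable` bundles the events of a cohort with per-patient
clinical metadata. Positions are 1-based (VCF convention) throughout;
BED export converts to 0-based half-open coordinates at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "VariantRecord",
    "PatientMeta",
    "CohortTable",
    "CHROMOSOMES",
    "AUTOSOMES",
    "CONSEQUENCES",
    "normalize_chromosome",
    "normalize_gene",
    "chromosome_sort_key",
]

#: Valid chromosome names, in genome order.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

#: Chromosomes eligible for homozygosity mapping.
AUTOSOMES: frozenset[str] = frozenset(f"chr{i}" for i in range(1, 23))

#: Recognised functional consequences of a variant.
CONSEQUENCES: frozenset[str] = frozenset(
    {"missense", "synonymous", "frameshift", "inframe", "splice", "noncoding", "other"}
)

_CHROM_ORDER = {name: i for i, name in enumerate(CHROMOSOMES)}

_VALID_BASES = frozenset("ACGT")


def normalize_chromosome(chrom: str) -> str:
    """Map chromosome spellings like ``01``, ``chr03`` or ``X`` to ``chr1``/``chrX``."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.lstrip("0") or "0"
    c = c.upper() if c in ("x", "y", "X", "Y") else c
    name = f"chr{c}"
    if name not in _CHROM_ORDER:
        raise ValueError(f"unrecognised chromosome: {chrom!r}")
    return name


def normalize_gene(symbol: str) -> str:
    """Strip markdown emphasis and whitespace from a gene symbol; uppercase it."""
    return symbol.strip().strip("*").strip().upper()


def chromosome_sort_key(chrom: str) -> int:
    return _CHROM_ORDER[chrom]


@dataclass(frozen=True)
class VariantRecord:
    """One called variant event (SNP or indel) in one patient.

    ``population_freq`` is the highest frequency reported for the allele in
    population databases, as a fraction in [0, 1]; ``None`` means unknown
    (a novel allele). ``extras`` carries pass-through annotations such as
    the printed impact/category of fixture indels; it does not take part
    in equality.
    """

    patient_id: str
    gene: str
    variant_class: str  # "snp" | "indel"
    consequence: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # "het" | "hom"
    transcript_change: str = ""
    codon_change: str = ""
    population_freq: float | None = None
    extras: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.chromosome not in _CHROM_ORDER:
            raise ValueError(f"unrecognised chromosome: {self.chromosome!r}")
        for name, allele in (("ref_allele", self.ref_allele), ("alt_allele", self.alt_allele)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} must be a non-empty string over ACGT, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        is_snp = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        if (self.variant_class == "snp") != is_snp:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele}"
            )
        if self.variant_class not in ("snp", "indel"):
            raise ValueError(f"variant_class must be snp or indel, got {self.variant_class!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unrecognised consequence: {self.consequence!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")
        if self.population_freq is not None and not 0.0 <= self.population_freq <= 1.0:
            raise ValueError(f"population_freq outside [0, 1]: {self.population_freq}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Locus/allele identity used for tumor-vs-normal matching."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class PatientMeta:
    """Clinical metadata for one patient; unknown values are ``None``."""

    patient_id: str
    gender: str | None = None
    age_years: int | None = None
    size_mm: int | None = None
    tnm_stage: str | None = None
    location: str | None = None
    metastasis: bool | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years <= 0:
            raise ValueError("age_years must be positive when known")
        if self.size_mm is not None and self.size_mm <= 0:
            raise ValueError("size_mm must be positive when known")


@dataclass
class CohortTable:
    """Ordered variant events plus the patients they belong to."""

    variants: list[VariantRecord]
    patients: list[PatientMeta]

    def __post_init__(self) -> None:
        known = {p.patient_id for p in self.patients}
        missing = {v.patient_id for v in self.variants} - known
        if missing:
            raise ValueError(f"variants reference unknown patients: {sorted(missing)}")

    @classmethod
    def from_variants(cls, variants: list[VariantRecord]) -> "CohortTable":
        """Build a table whose patient list is stubbed from the variant rows."""
        seen: dict[str, None] = {}
        for v in variants:
            seen.setdefault(v.patient_id, None)
        return cls(list(variants), [PatientMeta(pid) for pid in seen])

    def genes(self) -> set[str]:
        return {normalize_gene(v.gene) for v in self.variants if v.gene != "unknown"}

    def __len__(self) -> int:
        return len(self.variants)
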