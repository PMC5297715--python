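"""Seeded synthetic data with known truth for every pipeline stage.

Two generators emulate the study design:

* :func:`generate_paired_cohort` — paired tumor/normal exome variant
  tables per patient: shared germline events plus tumor-only somatic
  events, with consequence classes, population frequencies and one
  recurrent driver-gene hit per patient (CTNNB1-like, probability 1 by
  default).
* :func:`generate_marker_map` — autosomal exome marker maps with planted
  homozygous stretches under a binomial read-sampling model: inside a
  plant the truth zygosity is homozygous and variant reads follow
  Binomial(depth, 1 - error); elsewhere markers are heterozygous with
  ``het_truth_rate`` and draw Binomial(depth, 0.5).

A single pseudo-random stream per run is seeded once and consumed in a
fixed order (per patient: germline, then somatic; per chromosome:
positions, zygosity, depths, reads), so identical configurations yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .records import VariantRecord

__all__ = ["SimulationConfig", "TruthLabels", "generate_paired_cohort", "generate_marker_map"]

#: hg19-scale autosome lengths (Mb resolution) — the coordinate frame for
#: synthetic events.
DEFAULT_GENOME: tuple[tuple[str, int], ...] = (
    ("chr1", 249_000_000), ("chr2", 243_000_000), ("chr3", 198_000_000),
    ("chr4", 191_000_000), ("chr5", 181_000_000), ("chr6", 171_000_000),
    ("chr7", 159_000_000), ("chr8", 146_000_000), ("chr9", 141_000_000),
    ("chr10", 136_000_000), ("chr11", 135_000_000), ("chr12", 134_000_000),
    ("chr13", 115_000_000), ("chr14", 107_000_000), ("chr15", 103_000_000),
    ("chr16", 90_000_000), ("chr17", 81_000_000), ("chr18", 78_000_000),
    ("chr19", 59_000_000), ("chr20", 63_000_000), ("chr21", 48_000_000),
    ("chr22", 51_000_000),
)

_BASES = np.array(list("ACGT"))
_VOCAB_SIZE = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    Defaults mirror the emulated study: nine patients, a few hundred
    germline calls and a few dozen somatic calls per exome, a driver
    gene hit in every patient, 30x mean depth and 5 kb mean marker
    spacing. ``marker_spacing_mode`` is ``"exponential"`` (Poisson
    process along the chromosome) or ``"fixed"`` (regular grid, useful
    when marker-resolution boundary accuracy is being measured).
    """

    seed: int = 0
    n_patients: int = 9
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    germline_rate: int = 500
    somatic_rate: int = 50
    fraction_synonymous: float = 0.25
    fraction_noncoding: float = 0.15
    fraction_common: float = 0.30
    driver_gene: str = "CTNNB1"
    driver_hit_probability: float = 1.0
    marker_spacing_bp: float = 5_000.0
    marker_spacing_mode: str = "exponential"
    mean_depth: int = 30
    het_truth_rate: float = 0.6
    sequencing_error: float = 0.01
    indel_fraction: float = 0.45
    roh_plants: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.genome or any(length <= 0 for _, length in self.genome):
            raise ValueError("genome must list chromosomes with positive lengths")
        for frac in (
            self.fraction_synonymous,
            self.fraction_noncoding,
            self.fraction_common,
            self.het_truth_rate,
            self.driver_hit_probability,
            self.indel_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.germline_rate < 0 or self.somatic_rate < 0:
            raise ValueError("rates must be non-negative")
        lengths = dict(self.genome)
        for chrom, start, end in self.roh_plants:
            if chrom not in lengths or not 1 <= start < end <= lengths[chrom]:
                raise ValueError(f"plant {chrom}:{start}-{end} outside genome bounds")
        if self.marker_spacing_mode not in ("exponential", "fixed"):
            raise ValueError("marker_spacing_mode must be 'exponential' or 'fixed'")


Key = tuple[str, str, int, str, str]  # (patient, chrom, pos, ref, alt)


@dataclass
class TruthLabels:
    """Ground truth emitted alongside the synthetic data."""

    origins: dict[Key, str] = field(default_factory=dict)  # germline | somatic
    consequences: dict[Key, str] = field(default_factory=dict)
    population_freqs: dict[Key, float | None] = field(default_factory=dict)
    expected_somatic_nonsilent_rare: dict[str, set[Key]] = field(default_factory=dict)
    marker_zygosity: dict[str, np.ndarray] = field(default_factory=dict)  # hom|het per marker
    roh_plants: tuple[tuple[str, int, int], ...] = ()


def _patient_ids(n: int) -> list[str]:
    return [f"Patient_{i:02d}" for i in range(1, n + 1)]


def _draw_locus(rng, genome, chrom_probs, used: set) -> tuple[str, int]:
    chroms = [c for c, _ in genome]
    lengths = dict(genome)
    while True:
        chrom = chroms[rng.choice(len(chroms), p=chrom_probs)]
        pos = int(rng.integers(1, lengths[chrom] + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _draw_alleles(rng, is_indel: bool) -> tuple[str, str]:
    anchor = str(rng.choice(_BASES))
    if not is_indel:
        alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
        return anchor, alt
    length = int(rng.integers(1, 7))
    tail = "".join(rng.choice(_BASES, size=length))
    if rng.random() < 0.5:
        return anchor, anchor + tail  # insertion
    return anchor + tail, anchor  # deletion


def _draw_consequence(rng, cfg: SimulationConfig, is_indel: bool) -> str:
    u = rng.random()
    if u < cfg.fraction_noncoding:
        return "noncoding"
    if u < cfg.fraction_noncoding + cfg.fraction_synonymous:
        return "noncoding" if is_indel else "synonymous"
    if not is_indel:
        return "missense"
    return "frameshift" if rng.random() < 0.6 else "inframe"


def _draw_freq(rng, cfg: SimulationConfig) -> float | None:
    if rng.random() < cfg.fraction_common:
        return round(float(rng.uniform(0.006, 0.2)), 6)
    if rng.random() < 0.5:
        return None  # novel allele, absent from population databases
    return round(float(rng.uniform(0.0, 0.005)), 6)


def generate_paired_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, list[VariantRecord]], dict[str, list[VariantRecord]], TruthLabels]:
    """Generate per-patient tumor and normal variant tables plus truth.

    Germline events appear in both members of a pair; somatic events in
    the tumor only. When the driver hit fires it replaces the first
    somatic event, so each tumor carries exactly
    ``germline_rate + somatic_rate`` records.
    """
    rng = np.random.default_rng(config.seed)
    lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_probs = lengths / lengths.sum()
    vocab = [f"GENE{i:03d}" for i in range(_VOCAB_SIZE)]

    tumor: dict[str, list[VariantRecord]] = {}
    normal: dict[str, list[VariantRecord]] = {}
    truth = TruthLabels(roh_plants=config.roh_plants)

    for pid in _patient_ids(config.n_patients):
        used: set[tuple[str, int]] = set()
        t_records: list[VariantRecord] = []
        n_records: list[VariantRecord] = []
        truth.expected_somatic_nonsilent_rare[pid] = set()

        driver_hit = rng.random() < config.driver_hit_probability

        for j in range(config.germline_rate + config.somatic_rate):
            somatic = j >= config.germline_rate
            is_driver = somatic and driver_hit and j == config.germline_rate
            chrom, pos = _draw_locus(rng, config.genome, chrom_probs, used)
            if is_driver:
                is_indel = False
                ref, alt = _draw_alleles(rng, False)
                consequence = "missense"
                freq = None
                gene = config.driver_gene
            else:
                is_indel = rng.random() < config.indel_fraction
                ref, alt = _draw_alleles(rng, is_indel)
                consequence = _draw_consequence(rng, config, is_indel)
                freq = _draw_freq(rng, config)
                gene = vocab[int(rng.integers(0, _VOCAB_SIZE))]
            zygosity = "hom" if rng.random() < 0.05 else "het"
            rec = VariantRecord(
                patient_id=pid,
                gene=gene,
                variant_class="indel" if is_indel else "snp",
                consequence=consequence,
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                zygosity=zygosity,
                population_freq=freq,
            )
            key: Key = (pid, chrom, pos, ref, alt)
            truth.origins[key] = "somatic" if somatic else "germline"
            truth.consequences[key] = consequence
            truth.population_freqs[key] = freq
            t_records.append(rec)
            if not somatic:
                n_records.append(rec)
            elif consequence not in ("synonymous", "noncoding") and (
                freq is None or freq <= 0.005
            ):
                truth.expected_somatic_nonsilent_rare[pid].add(key)
        tumor[pid] = t_records
        normal[pid] = n_records
    return tumor, normal, truth


def generate_marker_map(config: SimulationConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Generate an autosomal marker map with planted homozygous stretches.

    Returns a frame with columns ``chrom pos depth variant_reads`` and
    truth labels holding the per-marker truth zygosity and plant spans.
    Depths are Poisson around ``mean_depth``; variant reads are binomial
    with success probability ``1 - sequencing_error`` at homozygous
    markers and 0.5 at heterozygous markers.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthLabels(roh_plants=config.roh_plants)
    frames = []
    for chrom, length in config.genome:
        if config.marker_spacing_mode == "fixed":
            step = int(round(config.marker_spacing_bp))
            positions = np.arange(step, length + 1, step, dtype=np.int64)
        else:
            gaps = rng.exponential(config.marker_spacing_bp, size=max(16, int(2.5 * length / config.marker_spacing_bp)))
            positions = np.cumsum(gaps).astype(np.int64) + 1
            positions = positions[positions <= length]
        n = len(positions)
        if n == 0:
            continue
        in_plant = np.zeros(n, dtype=bool)
        for pchrom, start, end in config.roh_plants:
            if pchrom == chrom:
                in_plant |= (positions >= start) & (positions <= end)
        is_het = ~in_plant & (rng.random(n) < config.het_truth_rate)
        depths = rng.poisson(config.mean_depth, size=n)
        p_variant = np.where(is_het, 0.5, 1.0 - config.sequencing_error)
        reads = rng.binomial(depths, p_variant)
        truth.marker_zygosity[chrom] = np.where(is_het, "het", "hom")
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": positions, "depth": depths, "variant_reads": reads}
            )
        )
    if not frames:
        raise ValueError("configuration yields no markers")
    return pd.concat(frames, ignore_index=True), truth
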