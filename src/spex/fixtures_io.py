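"""Reading and writing of variant tables, marker tables, BED regions and
the packaged cohort fixtures.

Formats
-------
* Variant TSV: UTF-8, tab-separated, header row with the
  :class:`~spex.records.VariantRecord` field names. ``population_freq``
  left empty (or unparseable) means unknown. Extra columns are preserved
  in ``VariantRecord.extras``.
* VCF v4.x (via :mod:`cyvcf2`): one record per called sample allele;
  zygosity from GT, gene/consequence/frequency from the optional INFO
  keys ``GENE``, ``CONSEQUENCE`` and ``AF``.
* Marker TSV: columns ``chrom pos depth variant_reads``; marker VCF uses
  the DP and AD FORMAT fields.
* BED: 0-based half-open export of homozygous regions (the in-memory
  convention is 1-based inclusive), plus length and marker-count columns.

The packaged fixtures transcribe the study's printed cohort tables: the
nine patients' clinical characteristics, the 65 prominent SNP events and
the 56 indel events with their printed impact tier and functional
category. The source tables print no genomic coordinates, so fixture
rows carry deterministic placeholder positions; analyses that depend on
real coordinates (ROH mapping, indel classification against a transcript
model) run on synthetic data instead.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .records import (
    CohortTable,
    PatientMeta,
    VariantRecord,
    chromosome_sort_key,
    normalize_chromosome,
    normalize_gene,
)

__all__ = [
    "FormatError",
    "read_variant_table",
    "write_variant_table",
    "read_marker_table",
    "write_bed",
    "read_bed",
    "load_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table1_patients", "table2_snps", "table3_indels")

_VARIANT_COLUMNS = [
    "patient_id",
    "gene",
    "variant_class",
    "consequence",
    "transcript_change",
    "codon_change",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "zygosity",
    "population_freq",
]

_MANDATORY = {
    "patient_id",
    "gene",
    "variant_class",
    "consequence",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "zygosity",
}


class FormatError(ValueError):
    """An input file does not conform to the expected layout."""


def _parse_freq(raw: str | float | None) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in ("na", "nan", "unknown", ".", "none"):
        return None
    try:
        f = float(s)
    except ValueError:
        return None
    return f if 0.0 <= f <= 1.0 else None


def _records_from_frame(df: pd.DataFrame, source: str) -> list[VariantRecord]:
    extra_cols = [c for c in df.columns if c not in _VARIANT_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = dict(zip(df.columns, row))
        alleles = (str(d["ref_allele"]).strip(), str(d["alt_allele"]).strip())
        for a in alleles:
            if not a or not set(a) <= set("ACGT"):
                raise FormatError(
                    f"{source}, line {i}: allele {a!r} has characters outside ACGT"
                )
        extras = {c: d[c] for c in extra_cols if str(d.get(c, "")).strip() not in ("", "nan")}
        try:
            records.append(
                VariantRecord(
                    patient_id=str(d["patient_id"]).strip(),
                    gene=normalize_gene(str(d["gene"])) if str(d["gene"]).strip() else "unknown",
                    variant_class=str(d["variant_class"]).strip(),
                    consequence=str(d["consequence"]).strip(),
                    transcript_change=str(d.get("transcript_change", "") or "").strip(),
                    codon_change=str(d.get("codon_change", "") or "").strip(),
                    chromosome=normalize_chromosome(str(d["chromosome"])),
                    position=int(d["position"]),
                    ref_allele=alleles[0],
                    alt_allele=alleles[1],
                    zygosity=str(d["zygosity"]).strip(),
                    population_freq=_parse_freq(d.get("population_freq")),
                    extras=extras,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{source}, line {i}: {exc}") from exc
    return records


def read_variant_table(path: str | Path, dialect: str = "tsv") -> CohortTable:
    """Read a variant table from TSV or VCF into a :class:`CohortTable`.

    Records are returned in file order; the patient list is stubbed from
    the distinct patient ids encountered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = _MANDATORY - set(df.columns)
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
            )
        return CohortTable.from_variants(_records_from_frame(df, str(path)))
    if dialect == "vcf":
        return CohortTable.from_variants(_read_vcf_variants(path))
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_vcf_variants(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        gene = v.INFO.get("GENE") or "unknown"
        consequence = (v.INFO.get("CONSEQUENCE") or "other").lower()
        freq = _parse_freq(v.INFO.get("AF"))
        for alt in v.ALT:
            is_snp = len(v.REF) == 1 and len(alt) == 1
            for si, sample in enumerate(samples):
                gt_type = v.gt_types[si]  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
                if gt_type in (0, 2):
                    continue
                records.append(
                    VariantRecord(
                        patient_id=sample,
                        gene=normalize_gene(gene) if gene != "unknown" else gene,
                        variant_class="snp" if is_snp else "indel",
                        consequence=consequence,
                        chromosome=normalize_chromosome(v.CHROM),
                        position=v.POS,
                        ref_allele=v.REF,
                        alt_allele=alt,
                        zygosity="het" if gt_type == 1 else "hom",
                        population_freq=freq,
                    )
                )
    return records


def write_variant_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort's variants as a TSV that round-trips through
    :func:`read_variant_table`."""
    path = Path(path)
    extra_cols: list[str] = []
    for v in cohort.variants:
        for k in v.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_VARIANT_COLUMNS + extra_cols)
        for v in cohort.variants:
            writer.writerow(
                [
                    v.patient_id,
                    v.gene,
                    v.variant_class,
                    v.consequence,
                    v.transcript_change,
                    v.codon_change,
                    v.chromosome,
                    v.position,
                    v.ref_allele,
                    v.alt_allele,
                    v.zygosity,
                    "" if v.population_freq is None else repr(v.population_freq),
                ]
                + [v.extras.get(c, "") for c in extra_cols]
            )


def read_marker_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read exome map markers as a frame with columns
    ``chrom, pos, depth, variant_reads``."""
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = {"chrom", "pos", "depth", "variant_reads"} - set(df.columns)
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
            )
        df["chrom"] = df["chrom"].map(normalize_chromosome)
        return df[["chrom", "pos", "depth", "variant_reads"]]
    if dialect == "vcf":
        from cyvcf2 import VCF

        rows = []
        for v in VCF(str(path)):
            depths = v.format("DP")
            ads = v.format("AD")
            if depths is None or ads is None:
                continue
            depth = int(depths[0][0])
            variant_reads = int(sum(int(x) for x in ads[0][1:] if x >= 0))
            rows.append((normalize_chromosome(v.CHROM), v.POS, depth, variant_reads))
        return pd.DataFrame(rows, columns=["chrom", "pos", "depth", "variant_reads"])
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_bed(regions: Sequence, path: str | Path) -> None:
    """Write homozygous regions as BED3+2 (chrom, start, end, length_bp,
    n_markers); input must be sorted by chromosome then start."""
    keys = [(chromosome_sort_key(r.chromosome), r.start_bp) for r in regions]
    if keys != sorted(keys):
        raise ValueError("unsorted regions: sort by chromosome then start before export")
    with Path(path).open("w") as fh:
        fh.write("# chrom\tstart\tend\tlength_bp\tn_markers\n")
        for r in regions:
            fh.write(
                f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.length_bp}\t{r.n_markers}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, int, int]]:
    """Read the BED written by :func:`write_bed`; spans returned 1-based
    inclusive as ``(chrom, start_bp, end_bp, length_bp, n_markers)``."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, length, n = line.split("\t")
        out.append((chrom, int(start) + 1, int(end), int(length), int(n)))
    return out


def _fixture_path(name: str):
    return resources.files("spex").joinpath(f"data/{name}.tsv")


def load_fixture(name: str):
    """Load a packaged cohort fixture.

    ``table2_snps``/``table3_indels`` return a :class:`CohortTable`
    (indels pooled under patient_id ``cohort``, with the printed impact
    tier and functional category in ``extras``); ``table1_patients``
    returns a list of :class:`PatientMeta`.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = _fixture_path(name)
    with resources.as_file(ref) as p:
        if name == "table1_patients":
            return _load_patients(p)
        cohort = read_variant_table(p, dialect="tsv")
        if name == "table2_snps":
            # attach the clinical metadata of the nine subjects
            return CohortTable(cohort.variants, load_fixture("table1_patients"))
        return cohort


def _load_patients(path: Path) -> list[PatientMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patients = []
    for _, row in df.iterrows():
        size = row["size_mm"]
        patients.append(
            PatientMeta(
                patient_id=row["patient_id"],
                gender=row["gender"],
                age_years=int(row["age_years"]),
                size_mm=None if size in ("NA", "") else int(size),
                tnm_stage=row["tnm_stage"],
                location=row["location"],
                metastasis=row["metastasis"].strip().lower() == "yes",
            )
        )
    return patients
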