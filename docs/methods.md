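# Methods

## Data model

One variant event is a `VariantRecord`: patient, gene symbol, SNP/indel
class, functional consequence, 1-based locus, anchored ref/alt alleles
over ACGT, zygosity, and a population frequency in [0, 1] that may be
unknown. BED export converts to 0-based half-open coordinates at the
boundary; everything in memory is 1-based inclusive (VCF convention).

The packaged fixtures transcribe the study's three printed cohort
tables: nine patients' clinical characteristics, 65 prominent SNP
events, and 56 indel events with their printed impact tier and
functional category. The printed tables omit genomic coordinates, so
fixture rows carry deterministic placeholder positions; gene symbols
typeset with emphasis are stored bare, indel rows are pooled under the
patient id `cohort` because the source pools them across subjects, and
`NA`/`no abnormal` clinical values map to unknown. Anything that needs
real coordinates (transcript-model classification, homozygosity
mapping) runs on synthetic data instead, and fixture indels carry their
printed category verbatim.

## Somatic filtering

Three independent predicates applied in a fixed order: matched-normal
subtraction on the (chromosome, position, ref, alt) tuple; removal of
synonymous and non-coding calls; removal of calls with known population
frequency strictly above 0.5% (a frequency of exactly 0.5% is kept —
the rule removes *higher* frequencies — and unknown frequency is kept,
mirroring novel alleles that survive database lookup). Because each
stage is a per-record predicate, the retained set is invariant to stage
order; only the report's removal attribution depends on it (first
rejecting stage wins). No minimum depth or VAF is required for
tumor-only presence, and alleles are matched exactly — inputs are
assumed normalized (left-aligned) upstream by the caller.

## Indel classification

Alleles are VCF-anchored: a deletion removes positions
`pos+1 … pos+|ref|−1`; an insertion lands between `pos` and `pos+1`.
Decision order:

1. **Splice.** If the edit touches a donor or acceptor window — the two
   intronic bases flanking an internal exon boundary, strand-aware — the
   call is SSD/SSA (High) regardless of frame. An insertion disrupts a
   2-bp window only when it falls strictly between the two bases.
2. **CDS.** If the edit lies in coding sequence: a net length change
   that is not a multiple of 3 is a frameshift (High). In-frame edits
   split on codon alignment, computed from the reading frame accumulated
   across CDS intervals (on the − strand, offsets count from the
   genomic right): a pure insertion between two codons is CI, inside a
   codon C&I; a pure deletion of whole frame-aligned codons is CD,
   otherwise C&D (all Moderate). A complex in-frame substitution is
   binned by the sign of its net change.
3. Everything else is non-coding (Low).

The test suite checks the classifier against an independent brute-force
oracle that edits the CDS nucleotide string directly, translates before
and after with Biopython, and calls frameshift vs in-frame purely from
whether the distal protein is preserved.

## Homozygosity mapping

Marker calling and window rules use the study's thresholds as defaults
(`RohParameters`): map inclusion at ≥ 20× on autosomes; homozygous at
VAF ≥ 0.95 and ≥ 5×; heterozygous at 0.30–0.70 and ≥ 10×; everything
else ambiguous; 500-marker windows sliding one marker at a time,
qualified at ≤ 2 heterozygotes and ≤ 500 kb adjacent gaps; regions
≥ 1 Mb. Since the 20× map floor subsumes both classification depth
floors, the floors only matter for non-default parameter sets; they
remain implemented. Ambiguous markers stay in the map — they fill
window slots and gap chains but never spend the heterozygote budget.
Duplicate positions collapse to the deeper record; windows never
straddle chromosomes.

Two deliberate choices where the design was open:

* **Region trimming.** A qualified window tolerates up to 2
  heterozygous markers, so the maximal run of qualified windows can
  poke up to two (or, with ambiguous calls, a few more) markers past a
  true homozygous stretch. Emitted regions are therefore trimmed to
  their outermost homozygous-called markers: boundaries are confident
  homozygous sites, and recovered boundaries sit within the local
  marker spacing of the truth rather than two-plus spacings outside it.
* **Coalescence** merges qualified windows that overlap or touch in
  marker index; merging never crosses a disqualified stretch.

The minimum detectable run length is set by the window span (window
size × marker spacing): a window must fit inside a run for it to
qualify. The planted-recovery checks therefore use 300-marker windows
(~1.5 Mb at the 5 kb grid they simulate) against 2 Mb plants, keeping
every other parameter at its default; with the default 500-marker
window the same plants would fall below the detection floor by
construction. Recovery checks place plant edges on the marker grid so
boundary error is measured in whole marker spacings.

`oracle_scan` is a deliberately naive reference: it re-checks both
window constraints by full iteration with no incremental bookkeeping,
and the equivalence suite compares it against the vectorized scan on
exhaustive small patterns and seeded random maps.

## Group comparisons

The 2×2 construction behind the study's burden comparisons is not
uniquely determined by a per-patient count vector, so both natural
constructions are implemented and labeled: `median_dichotomy` (patients
above vs at-or-below the cohort median count, crossed with the clinical
grouping) and `pooled_events` (total events vs patient counts per
group). Neither is claimed to reproduce any published significance
level; on the packaged counts the metastatic subjects carry the two
largest burdens but neither construction reaches p < 0.05 with nine
patients. The two-sided p sums hypergeometric probabilities of all
tables with the observed margins that are no more probable than the
observed table (scipy's Fisher implementation; the test suite verifies
it against full enumeration for every table with N ≤ 40). Network hub
ranking applies a strict score threshold and breaks degree ties
alphabetically; interaction edges are user-supplied files, not live
database queries.

## Synthetic data

`SimulationConfig` defaults encode the emulated study: 9 patients, 500
germline + 50 somatic events per exome (counts are exact, not Poisson
draws, so truth-set recovery is checked without sampling slack), 25%
synonymous and 15% non-coding consequences, 30% of germline alleles
common (> 0.5%), one somatic missense hit in a CTNNB1-like driver gene
per patient with probability 1, and gene symbols from a fixed
200-symbol vocabulary so recurrence statistics are meaningful. Marker
maps default to 5 kb mean spacing at 30× (Poisson depths); spacing is
exponential by default, or a fixed grid where boundary accuracy is
being measured. Homozygous markers draw variant reads at
Binomial(depth, 0.99) — a 1% per-read error — heterozygous at
Binomial(depth, 0.5). One RNG stream per run, seeded once and consumed
in a fixed order, makes outputs byte-identical per configuration.

The generators emulate *called, annotated* variants and site-level read
counts only: no reads, no alignment artifacts, no tumor purity or
subclonality, no linkage structure between sites, and positions are
uniform rather than exome-target-shaped. Passing recovery tests
therefore demonstrates correctness of the filtering/mapping logic under
the stated noise model, not robustness to caller artifacts in real
exomes.

## Problem sizes and tolerances

The test and acceptance workloads are sized for a single CPU: window
scan vs oracle on exhaustive 8–10-marker patterns plus structured
2,000-marker and ten seeded 5,000-marker maps; planted-ROH recovery
over ten seeds on a 20 Mb chromosome (4,000 markers); the nine-patient
synthetic cohort at 550 events each; Fisher equivalence over all
~130,000 tables with N ≤ 40 (exact agreement to 1e-9 relative).
Floating-point comparisons elsewhere are exact-or-approx at 1e-9;
region coordinates and counts are compared exactly.

## Known limitations

* Fixture positions are placeholders; analyses needing real coordinates
  must come from user VCF/TSV input or the generators.
* The indel classifier assumes normalized, anchored alleles and a
  single transcript model per call; overlapping transcripts and NMD
  are out of scope, as is SNP effect prediction (SNP consequences
  arrive pre-annotated).
* Homozygosity mapping is read-count based only — no population
  allele-frequency likelihoods, no tumor–normal B-allele-frequency LOH.
* The Fisher constructions are descriptive tools for small cohorts;
  with nine subjects their power is minimal.
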