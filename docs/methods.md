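# Methods

## The problem

Shotgun sequencing of a predator's gut contents yields millions of reads,
nearly all from the predator's own genome. A small fraction — tens to
hundreds of reads per multi-million-read library — derives from ingested
organisms: prey, their parasitoids, their bacterial symbionts, plants and
fungi. `gutlink` identifies that foreign fraction without PCR by stringent
alignment against reference databases of different taxonomic resolution,
and integrates the detections into a qualitative trophic network.

The danger in this regime is false positives: with millions of host reads
and only a handful of true foreign templates, even a tiny per-read error
rate in taxon assignment swamps the signal. Every design choice below
errs on the side of discarding evidence.

## Pipeline stages

### Read quality control (`readqc`)

Reads are adapter-clipped (leftmost 3'-anchored occurrence with >= 10
aligned bases and mismatch rate <= 0.2 is removed together with everything
3' of it) and filtered on **mean** Phred quality >= 20. The mean-quality
reading of the Phred-20 criterion follows the conventional usage of the
quality-control tools this stage emulates; a per-base 3'-trimming mode is
provided as an alternative (`trim_quality_3prime`). No operation ever
alters a base call.

### Reference databases and matching policies (`refdb`)

Six databases with per-database acceptance policies:

| database            | contents                         | min identity | min overlap | E-value | search style |
|---------------------|----------------------------------|-------------:|------------:|--------:|--------------|
| `insect_mitogenome` | whole insect mitogenomes         | 98 %         | 225 bp      | 1e-5    | blastn-like  |
| `cox1_barcode`      | cox1 barcodes                    | 99 %         | 225 bp      | 1e-9    | megablast-like |
| `nuclear_genome`    | aphid nuclear genomes            | 99 %         | 225 bp      | 1e-9    | megablast-like |
| `parasitoid_markers`| parasitoid rRNA/ITS markers      | 99 %         | 225 bp      | 1e-5    | blastn-like  |
| `rrna`              | rRNA genes (all kingdoms)        | 99 %         | 225 bp      | 1e-5    | blastn-like  |
| `bacterial_genome`  | insect endosymbiont genomes      | 95 %         | 225 bp      | 1e-9    | megablast-like |

All thresholds are **inclusive** (>=): "minimum overlap of 225 bp" is read
as 225 qualifying. Overlap is measured in alignment columns (the BLAST
tabular `length` field), gaps included, not read span. At most 3 distinct
subjects are retained per read (`max_targets`), best raw score first.

Masked regions are discarded on any overlap (>= 1 bp, configurable):
mitochondrial control regions (supplied as explicit BED annotation — they
are curated knowledge, not something to infer), short sequence repeats
(SSRs, detectable automatically with `detect_ssr_regions`: maximal perfect
tandem repeats of 1–6 bp motifs totalling >= 12 bp, at least two full
copies), and shared markers. The SSR definition (motif lengths 1–6,
minimum total length 12) is this package's choice; field practice varies
and the parameters are exposed.

The rRNA database additionally carries `host_exclusion_rank = tribe`: a
hit whose subject taxon shares an ancestor with the focal predator at or
below that rank is discarded as non-diagnostic, generalising the
observation that rRNA does not separate a ladybird from its tribe-mates.
Coordinates are 0-based half-open everywhere except the BLAST outfmt-6
import/export boundary (1-based inclusive).

### Alignment (`match`)

A seed-and-extend local aligner stands in for BLASTn at desk scale:

* exact k-mer seeds, k = 12, indexed over the forward strand of every
  subject; the read and its reverse complement are both searched;
* seeds grouped per subject into diagonal clusters (diagonal jumps > 20
  start a new cluster); clusters need >= 2 seeds to be extended; the
  richest 12 clusters per read are extended (a read truly matching a
  subject at the identity levels that survive filtering shares dozens to
  hundreds of seeds, so these caps cost nothing in that regime);
* extension is an exact affine-gap local alignment (Gotoh) inside a
  diagonal band: the cluster's diagonal range widened by 30 on each side
  (full-matrix fallback when the seed diagonals span > 120). Scoring is
  blastn-like: match +1, mismatch −2, a gap of length L costs 5 + 2L;
* no query masking is performed (the "no dust" setting);
* E-values use the Karlin–Altschul form E = K·m·n·exp(−λS), with λ solved
  from Σ pᵢpⱼ e^{λsᵢⱼ} = 1 at the background base composition (uniform by
  default) and K fixed at 0.1. K is a scale constant, not fitted; only the
  E-value *ceilings* (1e-5 / 1e-9) consume it, and at these score levels
  the ceilings are insensitive to K within orders of magnitude.

Identity and overlap thresholds are deliberately **not** applied at this
stage — matching reports what aligns, filtering decides what counts. A
12-column BLAST outfmt-6 import path allows substituting real BLAST
output for the built-in aligner.

For multi-million-read libraries a prescreen avoids touching reads with
no realistic chance of a reportable hit: a read is considered against a
database only if it shares >= 4 exact 16-mers with it (union membership is
tested via a bitset over the 32-bit 16-mer space, then per database by
sorted-key lookup). A hit must ultimately cover >= 225 bp at >= 95 %
identity, which implies on the order of a hundred clean shared 16-mers,
so the prescreen is conservative by a wide margin. `align_reads` on small
inputs skips it.

### Identification (`filterid`)

Per database, in order: threshold filtering, masked-region exclusion,
host-lineage exclusion (where configured), host/foreign separation, LCA
assignment, tallying.

* Host separation: a hit is host-like if its subject taxon equals or
  descends from the focal predator. Reads with both host-like and foreign
  hits are resolved by best raw score; **ties go to host** — never claim
  prey on an ambiguous read.
* LCA assignment: all hits within 2 % of the best raw score
  (`score_tolerance = 0.98`) are treated as equally good, and the read is
  assigned to their lowest common ancestor. This automates "the lowest
  taxonomic level that can be reliably identified": reads landing in
  regions identical across related species (conserved 18S, shared
  barcode cores) resolve to genus, subfamily, superfamily or family; a
  read with a clearly separated best hit resolves to species. The 2 %
  window (≈ 5 score points on a 250-bp read, i.e. up to one extra
  mismatch plus rounding) collapses hits that differ by sequencing noise
  without collapsing hits to references ≥ 2 mismatches apart.
* A read detected in several databases is reported independently per
  database; pooling happens only in the network stage.

### Trophic network (`network`)

* **Cross-database merge**: detections of identical taxa, or of an
  ancestor/descendant pair (a genus-level barcode match alongside a
  species-level mitogenome match), collapse into the most specific taxon
  with summed read support. An ancestor with several detected descendants
  merges into the best-supported one.
* **Direct edges**: one per merged foreign insect taxon. Edges are
  intraguild when the prey's guild is a predator guild (the focal
  predators plus taxa annotated `other_predator`); guild membership is
  ecological knowledge supplied in the taxonomy table, not computed from
  reads. Parasitoid taxa resolved only above genus rank never form direct
  edges; species/genus-rank parasitoid prey (e.g. a coccinellid
  parasitoid whose DNA may reflect predation *or* parasitism of the
  predator) form direct edges annotated `role_uncertain`.
* **Inferred edges**: association rules map trigger tags
  (`aphid_specific_symbiont`, `aphid_parasitoid`) to an implied prey
  group (Aphididae). For each predator and group with at least one
  triggering detection and no direct edge into the group, one inferred
  (dashed) edge is emitted. Its support is the sum of the triggering
  *symbiont* read counts; parasitoid detections contribute evidence but
  not support. If a group were triggered by parasitoid evidence alone the
  edge would carry the parasitoid read sum instead, to keep support
  positive.
* **Summary**: the species-or-genus fraction is computed over direct
  links (family-rank prey count against it) and rounded to a whole
  percent. The pooled species/genus linked-taxa count deduplicates,
  across predators: direct prey at species/genus rank, parasitoid-database
  detections at species/genus rank, and detected taxa bearing a symbiont
  rule tag. Whether symbiont taxa belong in that count is a judgement
  call; this package includes them and documents it here.

## The synthetic data generator (`synthetic`, `profiles`)

Because the survey's raw libraries are not public, every read-level claim
is anchored on simulation with known truth. The generator emulates:

* a dominant host nuclear background (the overwhelming majority of reads
  align to nothing);
* host mitochondrial DNA at the per-library observed fraction
  (0.07–0.8 % of reads);
* foreign members at per-taxon read fractions equal to the survey's
  detected counts over its library depth — tens to hundreds of reads per
  multi-million-read library;
* 250 bp single-end reads; substitution-only errors at 0.2 % per base
  with Phred strings consistent with the rate (q ≈ 27 ± 2); 1 % of reads
  are low-quality (mean q ≈ 12) and are removed by QC; an indel toggle
  exists but is off by default;
* degraded foreign DNA: templates from a truncated normal (mean 120 bp,
  sd 40, hard max 200) yield reads shorter than the read length. Because
  a detection requires a 225 bp alignment, these reads are *never*
  detectable — which is exactly the low-recovery regime of gut-content
  sequencing. Conversely, the foreign reads that *were* detected in the
  survey aligned over >= 225 bp, so the detected fraction of ingested DNA
  was necessarily near full read length. The named profiles therefore
  give each detectable foreign member full-length templates plus a 3x
  larger degraded companion fraction that yields nothing.

Reference relatives are generated at controlled divergences straddling
the identity thresholds: coccinellid mitogenomes ~11 % apart (no
cross-species leakage at 98 %), a cryptic coccinellid 5 % from its
nearest reference (invisible at 98 %, detected — wrongly, and
instructively — at 90 %, reproducing the direction of the published
identity-threshold sensitivity comparison), congeneric aphids ~6 % apart,
two *Serratia* genomes 10 % apart across the 95 % bacterial threshold.
Group-level assignment is emulated with conserved marker cores: several
reference species share an identical 18S/ITS core while their flanks
diverge at 35 % (with forced substitutions at the core boundary so
alignments leaving the core immediately pay mismatches in every variant);
reads from an unreferenced source carrying the same core tie across the
references and resolve to the group's common ancestor. The host nuclear
genome embeds an rRNA cassette nearly identical to the Coccinellini rRNA
references, exercising the host-lineage exclusion on real host reads.

Deliberately not modelled: GC bias, PCR duplicates, flow-cell artifacts,
chimeras, paired-end geometry, post-ingestion decay dynamics (decay enters
only through the read fractions), and real genome repeat structure (host
genomes are i.i.d. random at 300 kb, scaled from hundreds of Mb — this
understates spurious seed hits from repeats, which the masked-region and
overlap rules would absorb, and makes per-read detection slightly cleaner
than reality). Passing the round-trip therefore shows the pipeline's
logic is sound under its stated assumptions, not that real libraries are
free of contamination or reference-database gaps.

## Problem sizes and determinism

Simulated libraries run at one million reads each (four predators plus
the unfed control) — the same order as, and roughly 40 % of, the survey's
per-library depth, preserving the foreign-read frequencies. All
randomness flows from a single integer seed through
`numpy.random.default_rng` streams; identical scenario and seed give
byte-identical FASTQ.

## Known limitations

* The built-in aligner targets desk-scale reference sets (megabases); it
  is not a BLAST replacement for nucleotide databases at NCBI scale. The
  outfmt-6 import path exists for that case.
* Karlin–Altschul K is a fixed constant rather than computed from the
  scoring system; E-values are therefore calibrated only up to a constant
  factor (the thresholds they serve are orders-of-magnitude tests).
* Read counts support edges qualitatively; no abundance or biomass
  inference is attempted, and none should be read into the support
  numbers.
* The LCA tolerance (0.98) and the SSR definition are package defaults
  standing in for manual curation steps; both are configurable.
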