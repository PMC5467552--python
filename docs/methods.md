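# Methods

## The problem

Genome annotation is exchanged as GFF, and real-world GFF is messy:
providers split one CDS over several lines sharing an ID, omit IDs from
CDS lines entirely, omit exon lines, omit gene records, ship GTF-style
files whose `gene_id`/`transcript_id` attributes never materialise as
parent features, disagree about what the phase column means, and
hand-edit the protein FASTA that accompanies the annotation. A strict
parser rejects such files; a silently lenient parser hides what it fixed.
gffmend takes a third route: parse everything, log every deviation as an
issue, and repair only what an explicit, ordered rule list says to
repair, recording each modification so the import is replayable.

## Data model

Coordinates are 1-based closed everywhere (the convention shared by GFF3
and EMBL flat files); exporters convert internally where needed. A
`Feature` owns one or more `(seq_id, start, end, strand)` segments with
per-segment phase — more than one only for multiline features. Feature
types are lower-cased for matching (`CDS` ≡ `cds`) with original casing
kept for output. The `FeatureGraph` holds parent edges (kept acyclic by
construction), *deferred* parent references — IDs that were named but not
(yet) defined, covering both forward references and GTF transcript links
— an ordered issue log, and an append-only provenance list.

Strand `.` is permitted on non-transcript features only; a CDS or
transcript line with `.` strand is quarantined as an error, since its
translation direction would be undefined.

## The repair rule language

Rules live in INI files as `CONDITION_n` keys and come in three kinds:

* `[MULTILINE <type>]` — merge same-ID provisional features of that type
  into one multi-segment feature (segments sorted by start, phases kept
  with their segments). Merging is unconditional for the named type;
  features on mixed scaffolds/strands are left alone with an
  `unmergeable` issue.
* `[LACKS_ID <type> make]` — mint IDs: `<parentID>.<type>.<n>` with `n`
  numbering same-type siblings in transcription direction, or
  `<type>.<seq_id>.<start>` for parentless features.
* `[EXPECTATION <type> hasParent|hasSister <alt1|alt2|…> force|warn|ignore]`
  — structural checks. `hasSister` passes when every segment of the
  subject is contained in a segment of a same-parent sibling of a listed
  type (the biological containment of CDS within exons; the check itself
  is a design choice, as containment is the only reading under which
  repair is exact). `force` synthesises what is missing; `warn` logs;
  `ignore` does nothing.

Rules apply strictly in numeric `CONDITION_n` order; no kind-based
reordering is imposed. After each rule, deferred references are
re-resolved. This ordering interplay is what makes CDS-only GTF input
repairable by the stock rule list: the `hasSister exon force` rule runs
while the CDS still lacks a real parent, so synthesised exons share the
CDS's deferred transcript reference; the subsequent `hasParent mrna
force` rule materialises **one** mRNA per referenced transcript ID
(grouping all children that name it, span = their envelope) rather than
one per CDS line; resolution then attaches the exons, and the gene-level
rule caps the hierarchy. A feature with neither a parent nor a deferred
reference genuinely lacks context for sister synthesis and degrades to a
warning (`unforceable`).

Synthesised parents take the referenced ID when one exists, else
`<childID>.<type>`; they carry only an ID attribute. Repairs never
delete input features — they add, merge or re-link — and every
modification is appended to provenance. A second pass with the same
rules performs zero modifications (idempotence, enforced by test).

When several existing features could serve as a referenced parent, the
child attaches to the one whose span minimally contains it, then first
by declaration order, with a warning.

## Naming

Extraction patterns `[selector->attribute/regex/]` (optional leading
ordinal, optional trailing `/match/replacement/`) pull stable IDs, names
and descriptions out of whichever attribute a provider used. The
selector is `SELF`, `PARENT`, `DAUGHTER` (ordinal = position in
coordinate order — file order would make output depend on input
shuffling) or a type token meaning nearest ancestor-or-self of that
type. `/` is the only delimiter; a literal slash in a regex is escaped
`\/`. Multi-valued attributes contribute their first value. Within a
section, the first pattern that yields a value wins; permuting patterns
that never both match leaves output unchanged. Duplicate stable IDs get
deterministic `_2`, `_3` suffixes plus an issue. Lookup tables built
from FASTA headers or two-column text files fill names/descriptions,
keyed on the stable ID after the same match/replace normalisation so
gene/transcript/protein ID variants join.

## Verification

CDS assembly sorts segments ascending on `+`, descending on `-` with
each segment reverse-complemented, concatenates, and removes the first
segment's phase (in transcription order) from the 5' end. Phase is read
the GFF3 way — bases to remove to reach the next codon boundary — not as
a reading frame; that distinction is exactly why the phase-shift
classifier exists. Translation uses the standard genetic code (table 1,
overridable): internal stops render `*`, one terminal stop is stripped,
trailing partial codons are dropped with an issue.

`verify_translations` set-compares IDs, then compares shared sequences
exactly. Mismatches are classified in this order:

1. `stop_truncation` — expected equals the prediction cut at its first
   internal stop (an expected file hand-edited to stop early);
2. `phase_shift` — re-translating the stored raw CDS with first-segment
   phase forced to 0, 1 and 2 reproduces the expected protein;
3. `other`.

Gene-set quality finds each gene's canonical transcript (longest summed
CDS; ties to the lexicographically smallest stable ID), counts genes
whose canonical transcript has exactly one exon segment, and intersects
with a domain-hit table (InterProScan-style TSV, column 1 only, presence
or absence). Percentages are rounded half-up to integers, which
reproduces the published figures for both example gene-set compositions
(21 493 genes: 5340 → 25%, 3251 → 15%; 13 920 genes: 1711 → 12%,
673 → 5%). Genes with no coding transcript are excluded from the total
with an info issue.

## Exporters

GFF3 output is sorted (scaffold, start, parent before child), multiline
features re-emitted one line per segment sharing the ID, and reserved
characters percent-encoded; a parse → repair → write → parse cycle is
structure-preserving. EMBL records (one per scaffold, no CON records)
follow ENA conventions: 80-column lines, `join(…)`/`complement(…)`
locations, `/codon_start` = first-segment phase + 1, `/translation`
recomputed from the graph at write time — if an expected-protein map is
supplied and disagrees, the record is refused rather than written wrong.
Record construction and formatting go through Biopython's SeqRecord and
EMBL writer; the data-class slot of the ID line, which that writer
leaves blank, is filled in (STD by default, configurable). A syntactic
validator (line lengths, ID-line shape, recursive location grammar,
codon_start range, SQ base count) guards the output in tests.

Assembly statistics: N50 (N90) is the length of the shortest sequence
in the smallest descending-sorted prefix whose sum reaches 50% (90%) of
the span; GC is computed over unambiguous bases only, N content over all
bases. Codon usage reads CDS in frame 0, drops trailing partial codons,
skips ambiguous codons, and reports counts, global frequencies and
per-synonymous-family shares. Both are exported as JSON; schemas ship in
`src/gffmend/data/`.

## Synthetic data

The generator is first-class, tested code, and its defaults define the
conditions under which everything else is validated: 5 scaffolds × 20
genes (tests scale this up or down explicitly), CDS of 50–200 codons
(ATG start, no internal stop, one terminal stop), 1–5 exons, introns of
40–200 bp, intergenic gaps of 60–300 bp, a deterministic 25%
single-exon allocation (exact count, not sampled), alternating strands
(50% minus), 80% of genes given a synthetic domain hit, ACGT alphabet
with optional N runs. Same seed ⇒ byte-identical output.

Two deliberate simplifications make repair-recovery *exact*: exon
coordinates coincide with CDS segments (no UTRs) and each gene has one
transcript spanning the gene, so a repair that rebuilds exons from CDS
or genes from transcripts lands on the truth coordinates. Real
annotations have UTRs, alternative isoforms, non-coding genes and
overlapping loci; passing the recovery suite therefore demonstrates the
repair *mechanics*, not that arbitrary real files round-trip losslessly.
Nucleotide composition is uniform — no codon bias, repeats or realistic
GC landscape — so codon-usage output is exercised numerically, not
biologically.

The corruptor records a manifest mapping every edit to the truth.
Repaired graphs are compared to truth by a coverage signature: per
feature class, merged base coverage per (scaffold, strand), plus gene
and transcript counts. Coverage rather than raw segment lists is the
right oracle because legitimate repairs change granularity without
changing annotated bases (GTF repair yields several single-segment CDS
features instead of one multiline feature; `split_multiline_cds` splits
a segment at a codon-internal point). Two modes need a word:

* `phase_as_frame` recomputes phases cumulatively in ascending
  coordinate order, strand ignored — only minus-strand multi-exon
  transcripts change. Since only the first transcription-order phase is
  consumed during assembly, injections that leave it unchanged would be
  provably undetectable and are skipped rather than counted.
* `truncate_expected_at_stop` needs a prediction containing an internal
  stop to be observable, so it makes a paired edit: one internal CDS
  codon (never straddling a segment boundary) is rewritten to TAA in
  the genome copy, and the expected protein is truncated at that
  residue. Gene coordinates are untouched. A transcript receives at
  most one of the two translation-level modes so every injection has a
  single expected classification.

## Numerical and degenerate-input choices

* Percentages: round-half-up in exact integer arithmetic
  (`(200·c + t) // (2·t)`), avoiding float edge cases.
* Empty assembly → error; empty CDS set → all-zero codon counts with
  frequencies flagged zero rather than NaN.
* Missing CDS phase → treated as 0 with a `missing_phase` warning.
* Genetic code: NCBI table 1 by default, parameterised.
* Tie-breaks (canonical transcript, ambiguous parents, duplicate stable
  IDs) are all lexicographic/ordinal and therefore deterministic; two
  runs on identical inputs produce byte-identical artifact directories
  (no timestamps are written).

## Problem sizes used in the checks

The repair-recovery suite runs 50 seeded genomes of ~100 genes each
against every structural corruption mode and the all-modes combination;
the translation suite uses 10 genomes of 40 genes; statistic oracles use
1000 random length lists; round-trip checks use 3 genomes. These sizes
give hundreds of independent injections per defect class while keeping
the whole suite fast to iterate on.

## Known limitations

* One transcript per generated gene; alternative splicing is parsed and
  handled by the graph but not exercised by the generator.
* The rule language does not act on attribute values (beyond ID
  presence) and has no score/strand repair rules.
* EMBL export targets ENA syntactic conventions; it has not been run
  through ENA's own validator.
* Remote `[FILES]` URLs are fetched and cached with checksums, but all
  shipped workflows operate on local files.
* Circular sequences, AGP assembly hierarchies and multi-scaffold
  features are out of scope; a feature spanning scaffolds is an error.
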