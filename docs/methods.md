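# Methods

## Editor model

An editor configuration is `(edit_from, edit_to, pam, pam_side,
spacer_length, window, safety)`. Protospacer positions are numbered
1..`spacer_length` from the spacer's 5′ end, PAM-distal for a 3′ PAM such as
NGG — the dominant convention when editing windows are quoted as "4–8".
Deamination acts on the protospacer-containing strand, so each editor
induces two plus-strand channels: `edit_from→edit_to` for plus-strand
guides, `complement(edit_from)→complement(edit_to)` for minus-strand guides.

Two presets ship: `ABE` (A→G) and `CBE` (C→T), both NGG / spacer 20 /
window 4–8 / safety 3–10. Window 4–8 and safety 3–10 are this package's
defaults for the classic NGG editors; published editors vary, so every
field is an overridable plain parameter (`--window`, `--safety`, `--pam`,
`--edit X>Y`). Editors carry a single from→to pair; dual-deaminase editors
and position-dependent efficiency weights are out of scope. 5′-PAM editors
are representable via `pam_side` but no 5′-PAM preset is shipped.

## Scanning and window profiling

`find_protospacers` enumerates every protospacer+PAM match on both strands
whose full protospacer+PAM lies inside the queried interval (region mode is
defined by containment: the region is extracted, then scanned). Candidates
containing non-ACGT bases (including N) are dropped; the bases themselves
are retained on fetch. Output ordering is deterministic:
`(chrom, guide_start, strand, editor)`.

A guide's profile lists every `edit_from` occurrence on the protospacer
strand within the safety region, expressed as a plus-strand genomic change
via the guide's channel. In-window edits form the committed set;
safety-only edits are annotated as "possible" and never enter codon
calculus or the editing/non-editing partition. The window center for an
even-width window is the half-integral midpoint (w₁+w₂)/2, so distances to
center may end in .5 — this avoids an arbitrary tie-break between the two
central positions.

Identical spacer sequences at different loci are distinct records;
deduplication by sequence is left to downstream tooling.

## Coordinates and annotation

All coordinates are 1-based inclusive (GTF/Ensembl convention); region
strings accept hyphen or en-dash. Contig names are matched exactly between
FASTA and GTF, and a vocabulary mismatch raises an error listing both
sides. GTF parsing is Ensembl-dialect (attribute keys `gene_name`,
`transcript_name`, `transcript_id`, `tag`); GFF3 and RefSeq dialects are
not supported. Because Ensembl GTFs exclude the stop codon from CDS
features, annotated `stop_codon` intervals are merged into the transcript's
CDS at load time (abutting intervals coalesce), so the CDS runs through the
stop and stop-lost edits are designable; fixtures that already include the
stop in CDS pass through unchanged.

A bare gene name resolves to its default transcript: the
`Ensembl_canonical`-tagged transcript, then `MANE_Select`, then the longest
CDS, ties broken by lexicographic transcript id. Spliced-CDS validation
(starts with ATG, no internal stop) warns rather than errors, since real
annotations contain exceptions.

## Variant mode

Notations are auto-detected: `chrom_pos_ref_alt`, `rs\d+`, or
`GENE[-NNN]-XnY` (gene names may themselves contain hyphens; the transcript
suffix is recognized when the penultimate dash-separated token is all
digits). rsID resolution is strictly local against a user-supplied VCF —
no network lookup — and expands multi-allelic records to one spec per SNV
allele, skipping non-SNV alleles with a report; an rsID mapping to several
contigs emits all of them for the user to filter. Protein substitutions are
reverse-translated by trying each of the three codon bases against both
strand channels and keeping single-base changes whose mutated codon
translates to the target; an unreachable substitution returns a
machine-readable `unreachable` status rather than an error.

A guide qualifies for a coordinate variant when its window covers the
position and its channel performs the requested plus-strand change. Guides
are reported even when bystander edits exist (`--specific-only` filters
them); guides achieving the edit only in the safety region are counted per
spec but excluded from the table. A reference-base mismatch is an error for
that spec while other specs in the batch proceed.

## Gene mode and consequences

The gene-mode candidate space is every protospacer whose editing window
overlaps the transcript's CDS segments extended 2 nt into each flanking
intron — the extension captures the canonical splice dinucleotides without
admitting extra UTR-only positions (a segment side is extended only where
it coincides with an exon boundary that faces an intron). Whether the
original tool requires window overlap or full containment in the CDS is
not documented anywhere we could rely on; window-overlap-plus-splice-margin
is this package's documented choice.

Consequences: `synonymous` (amino acid unchanged), `missense`, `nonsense`
(stop gained), `stop_lost`, `start_lost` (codon 1 changed away from ATG;
alternative initiation is not modeled), `splice_site` (edit in the 2-nt
donor/acceptor dinucleotide of an intron adjacent to a CDS-containing exon,
regardless of the reference dinucleotide's identity), `intronic`, `utr`,
`intergenic`. Classification uses the standard codon table and is total:
every in-window edit receives exactly one class. When several in-window
edits hit one codon, the combined codon reflects all of them and is
classified jointly; combined and single-edit classes are both reported.

Summary tallies are emitted two ways because they answer different
questions: `unique_edit_consequences` counts each distinct
(position, ref, alt, transcript) edit once however many guides induce it
(the natural breakdown of a library's mutational coverage), while
`guide_edit_consequences` counts guide–edit pairs. Both are recomputable
from the tables.

When a guide overlaps several requested transcripts, one report row is
produced per (guide, transcript) pair sharing the guide's identity key.

## Synthetic fixtures and the oracle

`make_fixture(seed, ...)` writes a mini-genome (a few kb): genes of 30–60
codons on alternating strands, 3 exons each with GT..AG introns, 15–30 nt
UTRs inside terminal exons, start/stop codons annotated, one extra
non-canonical transcript on the first gene, and four planted rsID records
(one A>G, one C>T, one multi-allelic, one non-SNV insertion). Regeneration
with the same seed is byte-identical. The defaults are sized so a full
gene-mode run stays well under a second while still containing every
consequence class, double-hit codons, and minus-strand genes.

The truth table shipped with a fixture is computed at construction time by
`oracle_scan` — an intentionally naive enumeration that checks every
offset on both strands and tests the PAM character by character — plus a
naive whole-CDS classification that re-derives codons directly from the
planted CDS string. Neither shares code with the engine, so truth-recovery
tests are genuinely dual-route.

What the fixtures do not emulate: real intron length distributions, GC
content and repeat structure, overlapping genes, multi-isoform complexity
beyond one extra transcript, and reference-quality chromosome sizes.
Passing tests therefore demonstrate coordinate and classification
correctness, not performance or annotation-edge-case coverage on full
genomes (gene-scale runs on a real reference are minutes, not tested
here).

## Numerical and degenerate-input choices

* Intervals shorter than spacer+PAM return an empty candidate list with a
  warning, not an error.
* Empty GTF → empty transcript index; a transcript with contradictory CDS
  strands is an error.
* `filter_by_consequence` with an empty wanted set empties the editing
  table; the non-editing table survives filtering only when `non_editing`
  is explicitly requested.
* Exit codes: 0 success, 1 usage/input error, 2 reference/annotation
  inconsistency. All engine paths are deterministic — identical inputs and
  flags give byte-identical outputs.

## Acceptance computation

`scripts/acceptance.py --seed N --out path.json` regenerates the bundle
from the seed and recomputes: engine/oracle agreement on 500 random 200-nt
sequences × 2 editors (expected 100%), the exhaustive 64-codon × 3-position
× 4-channel consequence matrix (expected 100%), gene/region/variant-mode
guide counts with their planted-truth agreement, the unique-edit
consequence breakdown, and partition-conservation violations (expected 0).
Problem sizes (4 genes, ~3.5 kb genome, 500 random sequences) are chosen to
exercise every code path while keeping the whole script a few seconds.
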