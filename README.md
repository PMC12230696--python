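# bedesign

Design and annotate single-guide RNA (sgRNA) libraries for CRISPR base-editing
screens.

Base editors (BEs) convert one base pair into another without double-strand
breaks: a cytosine base editor (CBE) converts C•G→T•A, an adenine base editor
(ABE) converts A•T→G•C. Pooled BE screens need guide libraries ranging from a
handful of guides installing pre-specified variants up to near-saturation
libraries tiling a whole coding sequence. `bedesign` covers the three standard
use cases:

* **variant mode** — find every guide that installs a given variant, accepted
  as a coordinate string (`12_6537866_C_T`), a dbSNP rsID resolved against a
  local VCF (`rs1062436`), or protein notation (`GAPDH-L270F`,
  `GAPDH-201-L270F`), with protein substitutions reverse-translated to the
  single-base codon edits that achieve them;
* **gene mode** — a near-saturation library over the coding sequence of named
  genes or transcripts (canonical splice dinucleotides included);
* **region mode** — all guides within an arbitrary genomic region
  (`19:44905791-44909393`).

## Model

A base editor is parameterized by its edit channel (`edit_from`→`edit_to` on
the protospacer strand), an IUPAC PAM pattern (e.g. `NGG`), spacer length
*L* (default 20), an **editing window** [w₁, w₂] of protospacer positions
(numbered 1 at the 5′, PAM-distal end; default 4–8), and a wider **safety
region** [s₁, s₂] ⊇ [w₁, w₂] (default 3–10). Every occurrence of
`edit_from` inside the window is treated as edited (the committed set);
occurrences in the safety region outside the window are annotated as
possible low-efficiency edits but not committed. Each editor induces two
strand-resolved channels on the plus strand — a CBE acts as C→T via
plus-strand guides and G→A via minus-strand guides.

A guide is *editing* if its window contains ≥ 1 editable base, *specific* if
exactly one (a second in-window edit is a *bystander*). All in-window edits
are mapped through the spliced CDS to codons; edits hitting the same codon
are applied jointly, and consequences are classified as synonymous /
missense / nonsense / stop_lost / start_lost / splice_site (the canonical
2-nt donor/acceptor dinucleotides) / intronic / UTR / intergenic. Filtering
by consequence yields screen controls: synonymous or non-editing guides as
negative controls, nonsense or splice-disrupting guides as positive controls.

## Worked example

`bedesign` ships a seeded synthetic genome generator, so a complete run needs
no external downloads:

```sh
bedesign make-fixture --seed 3 --out demo/
bedesign gene --genes ALPHA --genome demo/fixture.fa --gtf demo/fixture.gtf \
    --editor ABE --editor CBE --output demo/alpha.tsv --include-non-editing
```

prints

```
guides designed: 46 (editing 36, non-editing 10, specific 19)
unique-edit consequences: missense=32, nonsense=1, synonymous=21
```

meaning the ALPHA coding sequence admits 46 NGG guides whose editing window
touches the CDS: 36 make at least one edit (19 exactly one), 10 bind without
editing (useful as binding controls), and the 54 distinct edits break down
into 32 missense, 1 nonsense, and 21 synonymous changes. The table holds one
row per guide:

```
editor  strand  guide_start  spacer_seq            n_edits_window  specific  edits                    codon_alt  aa_ref  consequence
ABE     -       414          CGTGAAACTATCATATTCAC  3               False     429:T>C;428:T>C;427:T>C  GCC;CCA    V;S     missense;missense
CBE     -       414          CGTGAAACTATCATATTCAC  1               True      426:G>A                  ATT        V       missense
ABE     +       426          GTTTCACGTTGCGCACATGT  1               True      431:A>G                  TCG        S       synonymous
```

The first row shows bystander accounting: one ABE guide commits three
in-window T>C edits hitting two codons, and the two codon changes are
reported jointly. The same API is available in Python
(`bedesign.design_gene`, `design_region`, `design_variants`,
`filter_by_consequence`).

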