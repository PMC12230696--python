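"""Variant mode: parse variant notations, resolve them, design guides.

Three input notations are auto-detected:

* coordinate strings — ``"12_6537866_C_T"`` (chrom_pos_ref_alt);
* dbSNP rsIDs — ``"rs1062436"``, resolved against a local VCF;
* protein notation — ``"GAPDH-L270F"`` or ``"GAPDH-201-L270F"``
  (gene or transcript name plus a one-letter amino-acid substitution).

Protein-level variants are reverse-translated: for each of the three
codon bases and each of the editor's two strand channels, a single-base
substitution producing the target amino acid is converted to genomic
coordinates. Guide design then finds every protospacer whose main
editing window covers the variant position with the matching channel.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pysam

from .editor_model import BaseEditorConfig, edit_channels
from .reference_io import (
    CODON_TO_AA,
    ReferenceGenome,
    TranscriptIndex,
    complement_base,
    spliced_cds,
)
from .scan_core import (
    GuideReport,
    LibraryResult,
    find_protospacers,
    window_profile,
)

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY*")


@dataclass(frozen=True)
class VariantSpec:
    """One requested variant, in any of the three notations."""

    source: str  # "coordinate" | "rsid" | "protein"
    original_input: str
    chrom: str | None = None
    pos: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None
    rsid: str | None = None
    name: str | None = None  # gene or transcript name (protein notation)
    aa_ref: str | None = None
    aa_pos: int | None = None
    aa_alt: str | None = None


_COORD_RE = re.compile(r"^([\w.]+)_(\d+)_([A-Za-z])_([A-Za-z])$")
_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_AA_SUB_RE = re.compile(r"^([A-Za-z*])(\d+)([A-Za-z*])$")


def parse_variant_input(text: str) -> VariantSpec:
    """Auto-detect and parse one variant string.

    >>> parse_variant_input("12_6537866_C_T").pos
    6537866
    >>> parse_variant_input("GAPDH-201-L270F").name
    'GAPDH-201'
    >>> parse_variant_input("rs1062436").source
    'rsid'
    """
    text = text.strip()
    if not text:
        raise ValueError("empty variant string")
    m = _COORD_RE.match(text)
    if m:
        chrom, pos, ref, alt = m.groups()
        ref, alt = ref.upper(), alt.upper()
        if ref not in "ACGT" or alt not in "ACGT":
            raise ValueError(f"non-base ref/alt in {text!r}")
        if ref == alt:
            raise ValueError(f"ref equals alt in {text!r}")
        return VariantSpec(
            source="coordinate", original_input=text,
            chrom=chrom, pos=int(pos), ref_base=ref, alt_base=alt,
        )
    if _RSID_RE.match(text):
        return VariantSpec(source="rsid", original_input=text, rsid=text.lower())
    # protein notation: GENE[-TRANSCRIPTNUM]-XnY; gene names may contain "-"
    parts = text.split("-")
    if len(parts) >= 2:
        m = _AA_SUB_RE.match(parts[-1])
        if m:
            aa_ref, aa_pos, aa_alt = m.groups()
            aa_ref, aa_alt = aa_ref.upper(), aa_alt.upper()
            if aa_ref not in _AA_LETTERS or aa_alt not in _AA_LETTERS:
                raise ValueError(f"invalid amino-acid letter in {text!r}")
            if aa_ref == aa_alt:
                raise ValueError(f"amino-acid ref equals alt in {text!r}")
            if int(aa_pos) < 1:
                raise ValueError(f"amino-acid position must be >= 1 in {text!r}")
            name = "-".join(parts[:-1])
            return VariantSpec(
                source="protein", original_input=text, name=name,
                aa_ref=aa_ref, aa_pos=int(aa_pos), aa_alt=aa_alt,
            )
    raise ValueError(
        f"unrecognized variant notation {text!r}; expected chrom_pos_ref_alt, "
        "rsID, or GENE[-TRANSCRIPT]-XnY"
    )


def resolve_rsid(spec: VariantSpec, vcf_path: str | Path) -> list[VariantSpec]:
    """Resolve an rsID against a local VCF into coordinate specs.

    One spec is emitted per single-nucleotide ALT allele of every record
    whose ID matches (multi-allelic records expand; an rsID on several
    contigs emits all of them). Non-SNV alleles are reported and skipped.
    """
    if spec.source != "rsid":
        raise ValueError(f"not an rsid spec: {spec.original_input!r}")
    out: list[VariantSpec] = []
    found = False
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.id is None or rec.id.lower() != spec.rsid:
                continue
            found = True
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and rec.ref != alt:
                    out.append(
                        VariantSpec(
                            source="coordinate",
                            original_input=spec.original_input,
                            chrom=rec.chrom, pos=rec.pos,
                            ref_base=rec.ref.upper(), alt_base=alt.upper(),
                        )
                    )
                else:
                    warnings.warn(
                        f"{spec.rsid}: allele {rec.ref}>{alt} is not a SNV; skipped"
                    )
    if not found:
        raise KeyError(f"rsID {spec.original_input!r} not found in {vcf_path}")
    return out


@dataclass
class ProteinEditResult:
    """Outcome of reverse-translating a protein variant."""

    edits: list[VariantSpec]
    status: str  # "ok" | "unreachable"
    transcript_name: str = ""


def protein_to_edits(
    spec: VariantSpec,
    transcripts: TranscriptIndex,
    genome: ReferenceGenome,
    editor: BaseEditorConfig,
) -> ProteinEditResult:
    """Find single-base codon edits installing an amino-acid substitution.

    For each of the three codon positions and each strand channel of the
    editor, the single substitution is applied in silico; edits whose
    mutated codon translates to the target amino acid are emitted as
    genomic coordinate specs. An empty list with status "unreachable"
    means the substitution cannot be installed by this editor.
    """
    if spec.source != "protein":
        raise ValueError(f"not a protein spec: {spec.original_input!r}")
    transcript = transcripts.resolve(spec.name)
    cds = spliced_cds(transcript, genome)
    n_codons = len(cds.seq) // 3
    if not (1 <= spec.aa_pos <= n_codons):
        raise ValueError(
            f"{spec.original_input}: amino-acid position {spec.aa_pos} outside "
            f"CDS of {transcript.transcript_name} ({n_codons} codons)"
        )
    ref_codon = cds.codon(spec.aa_pos)
    if CODON_TO_AA.get(ref_codon) != spec.aa_ref:
        raise ValueError(
            f"{spec.original_input}: reference codon {ref_codon} encodes "
            f"{CODON_TO_AA.get(ref_codon)}, not {spec.aa_ref}"
        )
    channels = edit_channels(editor)
    edits: list[VariantSpec] = []
    for offset in range(3):
        cds_pos = 3 * (spec.aa_pos - 1) + 1 + offset
        chrom, gpos, strand = cds.cds_to_genome[cds_pos]
        codon_base = ref_codon[offset]  # transcript orientation
        plus_ref = codon_base if strand == "+" else complement_base(codon_base)
        for channel in channels:
            if plus_ref != channel.ref:
                continue
            new_base = (
                channel.alt if strand == "+" else complement_base(channel.alt)
            )
            alt_codon = ref_codon[:offset] + new_base + ref_codon[offset + 1 :]
            if CODON_TO_AA.get(alt_codon) == spec.aa_alt:
                edits.append(
                    VariantSpec(
                        source="coordinate",
                        original_input=spec.original_input,
                        chrom=chrom, pos=gpos,
                        ref_base=plus_ref, alt_base=channel.alt,
                    )
                )
    status = "ok" if edits else "unreachable"
    return ProteinEditResult(edits, status, transcript.transcript_name)


def _annotation_transcript(
    transcripts: TranscriptIndex | None, chrom: str, pos: int
):
    """Default transcript whose span covers pos, if any."""
    if transcripts is None:
        return None
    covering = [
        t
        for t in transcripts
        if t.chrom == chrom and t.span[0] <= pos <= t.span[1]
    ]
    if not covering:
        return None
    genes = sorted({t.gene_name for t in covering})
    for gene in genes:
        pick = transcripts.resolve(gene)
        if pick in covering:
            return pick
    return sorted(covering, key=lambda t: t.transcript_id)[0]


def design_variants(
    specs: Sequence[VariantSpec | str],
    genome: ReferenceGenome,
    transcripts: TranscriptIndex | None,
    editor: BaseEditorConfig,
    dbsnp_vcf: str | Path | None = None,
) -> LibraryResult:
    """Design all guides that install each requested variant.

    rsID and protein specs are resolved to coordinate specs first. A
    guide qualifies when its main editing window covers the variant
    position and its strand channel performs the requested plus-strand
    change; each qualifying guide carries its full window profile so
    bystander edits stay visible. Guides achieving the edit only in the
    safety region are excluded from the table but counted per spec.

    Per-spec outcomes land in ``result.statuses`` keyed by the original
    input string; a reference-base mismatch is an error for that spec
    while the remaining specs proceed.
    """
    from .consequence import annotate_guide, summarize

    result = LibraryResult()
    coordinate_specs: list[VariantSpec] = []
    for item in specs:
        spec = parse_variant_input(item) if isinstance(item, str) else item
        key = spec.original_input
        try:
            if spec.source == "rsid":
                if dbsnp_vcf is None:
                    raise ValueError(
                        f"{key}: rsID input requires a dbSNP VCF (--dbsnp)"
                    )
                coordinate_specs.extend(resolve_rsid(spec, dbsnp_vcf))
            elif spec.source == "protein":
                if transcripts is None:
                    raise ValueError(
                        f"{key}: protein input requires a gene annotation"
                    )
                res = protein_to_edits(spec, transcripts, genome, editor)
                if res.status == "unreachable":
                    result.statuses[key] = {
                        "status": "not achievable", "n_guides": 0,
                        "transcript": res.transcript_name,
                    }
                coordinate_specs.extend(res.edits)
            else:
                coordinate_specs.append(spec)
        except (ValueError, KeyError) as exc:
            result.statuses[key] = {"status": "error", "message": str(exc)}

    channels = edit_channels(editor)
    L, P = editor.spacer_length, editor.pam_length
    for spec in coordinate_specs:
        key = spec.original_input
        status = result.statuses.setdefault(
            key, {"status": "ok", "n_guides": 0, "n_safety_only": 0}
        )
        status.setdefault("n_guides", 0)
        status.setdefault("n_safety_only", 0)
        if spec.chrom not in genome:
            status.update(status="error",
                          message=f"unknown contig {spec.chrom!r}")
            continue
        actual = genome.fetch(spec.chrom, spec.pos, spec.pos, "+")
        if actual != spec.ref_base:
            status.update(
                status="error",
                message=(
                    f"reference mismatch at {spec.chrom}:{spec.pos}: "
                    f"expected {spec.ref_base}, found {actual}"
                ),
            )
            continue
        matching = [
            c for c in channels if c.plus_strand_change == (spec.ref_base,
                                                            spec.alt_base)
        ]
        if not matching:
            status["status"] = "not achievable"
            continue
        margin = L + P
        scan_start = max(1, spec.pos - margin)
        scan_end = min(genome.contigs[spec.chrom], spec.pos + margin)
        transcript = _annotation_transcript(transcripts, spec.chrom, spec.pos)
        cds = spliced_cds(transcript, genome) if transcript else None
        found = 0
        for channel in matching:
            for guide in find_protospacers(
                genome, spec.chrom, scan_start, scan_end, editor
            ):
                if guide.strand != channel.protospacer_strand:
                    continue
                ws, we = guide.window_genomic_span
                ss, se = guide.safety_genomic_span
                if ws <= spec.pos <= we:
                    profile = window_profile(guide, genome, editor)
                    report = annotate_guide(
                        guide, profile, transcript, cds, variant_id=key
                    )
                    result.editing_guides.append(report)
                    found += 1
                elif ss <= spec.pos <= se:
                    status["n_safety_only"] += 1
        status["n_guides"] += found
        if found == 0 and status["status"] == "ok":
            status["status"] = "no guide"
    result.sort()
    summarize(result)
    return result
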