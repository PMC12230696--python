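"""Codon-level consequence annotation and gene-mode library design.

Maps plus-strand genomic edits onto transcript codons (strand-corrected),
classifies the biological consequence of each edit, computes combined
codons when several in-window edits hit the same codon, builds
near-saturation gene libraries, and filters libraries by consequence for
screen-control selection.

Consequences are computed on the committed edit set: every editable base
inside the main editing window is assumed edited. Safety-region edits are
annotated as "possible" only and never enter codon calculus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .editor_model import BaseEditorConfig
from .reference_io import (
    CODON_TO_AA,
    CdsSequence,
    ReferenceGenome,
    TranscriptIndex,
    TranscriptModel,
    complement_base,
    spliced_cds,
)
from .scan_core import (
    Edit,
    GuideCandidate,
    GuideReport,
    LibraryResult,
    WindowProfile,
    find_protospacers,
    window_profile,
)


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # plain value in tables
        return self.value


#: Non-coding classes carry no codon change.
NON_CODING = {
    Consequence.SPLICE_SITE,
    Consequence.INTRONIC,
    Consequence.UTR,
    Consequence.INTERGENIC,
}


@dataclass(frozen=True)
class CodonChange:
    """A codon before/after editing, in transcript orientation."""

    transcript_name: str
    codon_index: int  # 1-based along the CDS; equals aa_pos
    ref_codon: str
    alt_codon: str
    exon_number: int | None = None

    @property
    def ref_aa(self) -> str:
        return CODON_TO_AA.get(self.ref_codon, "X")

    @property
    def alt_aa(self) -> str:
        return CODON_TO_AA.get(self.alt_codon, "X")

    @property
    def aa_pos(self) -> int:
        return self.codon_index

    @property
    def consequence(self) -> Consequence:
        return consequence_of(self.ref_codon, self.alt_codon, self.codon_index)


def consequence_of(ref_codon: str, alt_codon: str, codon_index: int) -> Consequence:
    """Classify a single codon change.

    Rules: stop_lost when a stop codon is destroyed; nonsense when a stop
    is gained; start_lost when codon 1 is changed away from ATG;
    synonymous when the amino acid is unchanged; missense otherwise.
    """
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid codon {codon!r}")
    ref_aa, alt_aa = CODON_TO_AA[ref_codon], CODON_TO_AA[alt_codon]
    if ref_aa == "*" and alt_aa != "*":
        return Consequence.STOP_LOST
    if alt_aa == "*" and ref_aa != "*":
        return Consequence.NONSENSE
    if codon_index == 1 and alt_codon != "ATG":
        return Consequence.START_LOST
    if ref_aa == alt_aa:
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE


def splice_site_positions(transcript: TranscriptModel) -> set[int]:
    """Genomic positions of the canonical 2-nt splice dinucleotides.

    The first/last two intronic nucleotides of every intron flanking a
    CDS-containing exon. Edits there are splice_site regardless of the
    reference dinucleotide identity.
    """
    exons = sorted(transcript.exons)
    cds = [(s, e) for s, e, _ in transcript.cds_segments]

    def has_cds(exon: tuple[int, int]) -> bool:
        s, e = exon
        return any(s <= ce and cs <= e for cs, ce in cds)

    positions: set[int] = set()
    for left, right in zip(exons, exons[1:]):
        if right[0] <= left[1] + 1:
            continue  # abutting exons, no intron
        if has_cds(left):  # 2 nt just after the left exon
            positions.update(range(left[1] + 1, min(left[1] + 3, right[0])))
        if has_cds(right):  # 2 nt just before the right exon
            positions.update(range(max(right[0] - 2, left[1] + 1), right[0]))
    return positions


def map_to_codon(
    edit: Edit, transcript: TranscriptModel, cds: CdsSequence
) -> CodonChange | Consequence:
    """Map one plus-strand edit to a codon change or a non-coding class.

    The alternative base is strand-corrected so the returned codons read
    in transcript orientation. Positions outside the CDS classify as
    splice_site / intronic / utr / intergenic (a total function).
    """
    pos = edit.pos
    if edit.chrom != transcript.chrom:
        return Consequence.INTERGENIC
    cds_pos = cds.genome_to_cds.get(pos)
    if cds_pos is not None:
        codon_index = (cds_pos - 1) // 3 + 1
        offset = (cds_pos - 1) % 3
        ref_codon = cds.codon(codon_index)
        alt_base = (
            edit.alt_base
            if transcript.strand == "+"
            else complement_base(edit.alt_base)
        )
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        return CodonChange(
            transcript_name=transcript.transcript_name,
            codon_index=codon_index,
            ref_codon=ref_codon,
            alt_codon=alt_codon,
            exon_number=transcript.exon_number_at(pos),
        )
    if pos in splice_site_positions(transcript):
        return Consequence.SPLICE_SITE
    if any(s <= pos <= e for s, e in transcript.introns()):
        return Consequence.INTRONIC
    if any(s <= pos <= e for s, e in transcript.exons):
        return Consequence.UTR
    return Consequence.INTERGENIC


def _consequence_of_outcome(outcome: CodonChange | Consequence) -> Consequence:
    if isinstance(outcome, CodonChange):
        return outcome.consequence
    return outcome


def edit_consequence(
    edit: Edit, transcript: TranscriptModel | None, cds: CdsSequence | None
) -> Consequence:
    """Single-edit consequence of one genomic change (used for unique-edit
    tallies; combined per-guide codons are handled by annotate_guide)."""
    if transcript is None or cds is None:
        return Consequence.INTERGENIC
    return _consequence_of_outcome(map_to_codon(edit, transcript, cds))


def annotate_guide(
    guide: GuideCandidate,
    profile: WindowProfile,
    transcript: TranscriptModel | None,
    cds: CdsSequence | None,
    variant_id: str = "",
) -> GuideReport:
    """Annotate one guide against one transcript.

    Every in-window edit is mapped individually, then all in-window edits
    hitting the same codon are applied jointly and the combined codon is
    classified — two edits in one codon yield one combined consequence,
    which can differ from either single-edit class.
    """
    report = GuideReport(
        guide=guide,
        profile=profile,
        variant_id=variant_id,
        gene=transcript.gene_name if transcript else "",
        transcript=transcript.transcript_name if transcript else "",
    )
    if transcript is None or cds is None:
        return report
    per_codon: dict[int, list[tuple[Edit, CodonChange]]] = {}
    for edit in profile.window_edits:
        outcome = map_to_codon(edit, transcript, cds)
        report.edit_annotations.append(
            (edit, outcome, _consequence_of_outcome(outcome))
        )
        if isinstance(outcome, CodonChange):
            per_codon.setdefault(outcome.codon_index, []).append((edit, outcome))
    for codon_index in sorted(per_codon):
        hits = per_codon[codon_index]
        ref_codon = hits[0][1].ref_codon
        alt = list(ref_codon)
        for edit, _ in hits:
            cds_pos = cds.genome_to_cds[edit.pos]
            offset = (cds_pos - 1) % 3
            alt[offset] = (
                edit.alt_base
                if transcript.strand == "+"
                else complement_base(edit.alt_base)
            )
        combined = CodonChange(
            transcript_name=transcript.transcript_name,
            codon_index=codon_index,
            ref_codon=ref_codon,
            alt_codon="".join(alt),
            exon_number=hits[0][1].exon_number,
        )
        report.combined_codons.append(combined)
    return report


def _extended_cds_intervals(transcript: TranscriptModel) -> list[tuple[int, int]]:
    """CDS segments extended 2 nt into each flanking intron.

    A segment side is extended only where its boundary coincides with its
    exon's boundary and an intron lies beyond (captures the canonical
    splice dinucleotides without admitting extra UTR positions).
    """
    exons = sorted(transcript.exons)
    out = []
    for s, e, _ in transcript.cds_segments:
        lo, hi = s, e
        for i, (xs, xe) in enumerate(exons):
            if xs <= s and e <= xe:
                if s == xs and i > 0:
                    lo = s - 2
                if e == xe and i < len(exons) - 1:
                    hi = e + 2
                break
        out.append((lo, hi))
    return sorted(out)


def design_gene(
    names: str | Sequence[str],
    genome: ReferenceGenome,
    transcripts: TranscriptIndex,
    editors: BaseEditorConfig | Sequence[BaseEditorConfig],
) -> LibraryResult:
    """Gene mode: near-saturation library over the CDS of named targets.

    The candidate space is every protospacer (both strands) whose main
    editing window overlaps the transcript's CDS segments extended 2 nt
    into flanking introns (so splice-dinucleotide edits are designable).
    Guides split into editing / binding-but-non-editing exactly as in
    region mode; editing guides are annotated per transcript.
    """
    if isinstance(names, str):
        names = [names]
    if isinstance(editors, BaseEditorConfig):
        editors = [editors]
    result = LibraryResult()
    for name in names:
        transcript = transcripts.resolve(name)
        cds = spliced_cds(transcript, genome)
        intervals = _extended_cds_intervals(transcript)
        margin = max(e.spacer_length + e.pam_length for e in editors)
        scan_start = max(1, min(s for s, _ in intervals) - margin)
        scan_end = min(
            genome.contigs[transcript.chrom],
            max(e for _, e in intervals) + margin,
        )
        for editor in editors:
            for guide in find_protospacers(
                genome, transcript.chrom, scan_start, scan_end, editor
            ):
                ws, we = guide.window_genomic_span
                if not any(s <= we and ws <= e for s, e in intervals):
                    continue
                profile = window_profile(guide, genome, editor)
                report = annotate_guide(guide, profile, transcript, cds)
                if profile.is_editing:
                    result.editing_guides.append(report)
                else:
                    result.non_editing_guides.append(report)
    result.sort()
    summarize(result, genome=genome, transcripts=transcripts)
    return result


def filter_by_consequence(
    result: LibraryResult,
    wanted: Iterable[Consequence | str],
    mode: str = "any",
) -> LibraryResult:
    """Keep editing guides whose in-window edit consequences match.

    mode="any": at least one in-window edit's consequence is wanted;
    mode="all": every in-window edit's consequence is wanted. The
    non-editing table is kept only when the literal class "non_editing"
    is requested (non-editing guides have no consequences to match).
    """
    keep_non_editing = False
    wanted_set: set[Consequence] = set()
    for w in wanted:
        if isinstance(w, Consequence):
            wanted_set.add(w)
        elif w == "non_editing":
            keep_non_editing = True
        else:
            try:
                wanted_set.add(Consequence(w))
            except ValueError:
                raise ValueError(
                    f"unknown consequence {w!r}; valid: "
                    f"{[c.value for c in Consequence]} or 'non_editing'"
                ) from None
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    picker = any if mode == "any" else all
    editing = []
    for report in result.editing_guides:
        conseqs = [c for (_, _, c) in report.edit_annotations]
        if conseqs and picker(c in wanted_set for c in conseqs):
            editing.append(report)
    filtered = LibraryResult(
        editing_guides=editing,
        non_editing_guides=list(result.non_editing_guides) if keep_non_editing else [],
        statuses=dict(result.statuses),
    )
    filtered.sort()
    summarize(filtered)
    return filtered


def summarize(
    result: LibraryResult,
    genome: ReferenceGenome | None = None,
    transcripts: TranscriptIndex | None = None,
) -> dict:
    """Recompute summary counts from the tables.

    Consequence tallies are reported two ways: ``unique_edit_consequences``
    counts each distinct (chrom, pos, ref, alt, transcript) edit once no
    matter how many guides induce it; ``guide_edit_consequences`` counts
    every (guide, edit) pair. Both derive from the per-edit (single-edit)
    classification recorded in the reports.
    """
    unique: dict[tuple, Consequence] = {}
    per_pair: Counter = Counter()
    per_editor: Counter = Counter()
    n_specific = 0
    for report in result.editing_guides:
        per_editor[report.guide.editor.name] += 1
        if report.profile.specific:
            n_specific += 1
        for edit, _, conseq in report.edit_annotations:
            unique[edit.key + (report.transcript,)] = conseq
            per_pair[conseq.value] += 1
    unique_counts: Counter = Counter(c.value for c in unique.values())
    result.summary = {
        "n_editing": len(result.editing_guides),
        "n_non_editing": len(result.non_editing_guides),
        "n_total": len(result.editing_guides) + len(result.non_editing_guides),
        "n_specific": n_specific,
        "per_editor": dict(per_editor),
        "unique_edit_consequences": dict(unique_counts),
        "guide_edit_consequences": dict(per_pair),
    }
    return result.summary
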