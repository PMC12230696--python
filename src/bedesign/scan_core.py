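"""Protospacer/PAM scanning and editing-window profiling.

Enumerates every protospacer+PAM match on both strands of a genomic
interval, computes each candidate's editing-window content (edits,
distances to the window center, specificity), and partitions candidates
into editing and non-editing guides (region mode).

Conventions
-----------
Genomic coordinates are 1-based inclusive. ``guide_start``/``guide_end``
span the spacer on the plus strand regardless of guide strand; for a 3'
PAM, ``pam_start = guide_end + 1`` on the plus strand and
``pam_end = guide_start - 1`` on the minus strand. Protospacer position
``p`` (1 at the spacer 5' end) maps to genomic position
``guide_start + p - 1`` on the plus strand and ``guide_end - p + 1`` on
the minus strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .editor_model import (
    BaseEditorConfig,
    channel_for_strand,
    iupac_match,
)
from .reference_io import ReferenceGenome, reverse_complement

_ACGT = set("ACGT")


@dataclass(frozen=True)
class GuideCandidate:
    """One protospacer+PAM match, prior to window profiling."""

    chrom: str
    strand: str
    guide_start: int
    guide_end: int
    pam_start: int
    pam_end: int
    spacer_seq: str  # protospacer-strand orientation
    pam_seq: str
    editor: BaseEditorConfig

    def protospacer_to_genomic(self, p: int) -> int:
        if self.strand == "+":
            return self.guide_start + p - 1
        return self.guide_end - p + 1

    def genomic_to_protospacer(self, pos: int) -> int | None:
        if not self.guide_start <= pos <= self.guide_end:
            return None
        if self.strand == "+":
            return pos - self.guide_start + 1
        return self.guide_end - pos + 1

    def _span(self, p1: int, p2: int) -> tuple[int, int]:
        a, b = self.protospacer_to_genomic(p1), self.protospacer_to_genomic(p2)
        return (a, b) if a <= b else (b, a)

    @property
    def window_genomic_span(self) -> tuple[int, int]:
        return self._span(self.editor.window_start, self.editor.window_end)

    @property
    def safety_genomic_span(self) -> tuple[int, int]:
        return self._span(self.editor.safety_start, self.editor.safety_end)

    @property
    def window_seq(self) -> str:
        e = self.editor
        return self.spacer_seq[e.window_start - 1 : e.window_end]

    @property
    def safety_seq(self) -> str:
        e = self.editor
        return self.spacer_seq[e.safety_start - 1 : e.safety_end]

    @property
    def spacer_with_pam(self) -> str:
        if self.editor.pam_side == "3prime":
            return self.spacer_seq + self.pam_seq
        return self.pam_seq + self.spacer_seq

    @property
    def key(self) -> tuple:
        return (self.chrom, self.guide_start, self.strand, self.editor.name)


@dataclass(frozen=True)
class Edit:
    """One editable base of a guide, expressed on the genomic plus strand."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    protospacer_position: int
    in_window: bool
    in_safety_only: bool
    distance_to_center: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class WindowProfile:
    """Edits of one guide within the safety region, window flags resolved."""

    edits: tuple[Edit, ...]
    n_edits_window: int
    n_edits_safety_only: int

    @property
    def specific(self) -> bool:
        return self.n_edits_window == 1

    @property
    def is_editing(self) -> bool:
        return self.n_edits_window >= 1

    @property
    def window_edits(self) -> tuple[Edit, ...]:
        return tuple(e for e in self.edits if e.in_window)

    @property
    def min_dist_to_center(self) -> float | None:
        dists = [e.distance_to_center for e in self.edits if e.in_window]
        return min(dists) if dists else None


@dataclass
class GuideReport:
    """One guide with its profile and (optional) transcript annotation.

    ``edit_annotations`` holds one entry per in-window edit: the edit, a
    codon change or a non-coding class, and its consequence.
    ``combined_codons`` holds one entry per affected codon with all
    in-window edits of that codon applied jointly. Both are filled by
    :func:`bedesign.consequence.annotate_guide`; region-mode reports may
    leave them empty.
    """

    guide: GuideCandidate
    profile: WindowProfile
    variant_id: str = ""
    gene: str = ""
    transcript: str = ""
    edit_annotations: list = field(default_factory=list)
    combined_codons: list = field(default_factory=list)

    @property
    def sort_key(self) -> tuple:
        return self.guide.key


@dataclass
class LibraryResult:
    """Paired editing / non-editing guide tables plus summary counts."""

    editing_guides: list[GuideReport] = field(default_factory=list)
    non_editing_guides: list[GuideReport] = field(default_factory=list)
    statuses: dict[str, dict] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def recompute_summary(self) -> dict:
        """Rebuild summary counts from the tables (self-consistency)."""
        from .consequence import summarize  # local: avoids import cycle

        self.summary = summarize(self)
        return self.summary

    def sort(self) -> "LibraryResult":
        self.editing_guides.sort(key=lambda r: r.sort_key)
        self.non_editing_guides.sort(key=lambda r: r.sort_key)
        return self


def find_protospacers(
    genome: ReferenceGenome,
    chrom: str,
    start: int,
    end: int,
    editor: BaseEditorConfig,
) -> list[GuideCandidate]:
    """All protospacer+PAM matches fully contained in [start, end].

    Both strands are scanned; candidates whose spacer or PAM contains a
    non-ACGT base are dropped. Output is sorted by (guide_start, strand).
    """
    L, P = editor.spacer_length, editor.pam_length
    if end - start + 1 < L + P:
        warnings.warn(
            f"interval {chrom}:{start}-{end} shorter than spacer+PAM "
            f"({L + P} nt); no candidates"
        )
        return []
    seq = genome.fetch(chrom, start, end, "+")
    out: list[GuideCandidate] = []
    three_prime = editor.pam_side == "3prime"
    for i in range(len(seq) - (L + P) + 1):
        block = seq[i : i + L + P]
        # plus strand: [spacer][PAM] for 3' PAM, [PAM][spacer] for 5'
        if three_prime:
            spacer_p, pam_p = block[:L], block[L:]
            gs_p = start + i
        else:
            pam_p, spacer_p = block[:P], block[P:]
            gs_p = start + i + P
        if iupac_match(editor.pam, pam_p) and _ACGT.issuperset(spacer_p + pam_p):
            ge_p = gs_p + L - 1
            ps = ge_p + 1 if three_prime else gs_p - P
            out.append(
                GuideCandidate(
                    chrom, "+", gs_p, ge_p, ps, ps + P - 1, spacer_p, pam_p, editor
                )
            )
        # minus strand: the protospacer-strand layout reverse-complemented
        rc = reverse_complement(block)
        if three_prime:
            spacer_m, pam_m = rc[:L], rc[L:]
            gs_m = start + i + P
        else:
            pam_m, spacer_m = rc[:P], rc[P:]
            gs_m = start + i
        if iupac_match(editor.pam, pam_m) and _ACGT.issuperset(spacer_m + pam_m):
            ge_m = gs_m + L - 1
            ps = gs_m - P if three_prime else ge_m + 1
            out.append(
                GuideCandidate(
                    chrom, "-", gs_m, ge_m, ps, ps + P - 1, spacer_m, pam_m, editor
                )
            )
    out.sort(key=lambda g: (g.guide_start, g.strand))
    return out


def window_profile(
    guide: GuideCandidate, genome: ReferenceGenome, editor: BaseEditorConfig
) -> WindowProfile:
    """Locate every editable base of a guide within its safety region.

    An editable base is an occurrence of the editor's ``edit_from`` base
    on the protospacer strand. Each is reported as a plus-strand genomic
    change via the guide's strand-resolved edit channel, flagged as
    in-window or safety-only, with its distance to the window center.
    """
    channel = channel_for_strand(editor, guide.strand)
    center = editor.window_center
    edits: list[Edit] = []
    for p in range(editor.safety_start, editor.safety_end + 1):
        if guide.spacer_seq[p - 1] != editor.edit_from:
            continue
        gpos = guide.protospacer_to_genomic(p)
        in_window = editor.window_start <= p <= editor.window_end
        edits.append(
            Edit(
                chrom=guide.chrom,
                pos=gpos,
                ref_base=channel.ref,
                alt_base=channel.alt,
                protospacer_position=p,
                in_window=in_window,
                in_safety_only=not in_window,
                distance_to_center=abs(p - center),
            )
        )
    n_win = sum(e.in_window for e in edits)
    return WindowProfile(tuple(edits), n_win, len(edits) - n_win)


_REGION_RE = re.compile(r"^\s*([\w.]+):(\d+)\s*[-–]\s*(\d+)\s*$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse "chrom:start-end" (1-based inclusive; hyphen or en-dash)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(
            f"malformed region {region!r}; expected chrom:start-end"
        )
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if not (1 <= start <= end):
        raise ValueError(f"invalid region coordinates in {region!r}")
    return chrom, start, end


def design_region(
    genome: ReferenceGenome,
    region: str,
    editors: BaseEditorConfig | Sequence[BaseEditorConfig],
) -> LibraryResult:
    """Region mode: all guides whose protospacer+PAM lie inside the region.

    Guides with at least one in-window editable base go to the editing
    table; the remainder are "binding but non-editing" guides. With
    several editors, each is run independently and the tables are
    concatenated (the editor name distinguishes rows).
    """
    if isinstance(editors, BaseEditorConfig):
        editors = [editors]
    chrom, start, end = parse_region(region)
    if chrom not in genome:
        from .reference_io import ReferenceError

        raise ReferenceError(
            f"unknown contig {chrom!r}; known: {sorted(genome.contigs)}"
        )
    result = LibraryResult()
    for editor in editors:
        for guide in find_protospacers(genome, chrom, start, end, editor):
            profile = window_profile(guide, genome, editor)
            report = GuideReport(guide=guide, profile=profile)
            if profile.is_editing:
                result.editing_guides.append(report)
            else:
                result.non_editing_guides.append(report)
    result.sort()
    result.recompute_summary()
    return result
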