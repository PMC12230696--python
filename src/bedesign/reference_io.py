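"""Reference genome and gene annotation access.

Provides random-access, strand-aware sequence fetch over an indexed FASTA
(via pyfaidx), transcript models parsed from an Ensembl-dialect GTF (via
pyranges), spliced CDS extraction, and bidirectional genomic<->CDS
coordinate maps.

Coordinates are 1-based inclusive throughout, matching the GTF/Ensembl
convention. Contig names are matched exactly between FASTA and GTF; no
"chr"-prefix normalization is attempted, and a vocabulary mismatch is
reported listing both sides.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pyfaidx
import pyranges as pr

from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Standard (NCBI table 1) codon -> one-letter amino acid, stops as "*".
CODON_TO_AA: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)
CODON_TO_AA.update({c: "*" for c in CodonTable.unambiguous_dna_by_id[1].stop_codons})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate_cds(seq: str) -> str:
    """Translate an in-frame DNA string with the standard codon table.

    Trailing partial codons are ignored; unknown codons (containing N)
    translate to "X".
    """
    return "".join(
        CODON_TO_AA.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


class ReferenceError(Exception):
    """Inconsistency between the query and the reference data."""


class ReferenceGenome:
    """Indexed FASTA with 1-based inclusive, strand-aware fetch.

    Sequences are uppercased on access. Bases outside {A,C,G,T} (including
    N) are retained; downstream protospacer scanning skips candidates
    containing them.
    """

    def __init__(self, fasta_path: str | Path):
        fasta_path = Path(fasta_path)
        if not fasta_path.exists():
            raise FileNotFoundError(f"FASTA not found: {fasta_path}")
        try:
            self._fasta = pyfaidx.Fasta(
                str(fasta_path), sequence_always_upper=True, as_raw=True
            )
        except ValueError as exc:  # pyfaidx raises on duplicate names
            raise ReferenceError(f"cannot index {fasta_path}: {exc}") from exc
        if len(self._fasta.keys()) == 0:
            raise ReferenceError(f"empty FASTA: {fasta_path}")
        self.path = fasta_path

    @property
    def contigs(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of chrom:start-end (1-based inclusive).

        strand "-" returns the reverse complement of the plus-strand
        sequence over the same coordinates.
        """
        if chrom not in self._fasta:
            raise ReferenceError(
                f"unknown contig {chrom!r}; known: {sorted(self._fasta.keys())}"
            )
        length = len(self._fasta[chrom])
        if not (1 <= start <= end <= length):
            raise ReferenceError(
                f"coordinates {chrom}:{start}-{end} out of bounds (1-{length})"
            )
        seq = self._fasta[chrom][start - 1 : end]
        if strand == "-":
            return reverse_complement(seq)
        if strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return seq


def load_genome(fasta_path: str | Path) -> ReferenceGenome:
    """Open an indexed FASTA (the .fai index is built on first load)."""
    return ReferenceGenome(fasta_path)


def fetch_sequence(
    genome: ReferenceGenome, chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    return genome.fetch(chrom, start, end, strand)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon/CDS structure in transcription order.

    ``exons`` and ``cds_segments`` are ordered 5'->3' of the transcript
    (descending genomic coordinates on the minus strand). Intervals are
    1-based inclusive ``(start, end)`` genomic tuples; CDS segments carry
    a third element, the GTF frame.
    """

    gene_name: str
    transcript_name: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int, int], ...]
    start_codon: tuple[tuple[int, int], ...] = ()
    stop_codon: tuple[tuple[int, int], ...] = ()
    canonical: bool = False
    tags: frozenset[str] = frozenset()

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    @property
    def cds_span(self) -> tuple[int, int]:
        starts = [s for s, e, _ in self.cds_segments]
        ends = [e for s, e, _ in self.cds_segments]
        return min(starts), max(ends)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (ascending), between adjacent exons."""
        ex = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def exon_number_at(self, pos: int) -> int | None:
        """1-based exon number (transcription order) containing pos."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None


@dataclass
class CdsSequence:
    """Spliced CDS in transcript orientation with coordinate maps.

    ``cds_to_genome`` maps 1-based CDS position -> (chrom, genomic pos,
    strand); ``genome_to_cds`` is its inverse keyed on genomic position.
    """

    transcript: TranscriptModel
    seq: str
    cds_to_genome: dict[int, tuple[str, int, str]]
    genome_to_cds: dict[int, int]

    def codon(self, codon_index: int) -> str:
        return self.seq[3 * (codon_index - 1) : 3 * codon_index]

    @property
    def protein(self) -> str:
        return translate_cds(self.seq)


def spliced_cds(transcript: TranscriptModel, genome: ReferenceGenome) -> CdsSequence:
    """Extract the spliced CDS and build the genomic<->CDS maps.

    When start/stop codons are annotated, the CDS is expected to begin
    with ATG and translate without internal stops; violations are
    reported as warnings (real annotations contain exceptions), not
    errors.
    """
    if not transcript.cds_segments:
        raise ValueError(f"{transcript.transcript_name} has no CDS segments")
    parts: list[str] = []
    cds_to_genome: dict[int, tuple[str, int, str]] = {}
    p = 1
    for s, e, _frame in transcript.cds_segments:
        plus = genome.fetch(transcript.chrom, s, e, "+")
        if transcript.strand == "+":
            parts.append(plus)
            positions = range(s, e + 1)
        else:
            parts.append(reverse_complement(plus))
            positions = range(e, s - 1, -1)
        for gpos in positions:
            cds_to_genome[p] = (transcript.chrom, gpos, transcript.strand)
            p += 1
    seq = "".join(parts)
    genome_to_cds = {g: c for c, (_, g, _) in cds_to_genome.items()}
    if transcript.start_codon and transcript.stop_codon:
        if not seq.startswith("ATG"):
            warnings.warn(
                f"{transcript.transcript_name}: CDS does not start with ATG "
                f"(got {seq[:3]})"
            )
        prot = translate_cds(seq)
        if "*" in prot[:-1]:
            warnings.warn(
                f"{transcript.transcript_name}: internal stop codon in CDS"
            )
    return CdsSequence(transcript, seq, cds_to_genome, genome_to_cds)


_TAG_RE = re.compile(r'tag "([^"]+)"')


def _collect_tags(gtf_path: Path) -> dict[str, set[str]]:
    """transcript_id -> full set of tag attribute values.

    pyranges keeps only the last ``tag`` key per line, so the multi-valued
    tag sets (Ensembl_canonical, MANE_Select, ...) are collected in one
    extra pass over the attribute column.
    """
    tid_re = re.compile(r'transcript_id "([^"]+)"')
    tags: dict[str, set[str]] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "transcript":
                continue
            m = tid_re.search(fields[8])
            if m:
                tags.setdefault(m.group(1), set()).update(
                    _TAG_RE.findall(fields[8])
                )
    return tags


def _intervals_raw(sub, feature: str, reverse: bool):
    rows = sub[sub["Feature"] == feature]
    return [
        (int(s), int(e))
        for s, e in sorted(zip(rows["start1"], rows["end1"]), reverse=reverse)
    ]


class TranscriptIndex:
    """Transcripts indexed by gene name, transcript name, and id."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        self.by_transcript_name: dict[str, TranscriptModel] = {}
        self.by_transcript_id: dict[str, TranscriptModel] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_name, []).append(t)
            self.by_transcript_name[t.transcript_name] = t
            self.by_transcript_id[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def resolve(self, name: str) -> TranscriptModel:
        """Resolve a gene or transcript name to a single transcript.

        A transcript name or id matches directly. A bare gene name
        selects the default transcript: Ensembl_canonical tag, then
        MANE_Select, then longest CDS, ties broken by lexicographic
        transcript_id.
        """
        if name in self.by_transcript_name:
            return self.by_transcript_name[name]
        if name in self.by_transcript_id:
            return self.by_transcript_id[name]
        if name not in self.by_gene:
            raise KeyError(
                f"unknown gene or transcript name {name!r}; known genes: "
                f"{sorted(self.by_gene)}"
            )
        candidates = self.by_gene[name]
        for pick in (
            [t for t in candidates if t.canonical],
            [t for t in candidates if "MANE_Select" in t.tags],
        ):
            if pick:
                return sorted(pick, key=lambda t: t.transcript_id)[0]
        return sorted(
            candidates, key=lambda t: (-t.cds_length, t.transcript_id)
        )[0]


def load_annotation(gtf_path: str | Path) -> TranscriptIndex:
    """Parse an Ensembl-dialect GTF into transcript models.

    One model is built per transcript that has at least one CDS feature.
    The canonical flag is set from the ``Ensembl_canonical`` tag.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(f"GTF not found: {gtf_path}")
    with open(gtf_path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return TranscriptIndex([])
    try:
        ranges = pr.read_gtf(str(gtf_path))
    except Exception as exc:
        raise ReferenceError(f"cannot parse GTF {gtf_path}: {exc}") from exc
    if len(ranges) == 0:
        return TranscriptIndex([])
    df = ranges.df
    # pyranges is 0-based half-open; convert to 1-based inclusive
    df = df.assign(start1=df["Start"] + 1, end1=df["End"])
    tag_sets = _collect_tags(gtf_path)

    models: list[TranscriptModel] = []
    coding = df[df["Feature"].isin(["exon", "CDS", "start_codon", "stop_codon"])]
    for tid, sub in coding.groupby("transcript_id", sort=True, observed=True):
        cds_rows = sub[sub["Feature"] == "CDS"]
        if cds_rows.empty:
            continue
        strands = set(sub["Strand"])
        if len(strands) != 1:
            raise ReferenceError(
                f"transcript {tid} has contradictory strands: {sorted(strands)}"
            )
        strand = strands.pop()
        chroms = set(str(c) for c in sub["Chromosome"])
        if len(chroms) != 1:
            raise ReferenceError(
                f"transcript {tid} spans multiple contigs: {sorted(chroms)}"
            )
        chrom = chroms.pop()
        reverse = strand == "-"

        def _intervals(feature: str):
            rows = sub[sub["Feature"] == feature]
            ivals = sorted(
                zip(rows["start1"], rows["end1"]), reverse=reverse
            )
            return tuple((int(s), int(e)) for s, e in ivals)

        cds = sorted(
            zip(cds_rows["start1"], cds_rows["end1"], cds_rows["Frame"]),
            reverse=reverse,
        )
        cds_segments = [
            (int(s), int(e), int(f) if str(f).isdigit() else 0) for s, e, f in cds
        ]
        # Ensembl GTFs exclude the stop codon from CDS features; the
        # transcript model runs the CDS through the stop so stop-lost
        # edits are designable. Merge stop_codon intervals not already
        # covered (abutting intervals coalesce, split stops append).
        for ss, se in _intervals_raw(sub, "stop_codon", reverse):
            if any(s <= ss and se <= e for s, e, _ in cds_segments):
                continue
            merged = False
            for i, (s, e, f) in enumerate(cds_segments):
                if strand == "+" and ss == e + 1:
                    cds_segments[i] = (s, se, f)
                    merged = True
                    break
                if strand == "-" and se == s - 1:
                    cds_segments[i] = (ss, e, f)
                    merged = True
                    break
            if not merged:
                cds_segments.append((ss, se, 0))
        cds_segments = tuple(sorted(cds_segments, reverse=reverse))
        first = sub.iloc[0]
        gene_name = str(first.get("gene_name", "") or first.get("gene_id", ""))
        tname = str(first.get("transcript_name", "") or tid)
        tags = frozenset(tag_sets.get(str(tid), set()))
        models.append(
            TranscriptModel(
                gene_name=gene_name,
                transcript_name=tname,
                transcript_id=str(tid),
                chrom=chrom,
                strand=strand,
                exons=_intervals("exon"),
                cds_segments=cds_segments,
                start_codon=_intervals("start_codon"),
                stop_codon=_intervals("stop_codon"),
                canonical="Ensembl_canonical" in tags,
                tags=tags,
            )
        )
    return TranscriptIndex(models)


def check_contig_compatibility(
    genome: ReferenceGenome, transcripts: TranscriptIndex
) -> None:
    """Raise if the annotation references contigs absent from the FASTA."""
    gtf_contigs = {t.chrom for t in transcripts}
    missing = gtf_contigs - set(genome.contigs)
    if missing:
        raise ReferenceError(
            "annotation contigs absent from FASTA: "
            f"{sorted(missing)}; FASTA has {sorted(genome.contigs)}"
        )
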