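"""Deterministic tabular output for guide libraries.

One row per guide report, fixed column order, rows sorted by
(chrom, guide_start, strand, editor). Multi-valued codon fields (a guide
can affect several codons) are semicolon-joined within a cell. The
non-editing table goes to a sibling file with a ``.non_editing`` suffix
inserted before the extension.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .scan_core import GuideReport, LibraryResult

COLUMNS = [
    "variant_id", "editor", "chrom", "strand", "guide_start", "guide_end",
    "spacer_seq", "spacer_with_pam", "pam_seq", "window_seq", "safety_seq",
    "n_edits_window", "n_edits_safety", "min_dist_to_center", "specific",
    "edits", "gene", "transcript", "exon", "codon_ref", "codon_alt",
    "aa_ref", "aa_alt", "aa_pos", "consequence",
]


def _join(values) -> str:
    return ";".join(str(v) for v in values)


def report_row(report: GuideReport) -> dict:
    guide, profile = report.guide, report.profile
    combined = report.combined_codons
    # non-coding in-window edits contribute a consequence but no codon
    non_coding = [
        c for (_, outcome, c) in report.edit_annotations
        if not hasattr(outcome, "ref_codon")
    ]
    consequences = [c.consequence.value for c in combined] + [
        c.value for c in non_coding
    ]
    return {
        "variant_id": report.variant_id,
        "editor": guide.editor.name,
        "chrom": guide.chrom,
        "strand": guide.strand,
        "guide_start": guide.guide_start,
        "guide_end": guide.guide_end,
        "spacer_seq": guide.spacer_seq,
        "spacer_with_pam": guide.spacer_with_pam,
        "pam_seq": guide.pam_seq,
        "window_seq": guide.window_seq,
        "safety_seq": guide.safety_seq,
        "n_edits_window": profile.n_edits_window,
        "n_edits_safety": profile.n_edits_safety_only,
        "min_dist_to_center": (
            "" if profile.min_dist_to_center is None else profile.min_dist_to_center
        ),
        "specific": profile.specific,
        "edits": _join(
            f"{e.pos}:{e.ref_base}>{e.alt_base}" for e in profile.window_edits
        ),
        "gene": report.gene,
        "transcript": report.transcript,
        "exon": _join(c.exon_number for c in combined if c.exon_number),
        "codon_ref": _join(c.ref_codon for c in combined),
        "codon_alt": _join(c.alt_codon for c in combined),
        "aa_ref": _join(c.ref_aa for c in combined),
        "aa_alt": _join(c.alt_aa for c in combined),
        "aa_pos": _join(c.aa_pos for c in combined),
        "consequence": _join(consequences),
    }


def result_frames(result: LibraryResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    def frame(reports):
        df = pd.DataFrame([report_row(r) for r in reports], columns=COLUMNS)
        return df.sort_values(
            ["chrom", "guide_start", "strand", "editor"], kind="stable"
        ).reset_index(drop=True)

    return frame(result.editing_guides), frame(result.non_editing_guides)


def non_editing_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".non_editing" + path.suffix)


def write_table(
    result: LibraryResult, path: str | Path, format: str = "tsv"
) -> Path:
    """Write the editing table to ``path`` and the non-editing table to
    its ``.non_editing`` sibling. Returns the editing-table path."""
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be tsv or csv, got {format!r}")
    sep = "\t" if format == "tsv" else ","
    path = Path(path)
    editing, non_editing = result_frames(result)
    editing.to_csv(path, sep=sep, index=False)
    non_editing.to_csv(non_editing_path(path), sep=sep, index=False)
    return path


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a guide table back with the same dtypes written by write_table."""
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("guide_start", "guide_end", "n_edits_window", "n_edits_safety"):
        df[col] = df[col].astype(int)
    df["specific"] = df["specific"] == "True"
    return df
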