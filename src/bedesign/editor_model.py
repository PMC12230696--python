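"""Base-editor configuration.

A base editor is fully described by its edit channel (one from->to base
conversion acting on the protospacer-containing strand), a PAM pattern
(IUPAC), the spacer length, the main editing window, and a wider safety
region in which low-efficiency "possible" edits are annotated but not
committed.

Protospacer positions are numbered 1..spacer_length from the 5' end of
the spacer — PAM-distal for a 3' PAM such as NGG, the dominant convention
for quoting windows like "4-8".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .reference_io import complement_base

IUPAC_CODES: dict[str, set[str]] = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def iupac_match(pattern: str, seq: str) -> bool:
    """True if seq matches the IUPAC pattern position by position."""
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC_CODES[p] for p, b in zip(pattern, seq))


@dataclass(frozen=True)
class EditChannel:
    """One strand-resolved conversion, expressed on the genomic plus strand."""

    protospacer_strand: str  # "+" or "-"
    ref: str  # plus-strand reference base converted by this channel
    alt: str  # plus-strand result base

    @property
    def plus_strand_change(self) -> tuple[str, str]:
        return (self.ref, self.alt)


@dataclass(frozen=True)
class BaseEditorConfig:
    name: str
    edit_from: str
    edit_to: str
    pam: str = "NGG"
    pam_side: str = "3prime"
    spacer_length: int = 20
    window_start: int = 4
    window_end: int = 8
    safety_start: int = 3
    safety_end: int = 10

    def __post_init__(self):
        if self.edit_from not in "ACGT" or self.edit_to not in "ACGT":
            raise ValueError(
                f"edit bases must be A/C/G/T, got {self.edit_from}>{self.edit_to}"
            )
        if self.edit_from == self.edit_to:
            raise ValueError("edit_from must differ from edit_to")
        if not self.pam:
            raise ValueError("PAM pattern must be non-empty")
        bad = set(self.pam) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC characters in PAM: {sorted(bad)}")
        if self.pam_side not in ("3prime", "5prime"):
            raise ValueError(f"pam_side must be 3prime or 5prime, got {self.pam_side}")
        if not (1 <= self.window_start <= self.window_end <= self.spacer_length):
            raise ValueError(
                f"editing window {self.window_start}-{self.window_end} not within "
                f"spacer of length {self.spacer_length}"
            )
        if not (
            1 <= self.safety_start <= self.window_start
            and self.window_end <= self.safety_end <= self.spacer_length
        ):
            raise ValueError(
                f"safety region {self.safety_start}-{self.safety_end} must contain "
                f"window {self.window_start}-{self.window_end} within the spacer"
            )

    @property
    def pam_length(self) -> int:
        return len(self.pam)

    @property
    def window_center(self) -> float:
        """Midpoint of the editing window; half-integral for even widths."""
        return (self.window_start + self.window_end) / 2


#: Shipped presets. Window 4-8 and safety 3-10 are this package's defaults
#: for the classic NGG editors; all fields are overridable per parameter.
PRESETS: dict[str, BaseEditorConfig] = {
    "ABE": BaseEditorConfig(
        name="ABE", edit_from="A", edit_to="G", pam="NGG",
        spacer_length=20, window_start=4, window_end=8,
        safety_start=3, safety_end=10,
    ),
    "CBE": BaseEditorConfig(
        name="CBE", edit_from="C", edit_to="T", pam="NGG",
        spacer_length=20, window_start=4, window_end=8,
        safety_start=3, safety_end=10,
    ),
}


def make_editor(preset: str | None = None, **overrides) -> BaseEditorConfig:
    """Build a validated editor config from a preset and/or parameters.

    Examples
    --------
    >>> make_editor("ABE").edit_from
    'A'
    >>> make_editor("CBE", window_start=3, window_end=9).window_end
    9
    >>> make_editor(name="CGBE", edit_from="C", edit_to="G").edit_to
    'G'
    """
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        base = PRESETS[preset]
        return replace(base, **overrides) if overrides else base
    required = {"name", "edit_from", "edit_to"}
    missing = required - overrides.keys()
    if missing:
        raise ValueError(f"missing required editor parameters: {sorted(missing)}")
    return BaseEditorConfig(**overrides)


def edit_channels(editor: BaseEditorConfig) -> tuple[EditChannel, EditChannel]:
    """The two strand-resolved channels an editor induces on the plus strand.

    Deamination acts on the protospacer strand, so a guide on the minus
    strand converts complement(edit_from)->complement(edit_to) as seen on
    the plus strand (e.g. CBE: {(+, C>T), (-, G>A)}).
    """
    return (
        EditChannel("+", editor.edit_from, editor.edit_to),
        EditChannel(
            "-", complement_base(editor.edit_from), complement_base(editor.edit_to)
        ),
    )


def channel_for_strand(editor: BaseEditorConfig, strand: str) -> EditChannel:
    plus, minus = edit_channels(editor)
    return plus if strand == "+" else minus
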