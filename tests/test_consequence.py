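"""Codon mapping, consequence classification, gene mode, control filtering."""

import itertools

import pytest

from bedesign import (
    PRESETS,
    Consequence,
    consequence_of,
    design_gene,
    design_region,
    filter_by_consequence,
    map_to_codon,
    spliced_cds,
)
from bedesign.consequence import CodonChange, splice_site_positions
from bedesign.reference_io import CODON_TO_AA, complement_base
from bedesign.scan_core import Edit


def _edit(pos, ref, alt, chrom="chrT"):
    return Edit(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt,
        protospacer_position=5, in_window=True, in_safety_only=False,
        distance_to_center=1.0,
    )


class TestConsequenceOf:
    @pytest.mark.parametrize(
        "ref,alt,index,expected",
        [
            ("CTG", "TTG", 10, Consequence.SYNONYMOUS),  # Leu->Leu
            ("CAG", "TAG", 10, Consequence.NONSENSE),  # Gln->stop
            ("TGC", "CGC", 130, Consequence.MISSENSE),  # Cys->Arg
            ("GTG", "GCG", 129, Consequence.MISSENSE),  # Val->Ala
            ("TGA", "TGG", 200, Consequence.STOP_LOST),
            ("ATG", "GTG", 1, Consequence.START_LOST),
            ("ATG", "ACG", 2, Consequence.MISSENSE),  # Met->Thr, not codon 1
        ],
    )
    def test_classification(self, ref, alt, index, expected):
        assert consequence_of(ref, alt, index) is expected

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            consequence_of("AT", "ATG", 1)
        with pytest.raises(ValueError):
            consequence_of("ATG", "ANG", 1)

    def test_exhaustive_matrix_matches_independent_rules(self):
        """All 64 codons x 3 positions x both channels of ABE and CBE,
        against an inline re-derivation from the codon table."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        channels = [("A", "G"), ("T", "C"), ("C", "T"), ("G", "A")]
        n_checked = 0
        for codon_tuple in itertools.product("ACGT", repeat=3):
            ref = "".join(codon_tuple)
            for off, (frm, to) in itertools.product(range(3), channels):
                if ref[off] != frm:
                    continue
                alt = ref[:off] + to + ref[off + 1 :]
                for index in (1, 7):
                    got = consequence_of(ref, alt, index)
                    ref_aa, alt_aa = CODON_TO_AA[ref], CODON_TO_AA[alt]
                    if ref_aa == "*" and alt_aa != "*":
                        expected = Consequence.STOP_LOST
                    elif alt_aa == "*" and ref_aa != "*":
                        expected = Consequence.NONSENSE
                    elif index == 1 and alt != "ATG":
                        expected = Consequence.START_LOST
                    elif ref_aa == alt_aa:
                        expected = Consequence.SYNONYMOUS
                    else:
                        expected = Consequence.MISSENSE
                    assert got is expected, (ref, alt, index)
                    n_checked += 1
        assert n_checked > 300  # the matrix is genuinely exhaustive


class TestMapToCodon:
    def test_first_three_cds_positions_map_to_codon_one(
        self, genome, transcripts
    ):
        t = transcripts.resolve("ALPHA")
        cds = spliced_cds(t, genome)
        for p in (1, 2, 3):
            chrom, gpos, strand = cds.cds_to_genome[p]
            ref = genome.fetch(chrom, gpos, gpos)
            alt = "G" if ref != "G" else "A"
            outcome = map_to_codon(_edit(gpos, ref, alt), t, cds)
            assert isinstance(outcome, CodonChange)
            assert outcome.codon_index == 1
            assert outcome.aa_pos == 1

    def test_minus_strand_edit_is_strand_corrected(self, genome, transcripts):
        # a plus-strand G>A edit reads C>T in a minus-strand codon
        t = transcripts.resolve("BRAVO")
        assert t.strand == "-"
        cds = spliced_cds(t, genome)
        gpos = next(
            g for p, (c, g, s) in sorted(cds.cds_to_genome.items())
            if genome.fetch(c, g, g) == "G"
        )
        outcome = map_to_codon(_edit(gpos, "G", "A"), t, cds)
        assert isinstance(outcome, CodonChange)
        p = cds.genome_to_cds[gpos]
        off = (p - 1) % 3
        assert outcome.ref_codon[off] == "C"
        assert outcome.alt_codon[off] == "T"
        # manual reverse-complement oracle
        assert outcome.ref_codon[off] == complement_base("G")

    @pytest.mark.parametrize(
        "position_source,expected",
        [
            ("splice_positions", Consequence.SPLICE_SITE),
            ("intron_interior", Consequence.INTRONIC),
            ("utr", Consequence.UTR),
            ("intergenic", Consequence.INTERGENIC),
        ],
    )
    def test_non_coding_classes(
        self, genome, transcripts, bundle, position_source, expected
    ):
        name = "ALPHA"
        t = transcripts.resolve(name)
        cds = spliced_cds(t, genome)
        gt = bundle.truth["genes"][name]
        if position_source == "splice_positions":
            pos = gt["splice_positions"][0]
        elif position_source == "intron_interior":
            s, e = gt["introns"][0]
            pos = (s + e) // 2
            assert pos not in set(gt["splice_positions"])
        elif position_source == "utr":
            pos = gt["exons"][0][0]  # 5' UTR start of first exon
            assert pos not in set(gt["cds_positions"])
        else:
            pos = 5  # leading intergenic gap
        ref = genome.fetch("chrT", pos, pos)
        alt = "A" if ref != "A" else "G"
        assert map_to_codon(_edit(pos, ref, alt), t, cds) is expected

    def test_splice_positions_are_intron_termini(self, transcripts, bundle):
        for name, gt in bundle.truth["genes"].items():
            t = transcripts.resolve(name)
            got = splice_site_positions(t)
            assert got == set(gt["splice_positions"])
            for s, e in gt["introns"]:
                assert {s, s + 1, e - 1, e} <= got


class TestGeneMode:
    def test_counts_match_planted_truth(
        self, genome, transcripts, bundle, editors
    ):
        for name, gt in bundle.truth["genes"].items():
            res = design_gene(name, genome, transcripts, editors)
            assert res.summary["n_editing"] == gt["n_editing"]
            assert res.summary["n_specific"] == gt["n_specific"]
            assert res.summary["n_non_editing"] == gt["n_non_editing"]
            assert (
                res.summary["unique_edit_consequences"]
                == gt["unique_edit_consequences"]
            )

    def test_whole_cds_retranslation_oracle(self, genome, transcripts, editors):
        """Applying all in-window edits of a guide to the whole spliced CDS
        and re-translating reproduces the combined per-codon annotations."""
        t = transcripts.resolve("CHARLIE")
        cds = spliced_cds(t, genome)
        res = design_gene("CHARLIE", genome, transcripts, editors)
        assert res.editing_guides
        for report in res.editing_guides:
            edited = list(cds.seq)
            for edit in report.profile.window_edits:
                p = cds.genome_to_cds.get(edit.pos)
                if p is None:
                    continue
                base = (
                    edit.alt_base if t.strand == "+"
                    else complement_base(edit.alt_base)
                )
                edited[p - 1] = base
            edited = "".join(edited)
            for combined in report.combined_codons:
                i = combined.codon_index
                assert edited[3 * (i - 1) : 3 * i] == combined.alt_codon
                assert CODON_TO_AA[combined.alt_codon] == combined.alt_aa

    def test_two_edits_one_codon_combine(self, genome, transcripts, editors):
        found = False
        for name in ("ALPHA", "BRAVO", "CHARLIE", "DELTA"):
            res = design_gene(name, genome, transcripts, editors)
            cds = spliced_cds(transcripts.resolve(name), genome)
            for report in res.editing_guides:
                per_codon = {}
                for edit in report.profile.window_edits:
                    p = cds.genome_to_cds.get(edit.pos)
                    if p is not None:
                        per_codon.setdefault((p - 1) // 3 + 1, []).append(edit)
                for ci, hits in per_codon.items():
                    if len(hits) >= 2:
                        combined = next(
                            c for c in report.combined_codons
                            if c.codon_index == ci
                        )
                        diffs = sum(
                            a != b
                            for a, b in zip(combined.ref_codon,
                                            combined.alt_codon)
                        )
                        assert diffs == len(hits)
                        found = True
        assert found, "fixture produced no double-hit codon"

    def test_gene_mode_guides_appear_in_region_mode(
        self, genome, transcripts, bundle, editors
    ):
        name = "ALPHA"
        gt = bundle.truth["genes"][name]
        res_gene = design_gene(name, genome, transcripts, editors)
        margin = 25
        s, e = gt["span"][0] - margin, gt["span"][1] + margin
        res_region = design_region(genome, f"chrT:{s}-{e}", editors)
        region_keys = {
            r.guide.key
            for r in res_region.editing_guides + res_region.non_editing_guides
        }
        for r in res_gene.editing_guides + res_gene.non_editing_guides:
            assert r.guide.key in region_keys

    def test_every_in_window_edit_has_exactly_one_consequence(
        self, genome, transcripts, editors
    ):
        res = design_gene("DELTA", genome, transcripts, editors)
        for report in res.editing_guides:
            assert len(report.edit_annotations) == len(
                report.profile.window_edits
            )
            for _, _, conseq in report.edit_annotations:
                assert isinstance(conseq, Consequence)

    def test_unknown_gene_errors(self, genome, transcripts, editors):
        with pytest.raises(KeyError):
            design_gene("NOSUCH", genome, transcripts, editors)

    def test_summary_self_consistent(self, genome, transcripts, editors):
        res = design_gene("BRAVO", genome, transcripts, editors)
        stored = dict(res.summary)
        assert res.recompute_summary() == stored


@pytest.fixture(scope="module")
def library(genome, transcripts, editors):
    return design_gene("CHARLIE", genome, transcripts, editors)


class TestFilterByConsequence:
    def test_empty_wanted_empties_table(self, library):
        assert filter_by_consequence(library, []).editing_guides == []

    def test_all_classes_any_is_identity(self, library):
        res = filter_by_consequence(library, list(Consequence), mode="any")
        assert [r.guide.key for r in res.editing_guides] == [
            r.guide.key for r in library.editing_guides
        ]

    def test_all_mode_excludes_bystander_contaminated_guides(self, library):
        clean = filter_by_consequence(
            library, [Consequence.SYNONYMOUS], mode="all"
        )
        for report in clean.editing_guides:
            assert all(
                c is Consequence.SYNONYMOUS
                for (_, _, c) in report.edit_annotations
            )
        any_syn = filter_by_consequence(
            library, [Consequence.SYNONYMOUS], mode="any"
        )
        assert len(clean.editing_guides) <= len(any_syn.editing_guides)
        # brute-force recount from the parent library
        expected_all = [
            r.guide.key for r in library.editing_guides
            if all(c is Consequence.SYNONYMOUS
                   for (_, _, c) in r.edit_annotations)
        ]
        assert [r.guide.key for r in clean.editing_guides] == expected_all

    def test_non_editing_kept_only_on_request(self, library):
        dropped = filter_by_consequence(library, [Consequence.NONSENSE])
        assert dropped.non_editing_guides == []
        kept = filter_by_consequence(
            library, [Consequence.NONSENSE, "non_editing"]
        )
        assert len(kept.non_editing_guides) == len(library.non_editing_guides)

    def test_unknown_consequence_name(self, library):
        with pytest.raises(ValueError, match="frameshift"):
            filter_by_consequence(library, ["frameshift"])
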