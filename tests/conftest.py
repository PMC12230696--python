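"""Shared fixtures: a seeded synthetic genome bundle, loaded references."""

import pytest

from bedesign import PRESETS, load_annotation, load_genome
from bedesign.fixtures import make_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    return make_fixture(FIXTURE_SEED, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def genome(bundle):
    return load_genome(bundle.fasta)


@pytest.fixture(scope="session")
def transcripts(bundle):
    return load_annotation(bundle.gtf)


@pytest.fixture(scope="session")
def editors():
    return [PRESETS["ABE"], PRESETS["CBE"]]


def canonical_engine_records(genome, chrom, start, end, editor):
    """find_protospacers + window_profile as comparable tuples,
    with guide coordinates shifted to be relative to [start, end]."""
    from bedesign import find_protospacers, window_profile

    out = []
    for cand in find_protospacers(genome, chrom, start, end, editor):
        prof = window_profile(cand, genome, editor)
        edits = tuple(
            sorted(
                (e.pos - start + 1, e.ref_base, e.alt_base,
                 e.protospacer_position, e.in_window, e.distance_to_center)
                for e in prof.edits
            )
        )
        out.append(
            (cand.strand, cand.guide_start - start + 1,
             cand.guide_end - start + 1, cand.spacer_seq, cand.pam_seq,
             edits, prof.is_editing, prof.specific)
        )
    return sorted(out)


def canonical_oracle_records(sequence, editor):
    """oracle_scan output as the same comparable tuples."""
    from bedesign.fixtures import oracle_scan

    out = []
    for rec in oracle_scan(sequence, editor):
        edits = tuple(
            sorted(
                (e["pos"], e["ref"], e["alt"], e["protospacer_position"],
                 e["in_window"], e["distance_to_center"])
                for e in rec["edits"]
            )
        )
        out.append(
            (rec["strand"], rec["start"], rec["end"], rec["spacer"],
             rec["pam"], edits, rec["is_editing"], rec["specific"])
        )
    return sorted(out)
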