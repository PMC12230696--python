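"""Seeded synthetic mini-genome fixtures and a naive scanning oracle.

``make_fixture`` writes a small FASTA/GTF/VCF bundle — multi-exon genes
on both strands with annotated start/stop codons, UTRs, canonical splice
dinucleotides, and planted rsID SNVs — together with a truth table of
guide and consequence counts computed *by construction*: the truth comes
from :func:`oracle_scan` (an intentionally naive, quadratic enumeration)
and a naive whole-CDS classification, never from the scanning engine.
Regeneration with the same seed and parameters is byte-identical.

The oracle checks every offset on both strands, tests the PAM character
by character against the IUPAC code, and lists every editable base in
the safety region. It exists to disagree with the engine when the engine
is wrong; keep it simple, not fast.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio.Data import CodonTable

from .editor_model import IUPAC_CODES, BaseEditorConfig

_BIO_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_BIO_TABLE.forward_table)
_AA.update({c: "*" for c in _BIO_TABLE.stop_codons})
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# naive oracle
# ---------------------------------------------------------------------------

def oracle_scan(sequence: str, editor: BaseEditorConfig) -> list[dict]:
    """Naively enumerate every guide in a plain sequence string.

    Returns one record per protospacer+PAM match fully inside the
    sequence, on either strand, with 1-based plus-strand coordinates and
    the list of editable bases in the safety region. Candidates with
    non-ACGT bases are dropped, mirroring the documented scan contract.
    """
    records = []
    n = len(sequence)
    L, P = editor.spacer_length, editor.pam_length
    for strand, seq in (("+", sequence), ("-", _rc(sequence))):
        for i in range(n - (L + P) + 1):
            if editor.pam_side == "3prime":
                spacer = seq[i : i + L]
                pam = seq[i + L : i + L + P]
                spacer_lo = i  # 0-based within this strand's sequence
            else:
                pam = seq[i : i + P]
                spacer = seq[i + P : i + P + L]
                spacer_lo = i + P
            if any(b not in "ACGT" for b in spacer + pam):
                continue
            if any(b not in IUPAC_CODES[p] for p, b in zip(editor.pam, pam)):
                continue
            edits = []
            for p in range(editor.safety_start, editor.safety_end + 1):
                if spacer[p - 1] != editor.edit_from:
                    continue
                strand_pos = spacer_lo + p  # 1-based on this strand
                if strand == "+":
                    plus_pos = strand_pos
                    alt = editor.edit_to
                else:
                    plus_pos = n - strand_pos + 1
                    alt = _COMP[editor.edit_to]
                edits.append(
                    {
                        "pos": plus_pos,
                        "ref": sequence[plus_pos - 1],
                        "alt": alt,
                        "protospacer_position": p,
                        "in_window": editor.window_start <= p <= editor.window_end,
                        "distance_to_center": abs(
                            p - (editor.window_start + editor.window_end) / 2
                        ),
                    }
                )
            if strand == "+":
                start, end = spacer_lo + 1, spacer_lo + L
            else:
                start = n - (spacer_lo + L) + 1
                end = n - spacer_lo
            n_window = sum(e["in_window"] for e in edits)
            records.append(
                {
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "spacer": spacer,
                    "pam": pam,
                    "edits": edits,
                    "n_window": n_window,
                    "is_editing": n_window >= 1,
                    "specific": n_window == 1,
                }
            )
    records.sort(key=lambda r: (r["start"], r["strand"]))
    return records


# ---------------------------------------------------------------------------
# naive consequence classification (independent of bedesign.consequence)
# ---------------------------------------------------------------------------

def _naive_classify(ref_codon: str, alt_codon: str, codon_index: int) -> str:
    ref_aa, alt_aa = _AA[ref_codon], _AA[alt_codon]
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    if codon_index == 1 and alt_codon != "ATG":
        return "start_lost"
    return "synonymous" if ref_aa == alt_aa else "missense"


def naive_edit_consequence(pos: int, alt_plus: str, gene: dict) -> str:
    """Classify one plus-strand edit against a truth-table gene record."""
    cds_positions = gene["cds_positions"]  # transcript order
    if pos in cds_positions:
        idx = cds_positions.index(pos)
        codon_index = idx // 3 + 1
        off = idx % 3
        codon = gene["cds_seq"][3 * (codon_index - 1) : 3 * codon_index]
        alt_base = alt_plus if gene["strand"] == "+" else _COMP[alt_plus]
        alt_codon = codon[:off] + alt_base + codon[off + 1 :]
        return _naive_classify(codon, alt_codon, codon_index)
    if pos in gene["splice_positions"]:
        return "splice_site"
    if any(s <= pos <= e for s, e in gene["introns"]):
        return "intronic"
    if any(s <= pos <= e for s, e in gene["exons"]):
        return "utr"
    return "intergenic"


# ---------------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------------

_GENE_NAMES = ["ALPHA", "BRAVO", "CHARLIE", "DELTA", "ECHO", "FOXTROT"]
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass
class FixtureBundle:
    fasta: Path
    gtf: Path
    vcf: Path
    vcf_gz: Path
    truth: dict
    seed: int
    params: dict = field(default_factory=dict)


def _rand_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _rand_intergenic(rng: random.Random, n: int, pam_density: float) -> str:
    # pam_density 0 -> A/T only, so no NGG match on either strand
    return "".join(
        rng.choice("ACGT") if rng.random() < pam_density else rng.choice("AT")
        for _ in range(n)
    )


def _rand_cds(rng: random.Random, n_codons: int) -> str:
    codons = ["ATG"]
    sense = sorted(set(_AA) - set(_STOPS))
    for _ in range(n_codons - 2):
        codons.append(rng.choice(sense))
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def _partition(rng: random.Random, total: int, k: int, min_len: int) -> list[int]:
    lengths = []
    remaining = total
    for i in range(k - 1):
        hi = remaining - min_len * (k - i - 1)
        lengths.append(rng.randint(min_len, hi))
        remaining -= lengths[-1]
    lengths.append(remaining)
    return lengths


def _build_gene(rng: random.Random, name: str, strand: str,
                exons_per_gene: int) -> dict:
    """Build one gene block in transcript orientation, then mirror if minus.

    Returns block sequence (plus strand) and 1-based block-relative
    intervals for exons/CDS/start/stop, in ascending genomic order.
    """
    n_codons = rng.randint(30, 60)
    cds = _rand_cds(rng, n_codons)
    pieces = _partition(rng, len(cds), exons_per_gene, min_len=12)
    utr5 = _rand_seq(rng, rng.randint(15, 30))
    utr3 = _rand_seq(rng, rng.randint(15, 30))

    # transcript-orientation block coordinates (1-based)
    block_parts: list[str] = []
    exons_t: list[tuple[int, int]] = []
    cds_t: list[tuple[int, int]] = []
    cur = 0
    cds_off = 0
    for i, piece_len in enumerate(pieces):
        exon_seq = ""
        if i == 0:
            exon_seq += utr5
        cds_piece = cds[cds_off : cds_off + piece_len]
        cds_off += piece_len
        exon_seq += cds_piece
        if i == exons_per_gene - 1:
            exon_seq += utr3
        exon_s = cur + 1
        cds_s = exon_s + (len(utr5) if i == 0 else 0)
        block_parts.append(exon_seq)
        cur += len(exon_seq)
        exons_t.append((exon_s, cur))
        cds_t.append((cds_s, cds_s + piece_len - 1))
        if i < exons_per_gene - 1:
            intron = "GT" + _rand_seq(rng, rng.randint(56, 116)) + "AG"
            block_parts.append(intron)
            cur += len(intron)
    block = "".join(block_parts)
    start_t = (cds_t[0][0], cds_t[0][0] + 2)
    stop_t = (cds_t[-1][1] - 2, cds_t[-1][1])

    if strand == "-":
        n = len(block)
        block = _rc(block)
        flip = lambda iv: (n - iv[1] + 1, n - iv[0] + 1)  # noqa: E731
        exons_g = sorted(flip(iv) for iv in exons_t)
        cds_g = sorted(flip(iv) for iv in cds_t)
        start_g, stop_g = flip(start_t), flip(stop_t)
    else:
        exons_g, cds_g = exons_t, cds_t
        start_g, stop_g = start_t, stop_t

    # GTF frame per CDS segment, in transcript order
    frames = {}
    acc = 0
    order = cds_g if strand == "+" else list(reversed(cds_g))
    for s, e in order:
        frames[(s, e)] = (3 - acc % 3) % 3
        acc += e - s + 1
    return {
        "name": name,
        "strand": strand,
        "block": block,
        "exons": exons_g,
        "cds": cds_g,
        "frames": frames,
        "start_codon": start_g,
        "stop_codon": stop_g,
        "cds_seq": cds,
        "protein": "".join(_AA[cds[i : i + 3]] for i in range(0, len(cds), 3)),
        "n_exons": exons_per_gene,
    }


def _gtf_attrs(**kv) -> str:
    parts = [f'{k} "{v}";' for k, v in kv.items() if v is not None]
    return " ".join(parts)


def _splice_positions(exons: list[tuple[int, int]],
                      cds: list[tuple[int, int]]) -> set[int]:
    out: set[int] = set()

    def has_cds(exon):
        s, e = exon
        return any(s <= ce and cs <= e for cs, ce in cds)

    ex = sorted(exons)
    for left, right in zip(ex, ex[1:]):
        if right[0] <= left[1] + 1:
            continue
        if has_cds(left):
            out.update(range(left[1] + 1, min(left[1] + 3, right[0])))
        if has_cds(right):
            out.update(range(max(right[0] - 2, left[1] + 1), right[0]))
    return out


def make_fixture(
    seed: int,
    out_dir: str | Path,
    n_genes: int = 4,
    exons_per_gene: int = 3,
    intergenic_len: int = 400,
    planted_pam_density: float = 1.0,
    editors: list[BaseEditorConfig] | None = None,
    contig: str = "chrT",
) -> FixtureBundle:
    """Generate a deterministic FASTA+GTF+VCF bundle with a truth table.

    Genes alternate strands; the first gene carries a second,
    non-canonical transcript to exercise default-transcript resolution.
    ``planted_pam_density`` scales how PAM-prone the intergenic sequence
    is (0 means A/T-only intergenic DNA, hence no NGG guides there).
    """
    if n_genes < 1 or n_genes > len(_GENE_NAMES):
        raise ValueError(f"n_genes must be 1..{len(_GENE_NAMES)}")
    if exons_per_gene < 1:
        raise ValueError("exons_per_gene must be >= 1")
    if intergenic_len < 50:
        raise ValueError("intergenic_len must be >= 50 (degenerate fixture)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    genes = []
    seq_parts: list[str] = []
    cur = 0
    for gi in range(n_genes):
        gap = _rand_intergenic(rng, intergenic_len, planted_pam_density)
        seq_parts.append(gap)
        cur += len(gap)
        g = _build_gene(
            rng, _GENE_NAMES[gi], "+" if gi % 2 == 0 else "-", exons_per_gene
        )
        offset = cur
        g["offset"] = offset
        g["exons"] = [(s + offset, e + offset) for s, e in g["exons"]]
        g["cds"] = [(s + offset, e + offset) for s, e in g["cds"]]
        g["frames"] = {
            (s + offset, e + offset): f for (s, e), f in g["frames"].items()
        }
        g["start_codon"] = tuple(x + offset for x in g["start_codon"])
        g["stop_codon"] = tuple(x + offset for x in g["stop_codon"])
        seq_parts.append(g["block"])
        cur += len(g["block"])
        genes.append(g)
    tail = _rand_intergenic(rng, intergenic_len, planted_pam_density)
    seq_parts.append(tail)
    genome_seq = "".join(seq_parts)

    # ---- FASTA
    fasta = out_dir / "fixture.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome_seq), 60):
            fh.write(genome_seq[i : i + 60] + "\n")

    # ---- GTF
    gtf = out_dir / "fixture.gtf"
    lines = ["#!genome-build fixture"]

    def feat(feature, s, e, strand, frame, attrs):
        lines.append(
            f"{contig}\tfixture\t{feature}\t{s}\t{e}\t.\t{strand}\t{frame}\t{attrs}"
        )

    for gi, g in enumerate(genes):
        gene_id = f"FXG{gi + 1:04d}"
        span = (min(s for s, _ in g["exons"]), max(e for _, e in g["exons"]))
        feat("gene", span[0], span[1], g["strand"], ".",
             _gtf_attrs(gene_id=gene_id, gene_name=g["name"]))
        transcripts = [(f"FXT{gi + 1:04d}", f"{g['name']}-201", True)]
        if gi == 0:
            transcripts.append((f"FXT{gi + 1:04d}B", f"{g['name']}-202", False))
        for tid, tname, canonical in transcripts:
            base = dict(gene_id=gene_id, transcript_id=tid,
                        gene_name=g["name"], transcript_name=tname)
            tag = 'basic"; tag "Ensembl_canonical' if canonical else "basic"
            feat("transcript", span[0], span[1], g["strand"], ".",
                 _gtf_attrs(**base, tag=tag))
            exon_order = (
                g["exons"] if g["strand"] == "+" else list(reversed(g["exons"]))
            )
            for i, (s, e) in enumerate(exon_order, start=1):
                feat("exon", s, e, g["strand"], ".",
                     _gtf_attrs(**base, exon_number=i))
            cds_order = (
                g["cds"] if g["strand"] == "+" else list(reversed(g["cds"]))
            )
            # non-canonical transcript: truncated CDS, no start/stop features
            use_cds = cds_order if canonical else cds_order[:-1]
            for s, e in use_cds:
                feat("CDS", s, e, g["strand"], g["frames"][(s, e)],
                     _gtf_attrs(**base))
            if canonical:
                feat("start_codon", g["start_codon"][0], g["start_codon"][1],
                     g["strand"], 0, _gtf_attrs(**base))
                feat("stop_codon", g["stop_codon"][0], g["stop_codon"][1],
                     g["strand"], 0, _gtf_attrs(**base))
    with open(gtf, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    # ---- VCF with planted rsID SNVs inside gene 1's CDS
    def find_base(base: str, gene: dict) -> int:
        for s, e in gene["cds"]:
            for pos in range(s, e + 1):
                if genome_seq[pos - 1] == base:
                    return pos
        raise RuntimeError(f"fixture gene has no {base} in CDS")

    g0 = genes[0]
    planted = [
        {"rsid": "rs1000001", "pos": find_base("A", g0), "ref": "A",
         "alts": ["G"]},
        {"rsid": "rs1000002", "pos": find_base("C", g0), "ref": "C",
         "alts": ["T"]},
        {"rsid": "rs1000003", "pos": find_base("G", g0), "ref": "G",
         "alts": ["A", "T"]},
    ]
    ins_pos = find_base("T", g0)
    planted.append(
        {"rsid": "rs1000004", "pos": ins_pos, "ref": "T", "alts": ["TTA"]}
    )
    planted.sort(key=lambda r: r["pos"])
    vcf = out_dir / "fixture.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(genome_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in planted:
            fh.write(
                f"{contig}\t{rec['pos']}\t{rec['rsid']}\t{rec['ref']}\t"
                f"{','.join(rec['alts'])}\t.\t.\t.\n"
            )
    vcf_gz = out_dir / "fixture.vcf.gz"
    pysam.tabix_compress(str(vcf), str(vcf_gz), force=True)
    pysam.tabix_index(str(vcf_gz), preset="vcf", force=True)

    # ---- truth table, by construction (oracle + naive classification)
    if editors is None:
        from .editor_model import PRESETS

        editors = [PRESETS["ABE"], PRESETS["CBE"]]
    truth = {
        "contig": contig,
        "length": len(genome_seq),
        "sequence_md5": hashlib.md5(genome_seq.encode()).hexdigest(),
        "planted_variants": {
            r["rsid"]: {"pos": r["pos"], "ref": r["ref"], "alts": r["alts"]}
            for r in planted
        },
        "genes": {},
        "regions": {},
        "intergenic_region": None,
    }
    for g in genes:
        span = (min(s for s, _ in g["exons"]), max(e for _, e in g["exons"]))
        cds_positions = []
        order = g["cds"] if g["strand"] == "+" else list(reversed(g["cds"]))
        for s, e in order:
            rng_pos = range(s, e + 1) if g["strand"] == "+" else range(e, s - 1, -1)
            cds_positions.extend(rng_pos)
        gene_truth = {
            "name": g["name"],
            "transcript_name": f"{g['name']}-201",
            "strand": g["strand"],
            "span": span,
            "exons": g["exons"],
            "cds_segments": g["cds"],
            "introns": [
                (e1 + 1, s2 - 1)
                for (s1, e1), (s2, e2) in zip(sorted(g["exons"]),
                                              sorted(g["exons"])[1:])
                if s2 > e1 + 1
            ],
            "cds_positions": cds_positions,
            "cds_seq": g["cds_seq"],
            "protein": g["protein"],
            "splice_positions": sorted(
                _splice_positions(g["exons"], [(s, e) for s, e in g["cds"]])
            ),
            "start_codon": g["start_codon"],
            "stop_codon": g["stop_codon"],
        }
        gene_truth.update(
            _gene_mode_truth(genome_seq, gene_truth, editors)
        )
        truth["genes"][g["name"]] = gene_truth
        region = f"{contig}:{span[0]}-{span[1]}"
        truth["regions"][region] = _region_truth(
            genome_seq, span[0], span[1], editors
        )
    # a strictly intergenic region inside the leading gap
    ig_end = genes[0]["offset"] - 10
    ig_start = max(1, ig_end - (intergenic_len - 20))
    region = f"{contig}:{ig_start}-{ig_end}"
    truth["intergenic_region"] = {
        "region": region,
        **_region_truth(genome_seq, ig_start, ig_end, editors),
    }
    return FixtureBundle(
        fasta=fasta, gtf=gtf, vcf=vcf, vcf_gz=vcf_gz, truth=truth, seed=seed,
        params={
            "n_genes": n_genes, "exons_per_gene": exons_per_gene,
            "intergenic_len": intergenic_len,
            "planted_pam_density": planted_pam_density,
        },
    )


def _region_truth(genome_seq: str, start: int, end: int,
                  editors: list[BaseEditorConfig]) -> dict:
    n_editing = n_non_editing = 0
    for editor in editors:
        for rec in oracle_scan(genome_seq[start - 1 : end], editor):
            if rec["is_editing"]:
                n_editing += 1
            else:
                n_non_editing += 1
    return {"n_editing": n_editing, "n_non_editing": n_non_editing}


def _gene_mode_truth(genome_seq: str, gene: dict,
                     editors: list[BaseEditorConfig]) -> dict:
    """Naive re-derivation of gene-mode counts for one gene.

    Candidate space: guides whose window overlaps the CDS segments
    extended 2 nt into flanking introns, enumerated by the oracle over a
    widened span.
    """
    exons = sorted(gene["exons"])
    extended = []
    for s, e in sorted(gene["cds_segments"]):
        lo, hi = s, e
        for i, (xs, xe) in enumerate(exons):
            if xs <= s and e <= xe:
                if s == xs and i > 0:
                    lo = s - 2
                if e == xe and i < len(exons) - 1:
                    hi = e + 2
                break
        extended.append((lo, hi))
    margin = max(e.spacer_length + e.pam_length for e in editors)
    scan_s = max(1, min(s for s, _ in extended) - margin)
    scan_e = min(len(genome_seq), max(e for _, e in extended) + margin)
    sub = genome_seq[scan_s - 1 : scan_e]
    n_editing = n_specific = n_non_editing = 0
    unique: dict[tuple, str] = {}
    for editor in editors:
        for rec in oracle_scan(sub, editor):
            gstart = scan_s + rec["start"] - 1
            gend = scan_s + rec["end"] - 1
            if rec["strand"] == "+":
                ws, we = gstart + editor.window_start - 1, gstart + editor.window_end - 1
            else:
                ws, we = gend - editor.window_end + 1, gend - editor.window_start + 1
            if not any(s <= we and ws <= e for s, e in extended):
                continue
            if rec["is_editing"]:
                n_editing += 1
                if rec["specific"]:
                    n_specific += 1
                for ed in rec["edits"]:
                    if not ed["in_window"]:
                        continue
                    pos = scan_s + ed["pos"] - 1
                    key = (pos, genome_seq[pos - 1], ed["alt"])
                    unique[key] = naive_edit_consequence(pos, ed["alt"], gene)
            else:
                n_non_editing += 1
    from collections import Counter

    return {
        "n_editing": n_editing,
        "n_specific": n_specific,
        "n_non_editing": n_non_editing,
        "unique_edit_consequences": dict(Counter(unique.values())),
    }
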