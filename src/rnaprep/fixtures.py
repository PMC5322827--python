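"""Deterministic synthetic references and alignment scenarios.

Everything the test suite and the acceptance checks consume is generated
here: a pseudo-random reference, ten hand-built golden scenarios that
each exercise one pipeline rule (with independently written expected
outputs), and a randomized small-input generator for property testing
against a brute-force oracle.  All randomness flows through explicit
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PrepConfig

_BASES = "ACGT"

SCENARIOS = [
    "duplicate_cluster",
    "overlap_agree",
    "overlap_mismatch",
    "spliced_pair",
    "discordant_orientations",
    "cross_contig_pair",
    "soft_clipped",
    "mapq255",
    "single_vs_pair_dup",
    "exon_inconsistent_overlap",
]

#: default seed for the golden scenarios checked into the tests
DEFAULT_SEED = 20170317


def make_reference(n_contigs: int = 1, length: int = 2000, seed: int = 0) -> dict[str, str]:
    """Deterministic pseudo-random contigs, named chr1, chr2, ..."""
    if length < 200:
        raise ValueError("contig length must be >= 200")
    rng = np.random.default_rng(seed)
    return {
        f"chr{i + 1}": "".join(rng.choice(list(_BASES), size=length))
        for i in range(n_contigs)
    }


def reference_to_fasta(reference: dict[str, str]) -> str:
    lines = []
    for name, seq in reference.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), 70):
            lines.append(seq[i : i + 70])
    return "\n".join(lines) + "\n"


def write_fasta(reference: dict[str, str], path: str) -> str:
    """Write and faidx-index a reference; returns the path."""
    import pysam

    with open(path, "w") as fh:
        fh.write(reference_to_fasta(reference))
    pysam.faidx(path)
    return path


# ---------------------------------------------------------------------------
# SAM assembly helpers
# ---------------------------------------------------------------------------


def _other_base(base: str) -> str:
    return _BASES[(_BASES.index(base) + 1) % 4]


def _sam_header(reference: dict[str, str]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, seq in reference.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return lines


@dataclass
class _Rec:
    name: str
    flag: int
    reference: str
    pos: int  # 0-based
    mapq: int
    cigar: str
    seq: str
    quals: list[int]
    rnext: str = "*"
    pnext: int = -1  # 0-based; -1 -> unavailable
    tlen: int = 0

    def to_sam(self) -> str:
        qual = "".join(chr(q + 33) for q in self.quals)
        return "\t".join(
            [
                self.name,
                str(self.flag),
                self.reference,
                str(self.pos + 1),
                str(self.mapq),
                self.cigar,
                self.rnext,
                str(self.pnext + 1),
                str(self.tlen),
                self.seq,
                qual,
            ]
        )


def _records_to_sam(reference: dict[str, str], records: list[_Rec]) -> str:
    order = {name: i for i, name in enumerate(reference)}
    records = sorted(records, key=lambda r: (order[r.reference], r.pos))
    return "\n".join(_sam_header(reference) + [r.to_sam() for r in records]) + "\n"


def _pair_flags(orient: str, proper: bool) -> tuple[int, int]:
    """(read1 flag, read2 flag); read1 is the leftmost mate."""
    f1 = 0x1 | 0x40 | (0x2 if proper else 0)
    f2 = 0x1 | 0x80 | (0x2 if proper else 0)
    if orient == "FR":  # read1 forward, read2 reverse: inward
        return f1 | 0x20, f2 | 0x10
    if orient == "FF":  # both forward
        return f1, f2
    if orient == "outward":  # leftmost (read1) reverse, rightmost forward
        return f1 | 0x10, f2 | 0x20
    raise ValueError(orient)


def _expected(name, reference, pos, cigar, seq, quals, mapq=50, flag=0) -> dict:
    return {
        "name": name,
        "flag": flag,
        "reference": reference,
        "pos": pos,
        "mapq": mapq,
        "cigar": cigar,
        "seq": seq,
        "quals": tuple(quals),
    }


@dataclass
class Scenario:
    """One golden fixture: input SAM plus its hand-derived expectations."""

    name: str
    reference: dict[str, str]
    sam_text: str
    config: dict = field(default_factory=dict)
    expected_records: list[dict] = field(default_factory=list)
    #: input read name -> fate: kept / discarded-qc / discarded-duplicate /
    #: discarded-merge
    fates: dict[str, str] = field(default_factory=dict)

    def make_config(self, input_path: str, output_path: str) -> PrepConfig:
        return PrepConfig(input_path=input_path, output_path=output_path, **self.config)


def _fr_pair(name, contig, pos1, cigar1, seq1, q1, pos2, cigar2, seq2, q2,
             mapq=50, orient="FR", proper=True, contig2=None) -> list[_Rec]:
    contig2 = contig2 or contig
    f1, f2 = _pair_flags(orient, proper)
    rn1 = "=" if contig2 == contig else contig2
    rn2 = "=" if contig2 == contig else contig
    return [
        _Rec(name, f1, contig, pos1, mapq, cigar1, seq1, list(q1), rn1, pos2, 0),
        _Rec(name, f2, contig2, pos2, mapq, cigar2, seq2, list(q2), rn2, pos1, 0),
    ]


# ---------------------------------------------------------------------------
# Golden scenarios
# ---------------------------------------------------------------------------


def _sc_duplicate_cluster(ref):
    c = ref["chr1"]
    recs: list[_Rec] = []
    # three pairs, identical 5' keys; dupA has the top base-quality sum
    seqA1, seqA2 = c[100:176], c[300:376]
    qA1 = [35] * 76
    qA1[20] = 5  # low-quality base that dupC will overwrite
    recs += _fr_pair("dupA", "chr1", 100, "76M", seqA1, qA1, 300, "76M", seqA2, [35] * 76)
    seqB1 = list(c[100:176])
    seqB1[10] = _other_base(seqB1[10])  # credible conflict -> primary zeroed
    recs += _fr_pair("dupB", "chr1", 100, "76M", "".join(seqB1), [30] * 76,
                     300, "76M", c[300:376], [30] * 76)
    seqC1 = list(c[100:176])
    seqC1[20] = _other_base(seqC1[20])  # beats the primary's q5 base
    recs += _fr_pair("dupC", "chr1", 100, "76M", "".join(seqC1), [25] * 76,
                     300, "76M", c[300:376], [25] * 76)

    out_seq1 = list(c[100:176])
    out_seq1[20] = _other_base(out_seq1[20])
    out_q1 = [35] * 76
    out_q1[10] = 0   # dupB conflict, both qualities >= 10
    out_q1[20] = 25  # dupC base substituted over the q5 primary base
    expected = [
        _expected("dupA/1", "chr1", 100, "76M", "".join(out_seq1), out_q1),
        _expected("dupA/2", "chr1", 300, "76M", c[300:376], [35] * 76),
    ]
    fates = {"dupA": "kept", "dupB": "discarded-duplicate", "dupC": "discarded-duplicate"}
    return Scenario("duplicate_cluster", ref, _records_to_sam(ref, recs), {}, expected, fates)


def _sc_overlap_agree(ref):
    c = ref["chr1"]
    recs = _fr_pair("ovlA", "chr1", 500, "76M", c[500:576], [30] * 76,
                    540, "76M", c[540:616], [35] * 76)
    expected = [
        _expected("ovlA", "chr1", 500, "116M", c[500:616], [30] * 40 + [35] * 76),
    ]
    return Scenario("overlap_agree", ref, _records_to_sam(ref, recs), {},
                    expected, {"ovlA": "kept"})


def _sc_overlap_mismatch(ref):
    c = ref["chr1"]
    seq2 = list(c[540:616])
    seq2[10] = _other_base(seq2[10])  # disagrees with mate 1 at ref 550
    recs = _fr_pair("ovlM", "chr1", 500, "76M", c[500:576], [30] * 76,
                    540, "76M", "".join(seq2), [35] * 76)
    return Scenario("overlap_mismatch", ref, _records_to_sam(ref, recs), {},
                    [], {"ovlM": "discarded-merge"})


def _sc_spliced_pair(ref):
    c = ref["chr1"]
    seq1 = c[700:730] + c[830:876]  # 30M100N46M
    recs = _fr_pair("splA", "chr1", 700, "30M100N46M", seq1, [30] * 76,
                    830, "76M", c[830:906], [32] * 76)
    expected = [
        _expected("splA/1", "chr1", 700, "30M", c[700:730], [30] * 30),
        _expected("splA/2", "chr1", 830, "76M", c[830:906], [32] * 76),
    ]
    return Scenario("spliced_pair", ref, _records_to_sam(ref, recs), {},
                    expected, {"splA": "kept"})


def _sc_discordant_orientations(ref):
    c = ref["chr1"]
    recs = _fr_pair("sameS", "chr1", 1000, "76M", c[1000:1076], [30] * 76,
                    1100, "76M", c[1100:1176], [30] * 76, orient="FF")
    recs += _fr_pair("outw", "chr1", 1200, "76M", c[1200:1276], [30] * 76,
                     1400, "76M", c[1400:1476], [30] * 76, orient="outward")
    return Scenario("discordant_orientations", ref, _records_to_sam(ref, recs), {},
                    [], {"sameS": "discarded-qc", "outw": "discarded-qc"})


def _sc_cross_contig_pair(ref):
    c1, c2 = ref["chr1"], ref["chr2"]
    recs = _fr_pair("xctg", "chr1", 600, "76M", c1[600:676], [30] * 76,
                    600, "76M", c2[600:676], [30] * 76, contig2="chr2")
    return Scenario("cross_contig_pair", ref, _records_to_sam(ref, recs), {},
                    [], {"xctg": "discarded-qc"})


def _sc_soft_clipped(ref):
    c = ref["chr1"]
    cfg = {"soft_clips_exist": True, "min_flank_start": 3, "min_flank_end": 2}
    recs = _fr_pair("clipA", "chr1", 1000, "3S73M", "TTT" + c[1000:1073], [30] * 76,
                    1200, "76M", c[1200:1276], [30] * 76)
    recs += _fr_pair("clipB", "chr1", 1400, "76M", c[1400:1476], [28] * 76,
                     1600, "76M", c[1600:1676], [28] * 76)
    # masking hits only the soft-clipped read; its first three masked
    # cycles are the clipped bases themselves, stripped on output
    expected = [
        _expected("clipA/1", "chr1", 1000, "73M", c[1000:1073], [30] * 71 + [0, 0]),
        _expected("clipA/2", "chr1", 1200, "76M", c[1200:1276], [30] * 76),
        _expected("clipB/1", "chr1", 1400, "76M", c[1400:1476], [28] * 76),
        _expected("clipB/2", "chr1", 1600, "76M", c[1600:1676], [28] * 76),
    ]
    return Scenario("soft_clipped", ref, _records_to_sam(ref, recs), cfg,
                    expected, {"clipA": "kept", "clipB": "kept"})


def _sc_mapq255(ref):
    c = ref["chr1"]
    recs = _fr_pair("starA", "chr1", 1700, "76M", c[1700:1776], [33] * 76,
                    1740, "76M", c[1740:1816], [33] * 76, mapq=255)
    expected = [
        _expected("starA", "chr1", 1700, "116M", c[1700:1816], [33] * 116, mapq=50),
    ]
    return Scenario("mapq255", ref, _records_to_sam(ref, recs), {},
                    expected, {"starA": "kept"})


def _sc_single_vs_pair_dup(ref):
    c = ref["chr1"]
    cfg = {"properly_paired": False}
    recs = _fr_pair("pairD", "chr1", 100, "76M", c[100:176], [30] * 76,
                    300, "76M", c[300:376], [30] * 76)
    recs.append(_Rec("loneDup", 0, "chr1", 100, 50, "76M", c[100:176], [40] * 76))
    recs.append(_Rec("loneKeep", 0, "chr1", 900, 50, "76M", c[900:976], [20] * 76))
    expected = [
        _expected("pairD/1", "chr1", 100, "76M", c[100:176], [30] * 76),
        _expected("pairD/2", "chr1", 300, "76M", c[300:376], [30] * 76),
        _expected("loneKeep", "chr1", 900, "76M", c[900:976], [20] * 76),
    ]
    fates = {"pairD": "kept", "loneDup": "discarded-duplicate", "loneKeep": "kept"}
    return Scenario("single_vs_pair_dup", ref, _records_to_sam(ref, recs), cfg, expected, fates)


def _sc_exon_inconsistent_overlap(ref):
    c = ref["chr1"]
    seq1 = c[1500:1520] + c[1570:1626]  # 20M50N56M, junction reaches into the overlap
    recs = _fr_pair("exonX", "chr1", 1500, "20M50N56M", seq1, [30] * 76,
                    1550, "76M", c[1550:1626], [30] * 76)
    return Scenario("exon_inconsistent_overlap", ref, _records_to_sam(ref, recs), {},
                    [], {"exonX": "discarded-merge"})


_BUILDERS = {
    "duplicate_cluster": _sc_duplicate_cluster,
    "overlap_agree": _sc_overlap_agree,
    "overlap_mismatch": _sc_overlap_mismatch,
    "spliced_pair": _sc_spliced_pair,
    "discordant_orientations": _sc_discordant_orientations,
    "cross_contig_pair": _sc_cross_contig_pair,
    "soft_clipped": _sc_soft_clipped,
    "mapq255": _sc_mapq255,
    "single_vs_pair_dup": _sc_single_vs_pair_dup,
    "exon_inconsistent_overlap": _sc_exon_inconsistent_overlap,
}


def make_scenario(name: str, seed: int = DEFAULT_SEED) -> Scenario:
    """Build one golden scenario over a seeded reference.

    The expected outputs in the manifest are derived by hand-applying
    the rules in the builder, never by running the pipeline.
    """
    if name not in _BUILDERS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    ref = make_reference(n_contigs=2, length=2000, seed=seed)
    return _BUILDERS[name](ref)


# ---------------------------------------------------------------------------
# Randomized inputs for oracle-equivalence testing
# ---------------------------------------------------------------------------


def random_input(
    seed: int,
    n_fragments: int | None = None,
    contig_length: int = 3000,
    max_records: int = 40,
    error_rate: float = 0.005,
) -> tuple[str, dict[str, str]]:
    """A small random position-sorted SAM mixing every rule's trigger.

    Fragments are 76 bp paired-end with random inserts (overlapping and
    disjoint), optional single introns, PCR duplicate copies, soft
    clips, MAPQ values from the TopHat/STAR repertoire, occasional
    discordant orientations, cross-contig mates and unpaired reads
    (some sharing a pair's start).  Distinct fragments get distinct
    starts, as in a real library; duplicates share theirs by design.
    """
    rng = np.random.default_rng(seed)
    ref = make_reference(n_contigs=2, length=contig_length,
                         seed=int(rng.integers(2**31)))
    contigs = list(ref)
    records: list[_Rec] = []
    used_starts: set[tuple[str, int]] = set()
    pair_starts: list[tuple[str, int]] = []
    n_frag = int(rng.integers(6, 13)) if n_fragments is None else n_fragments

    def planted(cseq: str, lo: int, hi: int) -> str:
        bases = list(cseq[lo:hi])
        for i in range(len(bases)):
            if rng.random() < error_rate:
                bases[i] = _other_base(bases[i])
        return "".join(bases)

    def quals(n: int) -> list[int]:
        return [int(q) for q in rng.integers(2, 41, size=n)]

    def aligned_read(contig, genome, a, b, tj, ilen, lead_clip=0, trail_clip=0):
        """pos, cigar, seq over transcript interval [a, b)."""
        cseq = ref[contig]
        a2, b2 = a + lead_clip, b - trail_clip
        pos = genome(a2)
        parts = []
        if lead_clip:
            parts.append(("S", lead_clip, "".join(rng.choice(list(_BASES), size=lead_clip))))
        if tj is not None and a2 < tj < b2:
            parts.append(("M", tj - a2, planted(cseq, genome(a2), genome(a2) + (tj - a2))))
            parts.append(("N", ilen, ""))
            parts.append(("M", b2 - tj, planted(cseq, genome(tj), genome(tj) + (b2 - tj))))
        else:
            parts.append(("M", b2 - a2, planted(cseq, pos, pos + (b2 - a2))))
        if trail_clip:
            parts.append(("S", trail_clip, "".join(rng.choice(list(_BASES), size=trail_clip))))
        cigar = "".join(f"{n}{op}" for op, n, _ in parts)
        seq = "".join(s for _, _, s in parts)
        return pos, cigar, seq

    def draw_mapq() -> int:
        return int(rng.choice([255, 50, 45, 20, 3], p=[0.25, 0.35, 0.15, 0.15, 0.10]))

    for fi in range(n_frag):
        if len(records) + 2 > max_records:
            break
        contig = contigs[0] if rng.random() < 0.8 else contigs[1]
        flen = int(rng.integers(100, 301))
        spliced = rng.random() < 0.35
        ilen = int(rng.integers(60, 401)) if spliced else 0
        span = flen + ilen
        s = None
        for _ in range(50):
            cand = int(rng.integers(10, contig_length - span - 10))
            if (contig, cand) not in used_starts:
                s = cand
                break
        if s is None:
            continue
        used_starts.add((contig, s))
        tj = int(rng.integers(15, flen - 14)) if spliced else None

        def genome(t, _s=s, _tj=tj, _ilen=ilen):
            return _s + t + (_ilen if _tj is not None and t >= _tj else 0)

        name = f"f{fi}"

        if rng.random() < 0.15:  # unpaired read
            if rng.random() < 0.4 and pair_starts:
                dcontig, ds = pair_starts[int(rng.integers(len(pair_starts)))]
                pos, cigar, seq = ds, "76M", planted(ref[dcontig], ds, ds + 76)
                contig = dcontig
            else:
                pos, cigar, seq = aligned_read(contig, genome, 0, 76, tj, ilen)
            flag = 0x10 if rng.random() < 0.3 else 0
            records.append(_Rec(name, flag, contig, pos, draw_mapq(), cigar, seq, quals(76)))
            continue

        roll = rng.random()
        orient = "FF" if roll < 0.08 else "FR"
        cross = 0.08 <= roll < 0.13
        proper = rng.random() > 0.07

        mq1 = draw_mapq()
        mq2 = mq1 if rng.random() > 0.1 else draw_mapq()
        n_copies = 1
        if orient == "FR" and not cross and rng.random() < 0.3:
            n_copies += 1 + int(rng.random() < 0.3)

        for copy in range(n_copies):
            if len(records) + 2 > max_records:
                break
            cname = name if copy == 0 else f"{name}_d{copy}"
            lead1 = int(rng.integers(2, 7)) if (tj is None or not (0 < tj < 76)) and rng.random() < 0.2 else 0
            trail2 = int(rng.integers(2, 7)) if (tj is None or not (flen - 76 < tj < flen)) and rng.random() < 0.2 else 0
            pos1, cig1, seq1 = aligned_read(contig, genome, 0, 76, tj, ilen, lead_clip=lead1)
            if cross:
                other = contigs[1] if contig == contigs[0] else contigs[0]
                pos2 = int(rng.integers(10, contig_length - 86))
                cig2, seq2 = "76M", planted(ref[other], pos2, pos2 + 76)
                contig2 = other
            else:
                pos2, cig2, seq2 = aligned_read(contig, genome, flen - 76, flen, tj, ilen,
                                                trail_clip=trail2)
                contig2 = contig
            f1, f2 = _pair_flags(orient, proper)
            rn1 = "=" if contig2 == contig else contig2
            rn2 = "=" if contig2 == contig else contig
            records.append(_Rec(cname, f1, contig, pos1, mq1, cig1, seq1, quals(76), rn1, pos2, 0))
            records.append(_Rec(cname, f2, contig2, pos2, mq2, cig2, seq2, quals(76), rn2, pos1, 0))
            if copy == 0:
                pair_starts.append((contig, s))

    return _records_to_sam(ref, records), ref
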