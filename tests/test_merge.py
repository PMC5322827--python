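"""Flank masking, overlap merging, exon consistency and intron splitting."""

import pytest

from helpers import make_read
from rnaprep.merge import (
    emit_unit,
    exon_consistent,
    mask_flanks,
    merge_pair,
    overlap_window,
    split_at_introns,
)
from rnaprep.model import PrepConfig, ReadPair, layout_from_read, reference_span


def _pair(header, pos1=1000, cigar1="76M", pos2=1050, cigar2="76M",
          seq1=None, seq2=None, q1=30, q2=30):
    first = make_read(header, name="p", flag=99, pos=pos1, cigar=cigar1,
                      seq=seq1, quals=None if q1 is None else [q1] * 76)
    second = make_read(header, name="p", flag=147, pos=pos2, cigar=cigar2,
                       seq=seq2, quals=None if q2 is None else [q2] * 76)
    return ReadPair(first=first, second=second)


# --- flank masking ---------------------------------------------------------


def test_mask_forward_read_start(header):
    read = make_read(header)
    mask_flanks(read, PrepConfig(min_flank_start=3))
    assert list(read.query_qualities[:4]) == [0, 0, 0, 30]


def test_mask_zero_flanks_is_identity(header):
    read = make_read(header)
    mask_flanks(read, PrepConfig())
    assert set(read.query_qualities) == {30}


def test_mask_reverse_read_counts_in_sequencing_order(header):
    """A reverse alignment stores its sequencing start at the array tail."""
    read = make_read(header, flag=0x10)
    mask_flanks(read, PrepConfig(min_flank_start=3, min_flank_end=2))
    quals = list(read.query_qualities)
    assert quals[-3:] == [0, 0, 0] and quals[:2] == [0, 0]
    assert set(quals[2:-3]) == {30}


def test_mask_respects_soft_clip_conditional(header):
    cfg = PrepConfig(soft_clips_exist=True, min_flank_start=3)
    plain = make_read(header, cigar="76M")
    clipped = make_read(header, cigar="4S72M")
    mask_flanks(plain, cfg)
    mask_flanks(clipped, cfg)
    assert set(plain.query_qualities) == {30}
    assert list(clipped.query_qualities[:3]) == [0, 0, 0]


def test_mask_degenerate_flanks_zero_everything(header):
    read = make_read(header, cigar="4M", seq="ACGT", quals=[30] * 4)
    mask_flanks(read, PrepConfig(min_flank_start=3, min_flank_end=3))
    assert list(read.query_qualities) == [0, 0, 0, 0]


# --- overlap window and exon consistency -----------------------------------


@pytest.mark.parametrize(
    "pos2,expected",
    [(1050, (1050, 1076)), (1200, None), (1000, (1000, 1076))],
)
def test_overlap_window(header, pos2, expected):
    assert overlap_window(_pair(header, pos2=pos2)) == expected


def test_exon_consistency(header):
    both_plain = _pair(header, pos1=1000, pos2=1050)
    assert exon_consistent(both_plain)
    # junction inside the window on one mate only
    spliced = _pair(header, pos1=1000, cigar1="60M100N16M", pos2=1050)
    assert not exon_consistent(spliced)
    # the same junction on both mates
    both = _pair(header, pos1=1000, cigar1="60M100N16M",
                 pos2=1050, cigar2="10M100N66M")
    assert exon_consistent(both)
    # junction outside the window is no objection
    outside = _pair(header, pos1=1000, cigar1="20M100N56M", pos2=1140)
    assert reference_span(outside.first) == 176
    assert exon_consistent(outside)


# --- merging ---------------------------------------------------------------


def test_merge_agreeing_overlap_takes_max_quality(header):
    pair = _pair(header, q1=30, q2=35)
    (layout,) = merge_pair(pair, PrepConfig())
    assert layout.matches[1060] == ("A", 35)
    assert layout.matches[1010] == ("A", 30)
    assert layout.matches[1100] == ("A", 35)
    assert min(layout.matches) == 1000 and max(layout.matches) == 1125


def test_merge_mismatch_discards_by_default(header):
    seq2 = "C" + "A" * 75
    pair = _pair(header, seq2=seq2)
    assert merge_pair(pair, PrepConfig()) is None


def test_merge_mismatch_kept_and_zeroed_when_credible(header):
    seq2 = "C" + "A" * 75
    pair = _pair(header, seq2=seq2, q1=30, q2=35)
    (layout,) = merge_pair(pair, PrepConfig(keep_mismatches=True))
    assert layout.matches[1050] == ("A", 0)  # first-in-pair base, quality zeroed


def test_merge_mismatch_low_quality_base_loses(header):
    seq2 = "C" + "A" * 75
    pair = _pair(header, seq2=seq2, q1=5, q2=35)
    (layout,) = merge_pair(pair, PrepConfig(keep_mismatches=True))
    assert layout.matches[1050] == ("C", 35)


def test_disjoint_mates_stay_two_fragments(header):
    pair = _pair(header, pos2=1200)
    layouts = merge_pair(pair, PrepConfig())
    assert len(layouts) == 2
    reads = emit_unit("p", layouts, 50, header)
    assert [r.query_name for r in reads] == ["p/1", "p/2"]
    assert all(not r.is_paired and not r.is_reverse for r in reads)


# --- intron splitting ------------------------------------------------------


@pytest.mark.parametrize(
    "pos,cigar,expected",
    [
        (1000, "30M100N46M", [(1000, "30M"), (1130, "46M")]),
        (1000, "76M", [(1000, "76M")]),
        (1000, "20M50N30M60N26M", [(1000, "20M"), (1070, "30M"), (1160, "26M")]),
    ],
)
def test_split_fragment_arithmetic(header, pos, cigar, expected):
    read = make_read(header, pos=pos, cigar=cigar)
    frags = emit_unit("r", [layout_from_read(read)], 50, header)
    got = [(f.reference_start, f.cigarstring) for f in frags]
    assert got == expected
    if len(expected) > 1:
        assert [f.query_name for f in frags] == [f"r/{i+1}" for i in range(len(expected))]
    else:
        assert frags[0].query_name == "r"


def test_split_conserves_sequence_and_qualities(header):
    seq = "".join("ACGT"[i % 4] for i in range(76))
    quals = list(range(2, 78))
    read = make_read(header, pos=1000, cigar="20M50N30M60N26M", seq=seq, quals=quals)
    frags = emit_unit("r", [layout_from_read(read)], 50, header)
    assert "".join(f.query_sequence for f in frags) == seq
    assert [q for f in frags for q in f.query_qualities] == quals


def test_split_preserves_total_reference_span(header):
    read = make_read(header, pos=1000, cigar="20M50N30M60N26M")
    frags = split_at_introns(layout_from_read(read))
    skipped = 50 + 60
    spans = sum(max(f.matches) + 1 - min(f.matches) for f in frags)
    assert spans + skipped == reference_span(read)


def test_split_keeps_insertions_with_preceding_fragment(header):
    # 10M2I10M50N10M: the insertion is anchored inside the first exon
    read = make_read(header, pos=1000, cigar="10M2I10M50N10M",
                     seq="A" * 32, quals=[30] * 32)
    frags = emit_unit("r", [layout_from_read(read)], 50, header)
    assert [f.cigarstring for f in frags] == ["10M2I10M", "10M"]


def test_emitted_reads_have_no_skip_ops_and_forward_flags(header):
    read = make_read(header, flag=0x10 | 0x1 | 0x80, pos=1000, cigar="30M100N46M")
    frags = emit_unit("r", [layout_from_read(read)], 50, header)
    for f in frags:
        assert "N" not in f.cigarstring
        assert f.flag == 0
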