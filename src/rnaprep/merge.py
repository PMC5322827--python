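"""Flank masking, overlap merging and intron splitting.

Stage order matters: flank qualities are masked on the *original* reads
(sequencing-order ends), then overlapping mates are merged into a single
forward-strand read so the overlap is counted once, and finally every
intron-spanning read is split into its exonic fragments.  Output reads
never carry an N CIGAR operation and are always unpaired and on the
forward strand.
"""

from __future__ import annotations

import pysam

from .model import (
    Layout,
    PrepConfig,
    ReadPair,
    has_soft_clip,
    layout_from_read,
    layout_to_read,
    merge_intervals,
    reference_span,
)

#: quality boundary shared with dedup reconciliation: exactly 10 counts
#: as credible, so a credible-vs-credible overlap conflict is zeroed.
LOW_QUALITY = 10


def mask_flanks(read: pysam.AlignedSegment, cfg: PrepConfig) -> pysam.AlignedSegment:
    """Zero the first/last flank base qualities in sequencing order.

    For reverse-strand alignments the stored arrays are reference
    orientation, so the sequencing start is the tail of the array.  With
    ``soft_clips_exist`` set, only reads whose CIGAR contains soft clips
    are masked.  When the two flanks cover the whole read, every quality
    is zeroed and the read is retained.
    """
    n_start, n_end = cfg.min_flank_start, cfg.min_flank_end
    if n_start == 0 and n_end == 0:
        return read
    if cfg.soft_clips_exist and not has_soft_clip(read):
        return read
    quals = list(read.query_qualities)
    length = len(quals)
    head, tail = (n_end, n_start) if read.is_reverse else (n_start, n_end)
    for i in range(min(head, length)):
        quals[i] = 0
    for i in range(max(0, length - tail), length):
        quals[i] = 0
    read.query_qualities = quals
    return read


def overlap_window(pair: ReadPair) -> tuple[int, int] | None:
    """Intersection of the mates' aligned reference intervals, or None."""
    f, s = pair.reads
    lo = max(f.reference_start, s.reference_start)
    hi = min(
        f.reference_start + reference_span(f),
        s.reference_start + reference_span(s),
    )
    return (lo, hi) if lo < hi else None


def _junctions_in_window(
    junctions: list[tuple[int, int]], window: tuple[int, int]
) -> tuple[tuple[int, int], ...]:
    lo, hi = window
    clipped = [
        (max(a, lo), min(b, hi))
        for a, b in merge_intervals(junctions)
        if max(a, lo) < min(b, hi)
    ]
    return tuple(clipped)


def exon_consistent(pair: ReadPair) -> bool:
    """True when both mates imply the same exon structure in the overlap.

    The mates must agree on the intron (N) boundaries falling inside
    their overlap window; a disagreement means at least one mate was
    placed on the wrong exon and the mapping cannot be trusted.
    Non-overlapping pairs are vacuously consistent.
    """
    window = overlap_window(pair)
    if window is None:
        return True
    jf = _junctions_in_window(layout_from_read(pair.first).junctions, window)
    js = _junctions_in_window(layout_from_read(pair.second).junctions, window)
    return jf == js


def merge_layouts(
    first: Layout,
    second: Layout,
    window: tuple[int, int],
    keep_mismatches: bool,
) -> Layout | None:
    """Combine the mates' columns into one layout; None means discard.

    Agreeing overlap bases take the higher quality.  Disagreeing bases
    discard the pair unless ``keep_mismatches``; then a very-low-quality
    conflict keeps the higher-quality base while a credible conflict
    keeps the first-in-pair base at quality zero.  Insertions inside the
    overlap window come from the first-in-pair mate only.
    """
    matches: dict[int, tuple[str, int]] = dict(second.matches)
    for pos, (b1, q1) in first.matches.items():
        if pos not in matches:
            matches[pos] = (b1, q1)
            continue
        b2, q2 = matches[pos]
        if b1 == b2:
            matches[pos] = (b1, max(q1, q2))
        elif not keep_mismatches:
            return None
        elif q1 < LOW_QUALITY or q2 < LOW_QUALITY:
            matches[pos] = (b2, q2) if q2 > q1 else (b1, q1)
        else:
            matches[pos] = (b1, 0)
    lo, hi = window
    insertions = dict(first.insertions)
    for anchor, ins in second.insertions.items():
        if not lo <= anchor < hi and anchor not in insertions:
            insertions[anchor] = ins
    deletions = (first.deletions | second.deletions) - matches.keys()
    junctions = merge_intervals(first.junctions + second.junctions)
    return Layout(
        reference=first.reference,
        matches=matches,
        insertions=insertions,
        deletions=deletions,
        junctions=junctions,
    )


def merge_pair(pair: ReadPair, cfg: PrepConfig) -> list[Layout] | None:
    """Merge a QC-passed, flank-masked pair into output layouts.

    Overlapping mates yield one merged layout; disjoint mates are kept
    as the pair's two fragments.  None signals the pair is discarded
    (exon-inconsistent overlap, or an overlap mismatch with
    ``keep_mismatches`` unset).
    """
    window = overlap_window(pair)
    if window is None:
        return [layout_from_read(pair.first), layout_from_read(pair.second)]
    if not exon_consistent(pair):
        return None
    merged = merge_layouts(
        layout_from_read(pair.first),
        layout_from_read(pair.second),
        window,
        cfg.keep_mismatches,
    )
    return None if merged is None else [merged]


def split_at_introns(lay: Layout) -> list[Layout]:
    """Split a layout into its maximal intron-free fragments.

    One fragment per run of columns between N intervals; insertions
    attach to the fragment containing their anchor (a leading insertion
    joins the first fragment); deletions at a fragment edge are trimmed
    away with the uncovered columns.  A layout without junctions comes
    back unchanged.
    """
    junctions = merge_intervals(lay.junctions)
    if not junctions or not lay.matches:
        return [lay]

    def region_of(pos: int) -> int:
        r = 0
        for a, _ in junctions:
            if pos >= a:
                r += 1
        return r

    frags: dict[int, Layout] = {}
    for pos, col in sorted(lay.matches.items()):
        frags.setdefault(region_of(pos), Layout(reference=lay.reference)).matches[pos] = col
    ordered = [frags[k] for k in sorted(frags)]
    for frag in ordered:
        lo, hi = frag.start, frag.end
        frag.deletions = {p for p in lay.deletions if lo <= p < hi}
    for anchor, ins in lay.insertions.items():
        target = None
        for frag in ordered:
            if frag.start <= anchor < frag.end:
                target = frag
                break
        if target is None:  # leading insertion, or anchored in a skip
            target = ordered[0] if anchor < ordered[0].start else ordered[-1]
        target.insertions[anchor] = ins
    return ordered


def emit_unit(
    name: str,
    layouts: list[Layout],
    mapq: int,
    header: pysam.AlignmentHeader,
) -> list[pysam.AlignedSegment]:
    """Split a unit's layouts and build its output records.

    Fragments are numbered left to right; a unit producing a single
    fragment keeps its original name, otherwise fragments get an ordinal
    suffix (``name/1``, ``name/2``, ...) so downstream callers see
    unique names while the parent remains recoverable by prefix.  Every
    record is unpaired and forward strand.
    """
    frags: list[Layout] = []
    for lay in layouts:
        frags.extend(f for f in split_at_introns(lay) if f.matches)
    frags.sort(key=lambda f: (f.reference, f.start))
    multi = len(frags) > 1
    out: list[pysam.AlignedSegment] = []
    for i, frag in enumerate(frags, start=1):
        frag_name = f"{name}/{i}" if multi else name
        read = layout_to_read(frag, frag_name, mapq, header, flag=0)
        if read is not None:
            out.append(read)
    return out
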