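"""Data model and CIGAR algebra for spliced short-read alignments.

The pipeline operates on :class:`pysam.AlignedSegment` records throughout;
this module adds the small amount of alignment algebra the later stages
need on top of pysam: reference spans, unclipped 5' coordinates, and a
column-level :class:`Layout` view of a read used for overlap merging and
intron splitting.

All coordinates are 0-based, half-open.  Conversion to the 1-based SAM
text convention happens only inside pysam at file boundaries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pysam

# CIGAR operation codes as stored in BAM records.
CMATCH, CINS, CDEL, CREF_SKIP, CSOFT_CLIP, CHARD_CLIP, CPAD, CEQUAL, CDIFF = range(9)

#: operations that consume reference bases
REF_CONSUMING = frozenset({CMATCH, CDEL, CREF_SKIP, CEQUAL, CDIFF})
#: operations that consume query (read) bases
QUERY_CONSUMING = frozenset({CMATCH, CINS, CSOFT_CLIP, CEQUAL, CDIFF})
#: operations that align a query base to a reference base
ALIGN_OPS = frozenset({CMATCH, CEQUAL, CDIFF})


class PreprocessError(Exception):
    """Base class for errors raised by the pre-processing pipeline."""


class InputError(PreprocessError):
    """Malformed or unsupported input (unsorted file, bad flags, ...)."""


@dataclass
class PrepConfig:
    """User-facing parameters of the pre-processor.

    Parameters mirror the tool's command line:

    soft_clips_exist
        When True, flank masking is applied only to reads whose CIGAR
        contains soft clips (aggressive aligners mark troublesome read
        ends as soft clips; those reads carry most of the end errors).
    properly_paired
        When True (default) only intact read pairs are processed and
        orphan/unpaired reads are discarded.
    map_cutoff
        Minimum acceptable mapping quality for a read pair (default 40).
        Applied after MAPQ 255 ("unavailable", used by STAR for unique
        mappings) has been reassigned to 50.
    keep_mismatches
        Whether overlapping mates that disagree at one or more bases in
        the overlap are kept (reconciled) rather than discarded.
    min_flank_start, min_flank_end
        Number of base qualities zeroed at the start / end of each read
        in sequencing order, to silence error-prone first and last
        cycles (random-hexamer priming, late-cycle quality decay).
    """

    soft_clips_exist: bool = False
    properly_paired: bool = True
    map_cutoff: int = 40
    keep_mismatches: bool = False
    min_flank_start: int = 0
    min_flank_end: int = 0
    input_path: str | None = None
    output_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.map_cutoff <= 254:
            raise ValueError(f"map_cutoff must be in [0, 254], got {self.map_cutoff}")
        if self.min_flank_start < 0 or self.min_flank_end < 0:
            raise ValueError("flank lengths must be non-negative")


@dataclass
class ReadPair:
    """Two primary, mapped mates treated as one unit.

    ``first`` is the first-in-pair mate (0x40) when the flags allow the
    distinction; merge tie-breaks refer to it.
    """

    first: pysam.AlignedSegment
    second: pysam.AlignedSegment

    @property
    def reads(self) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
        return (self.first, self.second)

    @property
    def name(self) -> str:
        return self.first.query_name

    @property
    def leftmost(self) -> int:
        return min(self.first.reference_start, self.second.reference_start)


def _cigartuples(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    ct = read.cigartuples
    if ct is None:
        raise InputError(f"read {read.query_name!r} is unmapped or has no CIGAR")
    if any(op == CPAD for op, _ in ct):
        raise InputError(f"read {read.query_name!r} uses unsupported CIGAR padding (P)")
    return ct


def reference_span(read: pysam.AlignedSegment) -> int:
    """Total reference bases consumed by the alignment (M, D, N, =, X)."""
    return sum(n for op, n in _cigartuples(read) if op in REF_CONSUMING)


def leading_soft_clip(read: pysam.AlignedSegment) -> int:
    for op, n in _cigartuples(read):
        if op == CHARD_CLIP:
            continue
        return n if op == CSOFT_CLIP else 0
    return 0


def trailing_soft_clip(read: pysam.AlignedSegment) -> int:
    for op, n in reversed(_cigartuples(read)):
        if op == CHARD_CLIP:
            continue
        return n if op == CSOFT_CLIP else 0
    return 0


def has_soft_clip(read: pysam.AlignedSegment) -> bool:
    return any(op == CSOFT_CLIP for op, _ in _cigartuples(read))


def five_prime_coordinate(read: pysam.AlignedSegment) -> tuple[str, int, str]:
    """Unclipped sequencing-start coordinate of a mapped read.

    Forward reads start at their (soft-clip adjusted) left end, reverse
    reads at their right end.  Using the unclipped position makes the
    coordinate robust to aligners that clip differently across otherwise
    identical copies of a fragment.
    """
    if read.is_unmapped:
        raise InputError(f"read {read.query_name!r} is unmapped")
    if read.is_reverse:
        pos = read.reference_start + reference_span(read) - 1 + trailing_soft_clip(read)
        return (read.reference_name, pos, "-")
    return (read.reference_name, read.reference_start - leading_soft_clip(read), "+")


# ---------------------------------------------------------------------------
# Column-level layout view
# ---------------------------------------------------------------------------


@dataclass
class Layout:
    """A read decomposed into reference-anchored columns.

    ``matches`` maps each aligned reference position to the query
    ``(base, quality)`` observed there.  ``insertions`` holds inserted
    query bases anchored *after* a reference position (an insertion
    preceding the first aligned column is anchored at ``start - 1``).
    ``deletions`` is the set of deleted reference positions, and
    ``junctions`` the half-open intron (N) intervals.  Soft- and
    hard-clipped bases are not represented: by the time a read reaches
    this view its clipped bases have already had their say (flank
    masking inspects the raw record) and must not reach a variant
    caller as aligned evidence.
    """

    reference: str
    matches: dict[int, tuple[str, int]] = field(default_factory=dict)
    insertions: dict[int, tuple[str, list[int]]] = field(default_factory=dict)
    deletions: set[int] = field(default_factory=set)
    junctions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(self.matches)

    @property
    def end(self) -> int:
        return max(self.matches) + 1


def layout_from_read(read: pysam.AlignedSegment) -> Layout:
    """Decompose a mapped read into a :class:`Layout`."""
    lay = Layout(reference=read.reference_name)
    seq = read.query_sequence or ""
    quals = list(read.query_qualities) if read.query_qualities is not None else [0] * len(seq)
    r = read.reference_start
    q = 0
    for op, n in _cigartuples(read):
        if op in ALIGN_OPS:
            for i in range(n):
                lay.matches[r + i] = (seq[q + i], quals[q + i])
            r += n
            q += n
        elif op == CINS:
            anchor = r - 1
            if anchor in lay.insertions:
                s0, q0 = lay.insertions[anchor]
                lay.insertions[anchor] = (s0 + seq[q : q + n], q0 + quals[q : q + n])
            else:
                lay.insertions[anchor] = (seq[q : q + n], quals[q : q + n])
            q += n
        elif op == CDEL:
            lay.deletions.update(range(r, r + n))
            r += n
        elif op == CREF_SKIP:
            lay.junctions.append((r, r + n))
            r += n
        elif op == CSOFT_CLIP:
            q += n
        # hard clips consume nothing we track
    return lay


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _classify_gap(lo: int, hi: int, junctions: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Split the uncovered reference gap [lo, hi) into N and D runs.

    Positions inside a junction interval become N, the rest D.  Returns
    (op, start, length) runs in order.
    """
    runs: list[tuple[int, int, int]] = []
    pos = lo
    starts = [j[0] for j in junctions]
    while pos < hi:
        idx = bisect.bisect_right(starts, pos) - 1
        if idx >= 0 and junctions[idx][0] <= pos < junctions[idx][1]:
            nxt = min(hi, junctions[idx][1])
            runs.append((CREF_SKIP, pos, nxt - pos))
        else:
            nxt = hi
            if idx + 1 < len(junctions):
                nxt = min(hi, junctions[idx + 1][0])
            runs.append((CDEL, pos, nxt - pos))
        pos = nxt
    return runs


def layout_to_read(
    lay: Layout,
    name: str,
    mapq: int,
    header: pysam.AlignmentHeader,
    flag: int = 0,
) -> pysam.AlignedSegment | None:
    """Rebuild an alignment record from a layout.

    Returns None when the layout holds no aligned columns (a fragment
    consisting only of clips or insertions).  Leading/trailing deletions
    are trimmed implicitly: the record spans exactly the matched columns.
    """
    if not lay.matches:
        return None
    cols = sorted(lay.matches)
    junctions = merge_intervals(lay.junctions)

    cigar: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    qual_parts: list[int] = []

    def push(op: int, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    def push_insertion(anchor: int) -> None:
        if anchor in lay.insertions:
            s, q = lay.insertions[anchor]
            push(CINS, len(s))
            seq_parts.append(s)
            qual_parts.extend(q)

    # insertions anchored before the first aligned column
    for anchor in sorted(a for a in lay.insertions if a < cols[0]):
        s, q = lay.insertions[anchor]
        push(CINS, len(s))
        seq_parts.append(s)
        qual_parts.extend(q)

    prev: int | None = None
    for p in cols:
        if prev is not None and p > prev + 1:
            for op, _, n in _classify_gap(prev + 1, p, junctions):
                push(op, n)
        base, q = lay.matches[p]
        push(CMATCH, 1)
        seq_parts.append(base)
        qual_parts.append(q)
        push_insertion(p)
        prev = p

    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.flag = flag
    read.reference_id = header.get_tid(lay.reference)
    read.reference_start = cols[0]
    read.mapping_quality = mapq
    read.cigartuples = cigar
    read.query_sequence = "".join(seq_parts)
    read.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in qual_parts)
    )
    read.next_reference_id = -1
    read.next_reference_start = -1
    read.template_length = 0
    return read
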