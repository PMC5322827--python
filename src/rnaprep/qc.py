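"""Read- and pair-level quality control.

These filters run before any other processing: secondary/supplementary
alignments and low-MAPQ reads go first, then pair geometry is checked
(same-strand, outward-pointing and cross-contig pairs are untrustworthy
alignments), and finally orphan reads are admitted or discarded depending
on the ``properly_paired`` setting.
"""

from __future__ import annotations

from typing import Iterable

import pysam

from .model import PrepConfig, ReadPair

#: MAPQ value meaning "unavailable" in the SAM specification, emitted by
#: STAR for uniquely mapped reads.
MAPQ_UNAVAILABLE = 255
#: Replacement value assigned to such reads (TopHat's unique-mapping value).
MAPQ_REASSIGNED = 50


def effective_mapq(read: pysam.AlignedSegment) -> int:
    """Mapping quality after the 255 -> 50 reassignment, without mutation."""
    mq = read.mapping_quality
    return MAPQ_REASSIGNED if mq == MAPQ_UNAVAILABLE else mq


def reassign_mapq(read: pysam.AlignedSegment) -> pysam.AlignedSegment:
    """Rewrite MAPQ 255 ("not available") to 50 in place.

    Uniquely mapped STAR reads would otherwise be indistinguishable from
    reads with no mapping confidence at all.
    """
    read.mapping_quality = effective_mapq(read)
    return read


def passes_single_read_qc(read: pysam.AlignedSegment, cfg: PrepConfig) -> bool:
    """Per-record filter: mapped, primary, and MAPQ at or above the cutoff.

    Reads with MAPQ exactly equal to the cutoff pass ("lower than the
    cutoff" is strict).  Supplementary alignments are treated like
    secondary ones: both are non-primary descriptions of a read.
    """
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    return effective_mapq(read) >= cfg.map_cutoff


def passes_pair_qc(pair: ReadPair, cfg: PrepConfig) -> bool:
    """Pair-geometry filter.

    Rejects pairs whose mates map to different contigs, align on the
    same strand, or point outwards (leftmost mate on the reverse
    strand); rejects pairs whose weaker mate falls below the MAPQ
    cutoff; and, when ``properly_paired`` is set, pairs the aligner did
    not flag as proper.  Mates starting at the same position are treated
    as inward-pointing.
    """
    f, s = pair.reads
    if f.reference_id != s.reference_id:
        return False
    if f.is_reverse == s.is_reverse:
        return False
    left, right = (f, s) if f.reference_start <= s.reference_start else (s, f)
    if left.reference_start != right.reference_start and left.is_reverse and not right.is_reverse:
        return False
    if min(effective_mapq(f), effective_mapq(s)) < cfg.map_cutoff:
        return False
    if cfg.properly_paired and not (f.is_proper_pair and s.is_proper_pair):
        return False
    return True


def admit_single_reads(
    reads: Iterable[pysam.AlignedSegment], cfg: PrepConfig
) -> list[pysam.AlignedSegment]:
    """Keep or discard reads whose mate is absent or unmapped.

    With ``properly_paired`` (the default) such reads are discarded;
    otherwise they are retained and flow through deduplication and
    intron splitting (they are never overlap-merged).
    """
    if cfg.properly_paired:
        return []
    return list(reads)
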