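"""Shared helpers for running the pipeline on in-memory SAM text."""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pysam

from rnaprep.model import PrepConfig
from rnaprep.pipeline import run_pipeline


def run_sam(sam_text: str, tmp_path: Path, **cfg_kwargs):
    """Write SAM text, run the pipeline, return (records, summary, out path)."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    inp = tmp_path / "in.sam"
    inp.write_text(sam_text)
    out = tmp_path / "out.bam"
    cfg = PrepConfig(input_path=str(inp), output_path=str(out), **cfg_kwargs)
    summary = run_pipeline(cfg)
    with pysam.AlignmentFile(str(out)) as fh:
        records = list(fh)
    return records, summary, out


def record_tuple(read: pysam.AlignedSegment) -> tuple:
    return (
        read.query_name,
        read.flag,
        read.reference_name,
        read.reference_start,
        read.mapping_quality,
        read.cigarstring,
        read.query_sequence,
        tuple(read.query_qualities or ()),
    )


def pileup_of_records(records) -> dict:
    """{(contig, pos): Counter(base)} over non-zero-quality aligned bases."""
    pile: dict = {}
    for read in records:
        seq = read.query_sequence
        quals = read.query_qualities
        for qpos, rpos in read.get_aligned_pairs():
            if qpos is None or rpos is None:
                continue
            if quals[qpos] > 0:
                pile.setdefault((read.reference_name, rpos), Counter())[seq[qpos]] += 1
    return {k: v for k, v in pile.items() if v}


def make_read(
    header: pysam.AlignmentHeader,
    name: str = "r",
    flag: int = 0,
    reference: str = "chr1",
    pos: int = 100,
    mapq: int = 50,
    cigar: str = "76M",
    seq: str | None = None,
    quals=None,
) -> pysam.AlignedSegment:
    """Construct a single alignment record for unit tests."""
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.flag = flag
    read.reference_id = header.get_tid(reference)
    read.reference_start = pos
    read.mapping_quality = mapq
    read.cigarstring = cigar
    qlen = sum(n for op, n in read.cigartuples or [] if op in (0, 1, 4, 7, 8))
    read.query_sequence = seq if seq is not None else "A" * qlen
    read.query_qualities = list(quals) if quals is not None else [30] * qlen
    return read


def plain_header(contigs={"chr1": 2000, "chr2": 2000}) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        }
    )
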