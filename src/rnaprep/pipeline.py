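"""End-to-end pre-processing pipeline: BAM in, cleaned sorted BAM out.

Stage order: per-record QC -> mate pairing -> pair QC -> duplicate
collapse -> flank masking -> overlap merging -> intron splitting ->
coordinate sort + index.  The input must already be position sorted;
the output is again sorted (deterministically, including among records
at the same position) and indexed, ready for a haplotype-based caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from . import __version__
from .dedup import deduplicate, pair_key, single_key
from .merge import emit_unit, mask_flanks, merge_pair
from .model import InputError, PrepConfig, ReadPair, layout_from_read
from .qc import admit_single_reads, passes_pair_qc, reassign_mapq

log = logging.getLogger("rnaprep")


@dataclass
class RunSummary:
    """Per-stage record accounting for one pipeline run."""

    input_records: int = 0
    qc_discarded: int = 0
    duplicate_discarded: int = 0
    merge_discarded: int = 0
    fragments_emitted: int = 0
    output_path: str | None = None
    #: duplicate keys of the units (pairs/singles) that produced output;
    #: dedup guarantees these are unique per run.
    unit_keys: list[tuple] = field(default_factory=list)


def pair_collector(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[ReadPair], list[pysam.AlignedSegment]]:
    """Match mates by name in a position-sorted stream of primaries.

    Reads whose mate never arrives (absent, unmapped or filtered) come
    back as singles.  More than two primary records under one name is
    malformed input and raises :class:`InputError`.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    complete: set[str] = set()
    pairs: list[ReadPair] = []
    singles: list[pysam.AlignedSegment] = []
    for read in records:
        if not read.is_paired:
            if read.query_name in complete or read.query_name in pending:
                raise InputError(
                    f">2 primary records named {read.query_name!r} in input"
                )
            singles.append(read)
            continue
        name = read.query_name
        if name in complete:
            raise InputError(f">2 primary records named {name!r} in input")
        mate = pending.pop(name, None)
        if mate is None:
            pending[name] = read
        else:
            if read.is_read1 and not mate.is_read1:
                pairs.append(ReadPair(first=read, second=mate))
            else:
                pairs.append(ReadPair(first=mate, second=read))
            complete.add(name)
    singles.extend(pending.values())
    return pairs, singles


def _checked_sorted(
    records: Iterator[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    last_tid = -1
    last_pos = -1
    for read in records:
        if read.is_unmapped:
            yield read
            continue
        tid, pos = read.reference_id, read.reference_start
        if tid < last_tid or (tid == last_tid and pos < last_pos):
            raise InputError(
                f"input is not coordinate-sorted at record {read.query_name!r}"
            )
        last_tid, last_pos = tid, pos
        yield read


def _output_header(header: pysam.AlignmentHeader, cfg: PrepConfig) -> pysam.AlignmentHeader:
    hd = header.to_dict()
    pg = hd.setdefault("PG", [])
    used = {entry.get("ID") for entry in pg}
    pg_id = "rnaprep"
    k = 1
    while pg_id in used:
        pg_id = f"rnaprep.{k}"
        k += 1
    cl = (
        f"rnaprep --SoftClipsExist {cfg.soft_clips_exist}"
        f" --ProperlyPaired {cfg.properly_paired}"
        f" --MapCutoff {cfg.map_cutoff}"
        f" --KeepMismatches {cfg.keep_mismatches}"
        f" --MinFlankStart {cfg.min_flank_start}"
        f" --MinFlankEnd {cfg.min_flank_end}"
    )
    pg.append({"ID": pg_id, "PN": "rnaprep", "VN": __version__, "CL": cl})
    return pysam.AlignmentHeader.from_dict(hd)


def run_pipeline(cfg: PrepConfig) -> RunSummary:
    """Run the full pre-processor as configured; returns stage counts.

    The output BAM at ``cfg.output_path`` is coordinate-sorted (ties
    broken by name, flag and CIGAR for reproducibility) and indexed.
    """
    if cfg.input_path is None or cfg.output_path is None:
        raise ValueError("PrepConfig.input_path and output_path are required")
    summary = RunSummary(output_path=cfg.output_path)

    with pysam.AlignmentFile(cfg.input_path, check_sq=False) as fin:
        in_header = fin.header
        eligible: list[pysam.AlignedSegment] = []
        for read in _checked_sorted(iter(fin)):
            summary.input_records += 1
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                summary.qc_discarded += 1
                continue
            reassign_mapq(read)
            if read.mapping_quality < cfg.map_cutoff:
                summary.qc_discarded += 1
                continue
            eligible.append(read)

    pairs, singles = pair_collector(eligible)
    kept_pairs: list[ReadPair] = []
    for pair in pairs:
        if passes_pair_qc(pair, cfg):
            kept_pairs.append(pair)
        else:
            summary.qc_discarded += 2
    n_singles_before = len(singles)
    singles = admit_single_reads(singles, cfg)
    summary.qc_discarded += n_singles_before - len(singles)
    log.info("QC discarded %d of %d records", summary.qc_discarded, summary.input_records)

    kept_pairs, singles, summary.duplicate_discarded = deduplicate(kept_pairs, singles)
    log.info("duplicate collapse discarded %d records", summary.duplicate_discarded)

    for pair in kept_pairs:
        mask_flanks(pair.first, cfg)
        mask_flanks(pair.second, cfg)
    for read in singles:
        mask_flanks(read, cfg)

    out_header = _output_header(in_header, cfg)
    out_records: list[pysam.AlignedSegment] = []
    for pair in kept_pairs:
        layouts = merge_pair(pair, cfg)
        if layouts is None:
            summary.merge_discarded += 2
            log.debug("pair %r discarded at merge", pair.name)
            continue
        mapq = min(pair.first.mapping_quality, pair.second.mapping_quality)
        out_records.extend(emit_unit(pair.name, layouts, mapq, out_header))
        summary.unit_keys.append(pair_key(pair))
    for read in singles:
        out_records.extend(
            emit_unit(read.query_name, [layout_from_read(read)], read.mapping_quality, out_header)
        )
        summary.unit_keys.append(single_key(read))
    summary.fragments_emitted = len(out_records)
    log.info(
        "merge discarded %d records; emitted %d fragments",
        summary.merge_discarded,
        summary.fragments_emitted,
    )

    out_records.sort(
        key=lambda r: (
            r.reference_id,
            r.reference_start,
            r.query_name,
            r.flag,
            r.cigarstring or "",
        )
    )
    with pysam.AlignmentFile(cfg.output_path, "wb", header=out_header) as fout:
        for read in out_records:
            fout.write(read)
    pysam.index(cfg.output_path)
    return summary
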