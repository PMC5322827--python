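"""Per-cycle mismatch profiling for choosing flank-masking lengths.

Bases at the first few sequencing cycles (random-hexamer priming) and
the last few (quality decay, adapter read-through) mismatch the
reference far more often than interior bases.  This module measures the
mismatch fraction at each of the first and last K cycles — counting
positions in sequencing order, so reverse-strand alignments are read
from the right — and turns a user threshold into suggested
``MinFlankStart`` / ``MinFlankEnd`` values: the first cycle at which the
rate has fallen below the threshold (that cycle included), or 0 when
cycle 1 is already below it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
import pysam

from .model import ALIGN_OPS, CDEL, CINS, CREF_SKIP, CSOFT_CLIP, InputError, _cigartuples


@dataclass
class MismatchProfile:
    """Mismatch fractions at cycles 1..K from each read end.

    ``start_rates[i]`` / ``end_rates[i]`` are None where no aligned base
    was observed at that cycle.  ``n_start`` / ``n_end`` count aligned
    bases, ``mm_start`` / ``mm_end`` the mismatching ones.
    """

    k: int
    n_start: list[int]
    mm_start: list[int]
    n_end: list[int]
    mm_end: list[int]
    strand_scope: str = "first"

    @property
    def start_rates(self) -> list[float | None]:
        return [m / n if n else None for m, n in zip(self.mm_start, self.n_start)]

    @property
    def end_rates(self) -> list[float | None]:
        return [m / n if n else None for m, n in zip(self.mm_end, self.n_end)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side, n, mm, rates in (
            ("start", self.n_start, self.mm_start, self.start_rates),
            ("end", self.n_end, self.mm_end, self.end_rates),
        ):
            for i in range(self.k):
                rows.append(
                    {
                        "end": side,
                        "position": i + 1,
                        "aligned_bases": n[i],
                        "mismatches": mm[i],
                        "rate": rates[i],
                    }
                )
        return pd.DataFrame(rows)


def _in_scope(read: pysam.AlignedSegment, scope: str) -> bool:
    if scope == "all":
        return True
    if scope == "first":
        return read.is_paired and read.is_read1
    if scope == "second":
        return read.is_paired and read.is_read2
    raise ValueError(f"unknown strand scope {scope!r}")


def _aligned_ref_bases(
    read: pysam.AlignedSegment, reference: pysam.FastaFile | None
) -> list[tuple[int, str]]:
    """(query position, reference base) for every aligned base.

    Uses the MD tag when present, otherwise looks the bases up in the
    reference FASTA.  Soft-clipped and inserted bases have no reference
    base and are excluded.
    """
    if read.has_tag("MD"):
        out = []
        for qpos, _rpos, refbase in read.get_aligned_pairs(with_seq=True):
            if qpos is None or refbase is None:
                continue
            out.append((qpos, refbase.upper()))
        return out
    if reference is None:
        raise InputError(
            f"read {read.query_name!r} has no MD tag and no reference FASTA was given"
        )
    ref_seq = reference.fetch(
        read.reference_name, read.reference_start, read.reference_end
    ).upper()
    out = []
    r = 0
    q = 0
    for op, n in _cigartuples(read):
        if op in ALIGN_OPS:
            for i in range(n):
                out.append((q + i, ref_seq[r + i]))
            r += n
            q += n
        elif op == CINS:
            q += n
        elif op in (CDEL, CREF_SKIP):
            r += n
        elif op == CSOFT_CLIP:
            q += n
    return out


def compute_profile(
    reads,
    reference: pysam.FastaFile | None = None,
    k: int = 10,
    strand_scope: str = "first",
) -> MismatchProfile:
    """Count per-cycle mismatches over the first/last ``k`` cycles.

    ``reads`` is any iterable of mapped records (a ``pysam.AlignmentFile``
    works directly).  Cycle numbers count the full read length including
    soft-clipped cycles, since the error mechanisms are positional in
    the sequenced read; clipped bases themselves contribute no
    comparison.  By default only first-in-pair reads are profiled — the
    first strand carries the priming errors — and the resulting values
    are meant to be applied to all reads.
    """
    prof = MismatchProfile(
        k=k,
        n_start=[0] * k,
        mm_start=[0] * k,
        n_end=[0] * k,
        mm_end=[0] * k,
        strand_scope=strand_scope,
    )
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if not _in_scope(read, strand_scope):
            continue
        seq = read.query_sequence
        length = len(seq)
        for qpos, refbase in _aligned_ref_bases(read, reference):
            mismatch = seq[qpos].upper() != refbase
            s = length - qpos if read.is_reverse else qpos + 1  # 1-based cycle
            e = length - s + 1
            if s <= k:
                prof.n_start[s - 1] += 1
                prof.mm_start[s - 1] += int(mismatch)
            if e <= k:
                prof.n_end[e - 1] += 1
                prof.mm_end[e - 1] += int(mismatch)
    return prof


def _first_below(rates: list[float | None], threshold: float, k: int) -> int:
    defined = [(i, r) for i, r in enumerate(rates) if r is not None]
    if not defined:
        raise InputError("no defined mismatch rate on this side of the profile")
    for i, r in defined:
        if r < threshold:
            return 0 if i == 0 else i + 1
    warnings.warn(
        f"mismatch rate never falls below {threshold:g} within the first {k} cycles; "
        "consider a larger profiling window",
        stacklevel=3,
    )
    return k


def suggest_flanks(profile: MismatchProfile, threshold: float = 0.01) -> tuple[int, int]:
    """Flank lengths implied by a mismatch-rate threshold.

    Each side's value is the first (1-based) cycle whose rate is below
    the threshold — masking up to and including that cycle — or 0 when
    the very first cycle is already clean.  If the rate never drops
    below the threshold within the profiled window, the window size is
    returned with a warning.
    """
    start = _first_below(profile.start_rates, threshold, profile.k)
    end = _first_below(profile.end_rates, threshold, profile.k)
    return start, end


def write_table(profile: MismatchProfile, path: str) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def plot_profile(profile: MismatchProfile, path: str, threshold: float | None = None) -> None:
    """Bar plot of per-cycle mismatch rates at both read ends."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, side, rates in (
        (axes[0], "read start", profile.start_rates),
        (axes[1], "read end", profile.end_rates),
    ):
        xs = list(range(1, profile.k + 1))
        ys = [r if r is not None else 0.0 for r in rates]
        ax.bar(xs, [y * 100 for y in ys], color="#4878a8")
        if threshold is not None:
            ax.axhline(threshold * 100, color="crimson", ls="--", lw=1)
        ax.set_xlabel(f"position from {side}")
        ax.set_xticks(xs)
    axes[0].set_ylabel("mismatch rate (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
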