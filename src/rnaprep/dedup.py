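"""Duplicate detection and base reconciliation.

Duplicates are read pairs sharing both mates' unclipped 5' coordinates
and orientations (presumed PCR/optical copies of one fragment).  A
single read is pulled into a pair group, and discarded, when its 5'
coordinate matches either mate of the group.  Within each group the
member with the highest total base-quality sum becomes the primary;
every other member's bases are then folded into the primary:

* where the bases differ and either quality is below 10, the
  higher-quality base wins (the secondary's base can replace the
  primary's);
* where the bases differ and both qualities are >= 10, the primary's
  base stays but its quality is zeroed — two credible, conflicting
  observations should not vote at a SNP site.

This deliberately modifies the primary read, unlike conventional
duplicate markers (e.g. Picard MarkDuplicates), which only flag copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .model import ReadPair, five_prime_coordinate

#: base-quality boundary between "very low" and "credible"; a value of
#: exactly 10 falls on the credible (zeroing) side.
LOW_QUALITY = 10

SubKey = tuple[str, int, str]


def pair_key(pair: ReadPair) -> tuple[SubKey, SubKey]:
    """Canonical duplicate key of a pair: its two 5' sub-keys, sorted.

    Sorting makes the key independent of which mate carries the
    first-in-pair flag, so copies of a fragment sequenced in either
    orientation still collide.
    """
    a = five_prime_coordinate(pair.first)
    b = five_prime_coordinate(pair.second)
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def single_key(read: pysam.AlignedSegment) -> tuple[SubKey]:
    return (five_prime_coordinate(read),)


@dataclass
class DuplicateGroup:
    """All pairs/singles sharing one duplicate key."""

    key: tuple
    pairs: list[ReadPair] = field(default_factory=list)
    singles: list[pysam.AlignedSegment] = field(default_factory=list)


def quality_sum(member: ReadPair | pysam.AlignedSegment) -> int:
    if isinstance(member, ReadPair):
        return sum(member.first.query_qualities) + sum(member.second.query_qualities)
    return sum(member.query_qualities)


def _order_key(member: ReadPair | pysam.AlignedSegment):
    if isinstance(member, ReadPair):
        return (member.leftmost, member.name)
    return (member.reference_start, member.query_name)


def group_duplicates(
    pairs: list[ReadPair], singles: list[pysam.AlignedSegment]
) -> list[DuplicateGroup]:
    """Partition pairs and singles into duplicate groups.

    Singles whose coordinate matches a pair group's mate coordinate join
    that group (smallest key wins if several qualify); the rest form
    their own single-read groups.
    """
    groups: dict[tuple, DuplicateGroup] = {}
    by_subkey: dict[SubKey, list[tuple]] = {}
    for pair in pairs:
        key = pair_key(pair)
        grp = groups.setdefault(key, DuplicateGroup(key=key))
        grp.pairs.append(pair)
        for sub in key:
            by_subkey.setdefault(sub, []).append(key)
    for read in singles:
        sub = five_prime_coordinate(read)
        candidates = by_subkey.get(sub)
        if candidates:
            groups[min(candidates)].singles.append(read)
        else:
            key = (sub,)
            groups.setdefault(key, DuplicateGroup(key=key)).singles.append(read)
    return [groups[k] for k in sorted(groups)]


def select_primary(group: DuplicateGroup) -> ReadPair | pysam.AlignedSegment:
    """Highest base-quality-sum member; pairs outrank singles.

    Among pairs, properly-paired members are preferred.  Ties break by
    (leftmost position, read name) order so the choice is stable across
    runs and platforms.
    """
    if group.pairs:
        proper = [p for p in group.pairs if p.first.is_proper_pair and p.second.is_proper_pair]
        candidates: list = proper if proper else list(group.pairs)
    else:
        candidates = list(group.singles)
    if not candidates:
        raise ValueError("empty duplicate group")
    candidates.sort(key=_order_key)
    return max(candidates, key=quality_sum)  # max keeps the first of equals


def reconcile_bases(
    primary: pysam.AlignedSegment,
    secondary: pysam.AlignedSegment,
    zeroed: set[int],
) -> pysam.AlignedSegment:
    """Fold one secondary read's bases into the primary, in place.

    ``zeroed`` carries positions already zeroed by an earlier conflict in
    this group; those stay zeroed — a later duplicate must not resurrect
    a disputed base.  Only length, seq and quals are touched, never
    position or CIGAR.
    """
    pseq = list(primary.query_sequence)
    pqual = list(primary.query_qualities)
    sseq = secondary.query_sequence
    squal = secondary.query_qualities
    changed = False
    for i in range(len(pseq)):
        if i in zeroed or pseq[i] == sseq[i]:
            continue
        if pqual[i] < LOW_QUALITY or squal[i] < LOW_QUALITY:
            if squal[i] > pqual[i]:
                pseq[i] = sseq[i]
                pqual[i] = squal[i]
                changed = True
        else:
            pqual[i] = 0
            zeroed.add(i)
            changed = True
    if changed:
        primary.query_sequence = "".join(pseq)  # resets qualities in pysam
        primary.query_qualities = pqual
    return primary


def _reconcilable(a: pysam.AlignedSegment, b: pysam.AlignedSegment) -> bool:
    # identical placement makes per-base correspondence well defined
    return (
        a.cigarstring == b.cigarstring
        and a.reference_start == b.reference_start
        and a.query_length == b.query_length
    )


def _reconcile_pair_group(group: DuplicateGroup, primary: ReadPair) -> None:
    zeroed: dict[int, set[int]] = {id(primary.first): set(), id(primary.second): set()}
    sub_first = five_prime_coordinate(primary.first)
    sub_second = five_prime_coordinate(primary.second)
    for member in sorted(group.pairs, key=_order_key):
        if member is primary:
            continue
        if sub_first == sub_second:
            matched = [(primary.first, member.first), (primary.second, member.second)]
        else:
            matched = []
            for sec in member.reads:
                sub = five_prime_coordinate(sec)
                if sub == sub_first:
                    matched.append((primary.first, sec))
                elif sub == sub_second:
                    matched.append((primary.second, sec))
        for prim, sec in matched:
            if _reconcilable(prim, sec):
                reconcile_bases(prim, sec, zeroed[id(prim)])


def _reconcile_single_group(
    group: DuplicateGroup, primary: pysam.AlignedSegment
) -> None:
    zeroed: set[int] = set()
    for member in sorted(group.singles, key=_order_key):
        if member is primary:
            continue
        if _reconcilable(primary, member):
            reconcile_bases(primary, member, zeroed)


def deduplicate(
    pairs: list[ReadPair], singles: list[pysam.AlignedSegment]
) -> tuple[list[ReadPair], list[pysam.AlignedSegment], int]:
    """Collapse duplicate groups to their reconciled primaries.

    Returns (surviving pairs, surviving singles, number of discarded
    records).  Singles grouped with a pair are discarded without
    contributing bases.
    """
    out_pairs: list[ReadPair] = []
    out_singles: list[pysam.AlignedSegment] = []
    discarded = 0
    for group in group_duplicates(pairs, singles):
        primary = select_primary(group)
        if isinstance(primary, ReadPair):
            _reconcile_pair_group(group, primary)
            out_pairs.append(primary)
            discarded += 2 * (len(group.pairs) - 1) + len(group.singles)
        else:
            _reconcile_single_group(group, primary)
            out_singles.append(primary)
            discarded += len(group.singles) - 1
    out_pairs.sort(key=_order_key)
    out_singles.sort(key=_order_key)
    return out_pairs, out_singles, discarded
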