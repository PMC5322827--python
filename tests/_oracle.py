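"""Brute-force reference implementation of the pre-processing rules.

Used only as an independent oracle: it parses SAM text with its own
tiny parser (no pysam) and applies every rule naively over in-memory
lists, producing the per-position multiset of non-zero-quality bases
that the pipeline's output must reproduce.  Kept deliberately simple
and slow; correctness over elegance.
"""

from __future__ import annotations

import re
from collections import Counter

CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")
LOWQ = 10


class Rec:
    def __init__(self, fields):
        self.name = fields[0]
        self.flag = int(fields[1])
        self.ref = fields[2]
        self.pos = int(fields[3]) - 1
        self.mapq = int(fields[4])
        self.cigar = [(int(n), op) for n, op in CIG_RE.findall(fields[5])]
        self.cigar_str = fields[5]
        self.seq = list(fields[9])
        self.qual = [ord(c) - 33 for c in fields[10]]

    paired = property(lambda s: bool(s.flag & 0x1))
    proper = property(lambda s: bool(s.flag & 0x2))
    unmapped = property(lambda s: bool(s.flag & 0x4))
    reverse = property(lambda s: bool(s.flag & 0x10))
    read1 = property(lambda s: bool(s.flag & 0x40))
    secondary = property(lambda s: bool(s.flag & 0x100))
    supplementary = property(lambda s: bool(s.flag & 0x800))


def parse_sam(text):
    return [Rec(line.split("\t")) for line in text.splitlines()
            if line and not line.startswith("@")]


def ref_span(rec):
    return sum(n for n, op in rec.cigar if op in "MDN=X")


def lead_clip(rec):
    ops = [op for _, op in rec.cigar if op != "H"]
    lens = [n for n, op in rec.cigar if op != "H"]
    return lens[0] if ops and ops[0] == "S" else 0


def trail_clip(rec):
    ops = [op for _, op in rec.cigar if op != "H"]
    lens = [n for n, op in rec.cigar if op != "H"]
    return lens[-1] if ops and ops[-1] == "S" else 0


def five_key(rec):
    if rec.reverse:
        return (rec.ref, rec.pos + ref_span(rec) - 1 + trail_clip(rec), "-")
    return (rec.ref, rec.pos - lead_clip(rec), "+")


def columns(rec):
    """[(ref pos, base, qual)] for aligned (M/=/X) bases, clips dropped."""
    out = []
    r, q = rec.pos, 0
    for n, op in rec.cigar:
        if op in "M=X":
            for i in range(n):
                out.append((r + i, rec.seq[q + i], rec.qual[q + i]))
            r += n
            q += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
    return out


def junctions(rec):
    out = []
    r = rec.pos
    for n, op in rec.cigar:
        if op in "MD=X":
            r += n
        elif op == "N":
            out.append((r, r + n))
            r += n
    return out


def mask(rec, cfg):
    ns, ne = cfg.get("min_flank_start", 0), cfg.get("min_flank_end", 0)
    if ns == 0 and ne == 0:
        return
    if cfg.get("soft_clips_exist", False) and not any(op == "S" for _, op in rec.cigar):
        return
    L = len(rec.qual)
    head, tail = (ne, ns) if rec.reverse else (ns, ne)
    for i in range(min(head, L)):
        rec.qual[i] = 0
    for i in range(max(0, L - tail), L):
        rec.qual[i] = 0


def reconcile(primary, secondary, zeroed):
    for i in range(len(primary.seq)):
        if i in zeroed or primary.seq[i] == secondary.seq[i]:
            continue
        if primary.qual[i] < LOWQ or secondary.qual[i] < LOWQ:
            if secondary.qual[i] > primary.qual[i]:
                primary.seq[i] = secondary.seq[i]
                primary.qual[i] = secondary.qual[i]
        else:
            primary.qual[i] = 0
            zeroed.add(i)


def _member_order(member):
    if isinstance(member, tuple):
        return (min(member[0].pos, member[1].pos), member[0].name)
    return (member.pos, member.name)


def _qual_sum(member):
    if isinstance(member, tuple):
        return sum(member[0].qual) + sum(member[1].qual)
    return sum(member.qual)


def oracle_pileup(sam_text, cfg):
    """Apply every rule naively; return {(contig, pos): Counter(base)}.

    ``cfg`` is a plain dict with the PrepConfig field names.
    """
    cutoff = cfg.get("map_cutoff", 40)
    properly = cfg.get("properly_paired", True)
    keepmm = cfg.get("keep_mismatches", False)

    # --- per-record QC ---
    recs = []
    for r in parse_sam(sam_text):
        if r.unmapped or r.secondary or r.supplementary:
            continue
        if r.mapq == 255:
            r.mapq = 50
        if r.mapq < cutoff:
            continue
        recs.append(r)

    # --- mate pairing ---
    by_name = {}
    for r in recs:
        by_name.setdefault(r.name, []).append(r)
    pairs, singles = [], []
    for name, group in by_name.items():
        paired = [r for r in group if r.paired]
        if len(paired) == 2:
            first = paired[0] if paired[0].read1 or not paired[1].read1 else paired[1]
            second = paired[1] if first is paired[0] else paired[0]
            pairs.append((first, second))
        else:
            singles.extend(group)

    # --- pair QC ---
    kept = []
    for f, s in pairs:
        if f.ref != s.ref or f.reverse == s.reverse:
            continue
        left, right = (f, s) if f.pos <= s.pos else (s, f)
        if left.pos != right.pos and left.reverse and not right.reverse:
            continue
        if min(f.mapq, s.mapq) < cutoff:
            continue
        if properly and not (f.proper and s.proper):
            continue
        kept.append((f, s))
    pairs = kept
    singles = [] if properly else singles

    # --- duplicate grouping ---
    groups = {}
    sub_index = {}
    for pair in pairs:
        key = tuple(sorted((five_key(pair[0]), five_key(pair[1]))))
        groups.setdefault(key, {"pairs": [], "singles": []})["pairs"].append(pair)
        for sub in key:
            sub_index.setdefault(sub, []).append(key)
    for r in singles:
        sub = five_key(r)
        if sub in sub_index:
            groups[min(sub_index[sub])]["singles"].append(r)
        else:
            groups.setdefault((sub,), {"pairs": [], "singles": []})["singles"].append(r)

    surv_pairs, surv_singles = [], []
    for key in sorted(groups):
        g = groups[key]
        if g["pairs"]:
            proper_members = [p for p in g["pairs"] if p[0].proper and p[1].proper]
            cands = proper_members or g["pairs"]
            cands = sorted(cands, key=_member_order)
            primary = max(cands, key=_qual_sum)
            sub_map = {five_key(primary[0]): primary[0], five_key(primary[1]): primary[1]}
            same_sub = five_key(primary[0]) == five_key(primary[1])
            zeroed = {id(primary[0]): set(), id(primary[1]): set()}
            for member in sorted(g["pairs"], key=_member_order):
                if member is primary:
                    continue
                mates = (
                    [(primary[0], member[0]), (primary[1], member[1])]
                    if same_sub
                    else [(sub_map[five_key(m)], m) for m in member
                          if five_key(m) in sub_map]
                )
                for prim, sec in mates:
                    if (prim.cigar_str == sec.cigar_str and prim.pos == sec.pos
                            and len(prim.seq) == len(sec.seq)):
                        reconcile(prim, sec, zeroed[id(prim)])
            surv_pairs.append(primary)
        else:
            cands = sorted(g["singles"], key=_member_order)
            primary = max(cands, key=_qual_sum)
            zeroed = set()
            for member in cands:
                if member is primary:
                    continue
                if (primary.cigar_str == member.cigar_str and primary.pos == member.pos
                        and len(primary.seq) == len(member.seq)):
                    reconcile(primary, member, zeroed)
            surv_singles.append(primary)

    # --- flank masking ---
    for f, s in surv_pairs:
        mask(f, cfg)
        mask(s, cfg)
    for r in surv_singles:
        mask(r, cfg)

    # --- merging and pileup ---
    pile = {}

    def add(ref, cols):
        for pos, base, qual in cols:
            if qual > 0:
                pile.setdefault((ref, pos), Counter())[base] += 1

    for f, s in surv_pairs:
        lo = max(f.pos, s.pos)
        hi = min(f.pos + ref_span(f), s.pos + ref_span(s))
        if lo >= hi:  # disjoint mates: two fragments
            add(f.ref, columns(f))
            add(s.ref, columns(s))
            continue

        def clip(juncs):
            return tuple(sorted((max(a, lo), min(b, hi))
                                for a, b in juncs if max(a, lo) < min(b, hi)))

        if clip(junctions(f)) != clip(junctions(s)):
            continue  # exon-inconsistent: discard
        cf = {pos: (b, q) for pos, b, q in columns(f)}
        cs = {pos: (b, q) for pos, b, q in columns(s)}
        merged = dict(cs)
        bad = False
        for pos, (b1, q1) in cf.items():
            if pos not in merged:
                merged[pos] = (b1, q1)
                continue
            b2, q2 = merged[pos]
            if b1 == b2:
                merged[pos] = (b1, max(q1, q2))
            elif not keepmm:
                bad = True
                break
            elif q1 < LOWQ or q2 < LOWQ:
                merged[pos] = (b2, q2) if q2 > q1 else (b1, q1)
            else:
                merged[pos] = (b1, 0)
        if bad:
            continue
        add(f.ref, [(pos, b, q) for pos, (b, q) in merged.items()])

    for r in surv_singles:
        add(r.ref, columns(r))

    return {k: v for k, v in pile.items() if v}
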