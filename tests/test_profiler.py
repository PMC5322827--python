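"""Per-cycle mismatch profiling and flank suggestion."""

import warnings

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_read, plain_header
from rnaprep.fixtures import make_reference, write_fasta
from rnaprep.model import InputError
from rnaprep.profiler import MismatchProfile, compute_profile, suggest_flanks

OTHER = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _reads_with_planted_mismatches(ref, n_reads, start_mm, header, flag=0x1 | 0x40):
    """n_reads 76-mers over chr1; read i mismatches at cycle c (1-based)
    iff i < start_mm[c-1].  All reads forward, first-in-pair."""
    c = ref["chr1"]
    reads = []
    for i in range(n_reads):
        pos = 100 + 3 * i
        seq = list(c[pos : pos + 76])
        for cyc, n_mm in enumerate(start_mm, start=1):
            if i < n_mm:
                seq[cyc - 1] = OTHER[seq[cyc - 1]]
        reads.append(
            make_read(header, name=f"r{i}", flag=flag, pos=pos, cigar="76M",
                      seq="".join(seq))
        )
    return reads


@pytest.fixture(scope="module")
def ref():
    return make_reference(n_contigs=1, length=2000, seed=7)


@pytest.fixture(scope="module")
def fasta(ref, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    write_fasta(ref, str(path))
    return pysam.FastaFile(str(path))


def test_planted_rates_recovered_exactly(ref, fasta):
    header = plain_header()
    planted = [40, 20, 8, 5, 0, 0]
    reads = _reads_with_planted_mismatches(ref, 100, planted, header)
    prof = compute_profile(reads, fasta, k=6)
    assert prof.n_start == [100] * 6
    assert prof.mm_start == planted
    assert prof.start_rates == [0.40, 0.20, 0.08, 0.05, 0.0, 0.0]


def test_all_matching_reads_give_zero_rates(ref, fasta):
    header = plain_header()
    reads = _reads_with_planted_mismatches(ref, 20, [0] * 6, header)
    prof = compute_profile(reads, fasta, k=6)
    assert all(r == 0.0 for r in prof.start_rates)
    assert all(r == 0.0 for r in prof.end_rates)


def test_reverse_strand_counts_cycles_from_the_right(ref, fasta):
    """A reverse read's leftmost stored base is its last sequencing cycle,
    so a mismatch there lands at end position 1."""
    header = plain_header()
    c = ref["chr1"]
    seq = OTHER[c[500]] + c[501:576]
    read = make_read(header, flag=0x1 | 0x40 | 0x10, pos=500, cigar="76M", seq=seq)
    prof = compute_profile([read], fasta, k=4)
    assert prof.mm_end == [1, 0, 0, 0]
    assert prof.mm_start == [0, 0, 0, 0]


def test_md_tag_is_preferred_over_reference(ref):
    header = plain_header()
    read = make_read(header, flag=0x1 | 0x40, pos=500, cigar="6M",
                     seq="ACGTAC", quals=[30] * 6)
    read.set_tag("MD", "0G5")  # reference G under the first read base (A)
    prof = compute_profile([read], None, k=3)
    assert prof.mm_start == [1, 0, 0]


def test_missing_md_and_reference_is_an_error(header):
    read = make_read(header, flag=0x1 | 0x40)
    with pytest.raises(InputError):
        compute_profile([read], None, k=4)


def test_soft_clipped_cycles_contribute_no_comparison(ref, fasta):
    header = plain_header()
    c = ref["chr1"]
    read = make_read(header, flag=0x1 | 0x40, pos=500, cigar="3S73M",
                     seq="TTT" + c[500:573])
    prof = compute_profile([read], fasta, k=4)
    assert prof.n_start == [0, 0, 0, 1]  # cycles 1-3 are clipped


def test_strand_scope_filters_reads(ref, fasta):
    header = plain_header()
    first = _reads_with_planted_mismatches(ref, 5, [5, 0, 0], header)
    second = _reads_with_planted_mismatches(ref, 5, [0, 0, 0], header, flag=0x1 | 0x80)
    prof = compute_profile(first + second, fasta, k=3, strand_scope="first")
    assert prof.n_start[0] == 5 and prof.mm_start[0] == 5
    prof_all = compute_profile(first + second, fasta, k=3, strand_scope="all")
    assert prof_all.n_start[0] == 10


def _profile(start, end):
    k = len(start)
    return MismatchProfile(
        k=k,
        n_start=[1000] * k,
        mm_start=[int(r * 1000) for r in start],
        n_end=[1000] * k,
        mm_end=[int(r * 1000) for r in end],
    )


@pytest.mark.parametrize(
    "rates,threshold,expected",
    [
        ([0.02, 0.015, 0.008, 0.005], 0.01, 3),  # falls below at cycle 3
        ([0.001, 0.0, 0.0, 0.0], 0.01, 0),  # already clean at cycle 1
        ([0.02, 0.008, 0.005, 0.001], 0.01, 2),
    ],
)
def test_suggest_flanks_first_below_threshold(rates, threshold, expected):
    prof = _profile(rates, list(reversed(rates)))
    start, end = suggest_flanks(prof, threshold)
    assert start == expected
    # the end side mirrors the start rule on its own rate vector
    sym = _profile(rates, rates)
    assert suggest_flanks(sym, threshold) == (expected, expected)


def test_suggest_flanks_warns_when_never_below(recwarn):
    prof = _profile([0.05] * 4, [0.001] * 4)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        start, end = suggest_flanks(prof, 0.01)
    assert start == 4 and end == 0
    assert any("never falls below" in str(w.message) for w in caught)


@given(
    st.lists(st.floats(0, 0.2, allow_nan=False), min_size=1, max_size=8),
    st.floats(0.001, 0.1),
    st.floats(0.001, 0.1),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_suggest_flanks_monotone_in_threshold(rates, t_lo, t_hi):
    """A stricter (lower) threshold never suggests a smaller flank."""
    t_lo, t_hi = sorted((t_lo, t_hi))
    prof = _profile(rates, rates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strict, _ = suggest_flanks(prof, t_lo)
        lax, _ = suggest_flanks(prof, t_hi)
    assert strict >= lax
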