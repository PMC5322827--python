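# Methods

## Problem and model

Haplotype-based SNP callers perform local read assembly over windows of
at most a few kilobases.  Spliced RNA-seq alignments break this in two
ways: a read spanning a large intron looks like a single observation
stretching far beyond the assembly window, and the evidence callers use
to down-weight read ends and double-counted mate overlaps is lost if
reads are simply cut at splice junctions.  `rnaprep` resolves this by
encoding all read-level corrections *into the base qualities and read
structure first* — duplicate reconciliation, flank masking, overlap
merging — and only then splitting reads at `N` CIGAR operations.  After
that, base qualities are the single channel carrying uncertainty, so
the caller needs no recalibration or RNA-specific settings.

The stage order is fixed: per-record QC → mate pairing → pair QC →
duplicate collapse → flank masking → overlap merging → intron
splitting → sort/index.  Masking and merging act on the original,
unsplit reads by design; splitting last guarantees the encoded
information survives.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `MapCutoff` | 40 | minimum MAPQ for a read pair (min over mates, strict `<` fails). TopHat/STAR emit 0–3 for multimappers and 50/255 for unique mappings, so any value in 4–49 behaves identically for those aligners. |
| `ProperlyPaired` | True | require the aligner's proper-pair flag and discard orphan/unpaired reads. |
| `SoftClipsExist` | False | restrict flank masking to soft-clipped reads (useful for STAR, which marks error-dense read ends as clips). |
| `KeepMismatches` | False | keep overlapping mates that disagree inside the overlap, reconciling per base instead of discarding the pair. |
| `MinFlankStart` / `MinFlankEnd` | 0 | base qualities zeroed at the sequencing start/end of each read. Choose with `rnaprep-profile`. |

MAPQ 255 means "unavailable" in the SAM specification; it is rewritten
to 50 before the cutoff test so uniquely mapped STAR reads survive the
default cutoff.

## Numerical and tie-break choices

These points are underdetermined by the method's description; the
package fixes them as follows, and both the implementation and the
brute-force test oracle share the definitions.

* **Coordinates** are 0-based half-open internally; pysam converts at
  file boundaries.
* **Duplicate key**: unclipped 5′ coordinate + strand per mate, the two
  sub-keys sorted so the key does not depend on which mate is
  first-in-pair.  Unclipped (clip-adjusted) positions make the key
  robust to aligner clipping differences, matching standard
  duplicate-marking practice.  A single read joins a pair group when
  its sub-key equals either mate sub-key (smallest group key wins if
  several match) and is then discarded without contributing bases.
* **Primary selection**: highest total base-quality sum among
  properly-paired members (all pairs if none is proper; singles only in
  all-single groups).  Ties break by (leftmost position, read name),
  which two tests verify by permuting input order.
* **Reconciliation** folds secondaries into the primary one at a time
  in (position, name) order.  Quality exactly 10 counts as credible, so
  a 10-vs-10 conflict zeroes the primary quality rather than
  substituting.  A position zeroed by a credible conflict is frozen:
  later duplicates cannot resurrect it through the low-quality
  substitution branch (0 < 10 would otherwise re-trigger it).  Members
  whose CIGAR or position differs from the primary's are skipped —
  per-base correspondence is ill-defined across different placements.
* **Pair geometry**: "outward-pointing" means the leftmost-aligned mate
  is on the reverse strand; mates starting at the same coordinate are
  treated as inward.  Supplementary alignments are discarded alongside
  secondary ones.
* **Merging**: agreeing overlap bases take the max of the two qualities
  (two concordant observations; no fabricated combined score).  At a
  credible-vs-credible overlap conflict the first-in-pair base is kept
  at quality 0.  The merged read's MAPQ is the min of the mates'
  MAPQs, applied uniformly to all fragments a pair emits.
  Non-overlapping mates are emitted as the pair's two fragments rather
  than one read with an invented reference gap.  Insertions inside the
  overlap window are taken from the first-in-pair mate; indel-aware
  merging is out of scope.
* **Splitting**: one fragment per maximal `N`-free run; insertions
  attach to the fragment containing their anchor (leading insertions to
  the first fragment); deletions at fragment edges are trimmed.
  Fragments are numbered left to right; a unit emitting a single
  fragment keeps its original name.  Soft-clipped bases are removed
  from output (masking decisions are made on the pre-strip read, so a
  masked flank may fall on clipped bases).
* **Degenerate masking** (`MinFlankStart + MinFlankEnd ≥` read length)
  zeroes every quality and keeps the read.
* **Output order**: records are buffered in memory and sorted by
  (contig, position, name, flag, CIGAR) before writing.  The extra
  tie-break keys beyond plain coordinate sorting make repeated runs
  byte-identical in record content, which the fixed-point test relies
  on.  This trades streaming memory for determinism; at the intended
  scale (tens of millions of short reads) the output of a chromosome
  fits comfortably in memory, and the input is consumed as a stream.

## Mismatch profiler

For each mapped read in scope, every aligned base is classified as
match/mismatch against the reference — from the MD tag when present,
else from an indexed FASTA — and binned by its cycle number from the
read start and from the read end, counted in sequencing order (reverse
alignments are read from the right of the stored arrays; soft-clipped
cycles count toward position numbering but contribute no comparison).
By default only first-in-pair reads are profiled: the first strand
carries the random-hexamer priming errors, and the values chosen from
it are applied to all reads.  `suggest_flanks` returns, per side, the
first 1-based cycle whose rate is below the threshold — masking up to
and including that cycle — or 0 when cycle 1 is already below it, and
the window size `K` with a warning when the rate never drops below the
threshold.  The suggestion is monotone in the threshold (property
tested).

## Synthetic data

No external dataset is needed; all inputs are generated:

* `make_reference` — seeded i.i.d. nucleotide contigs.
* `make_scenario` — ten golden scenarios (duplicate cluster, agreeing
  and disagreeing overlaps, spliced pair, discordant orientations,
  cross-contig pair, soft clips, MAPQ 255, single-vs-pair duplicate,
  exon-inconsistent overlap), each with expected outputs derived by
  hand in the builder, never by running the pipeline.
* `random_input` — randomized small libraries of 76 bp paired-end
  fragments (the common short-read configuration): inserts of 100–300
  bp so overlapping and disjoint pairs both occur, 35% of fragments
  spliced with one 60–400 bp intron, 30% duplicated, 20% of reads
  soft-clipped, MAPQ drawn from the TopHat/STAR repertoire including
  255, and ~8%/5%/15% discordant, cross-contig and unpaired reads, with
  a 0.5% per-base error rate.  Distinct fragments get distinct starts,
  as in a real library; duplicate copies share theirs by construction.

This generator is a *rule-coverage stress mix*, not a faithful
transcriptome simulation: it has no expression structure, no shared
junctions between genes, uniform coverage, and exaggerated rates of
discordant events so every discard path is exercised in ≤ 40 records.
Passing the oracle-equivalence test therefore shows the rules are
implemented exactly as specified on every geometry the rules mention;
it does not measure variant-calling performance on real data, which
depends on aligner behaviour and library chemistry the generator does
not emulate.

## Verification strategy and problem sizes

The brute-force oracle (`tests/_oracle.py`) re-implements every rule
naively over lists, with its own SAM text parser, and reduces the
result to the per-position multiset of non-zero-quality bases — the
quantity a variant caller actually consumes.  The acceptance suite
compares pipeline output against it on 200 seeded random inputs of
≤ 40 records, cycling through five configuration mixes; the golden
scenarios are compared field-for-field against their manifests; and
structural invariants (no `N` ops, no secondary records, no MAPQ 255 or
sub-cutoff MAPQ, forward/unpaired flags, unique duplicate keys among
emitted units, sorted + indexed output) are asserted on every output.
Re-running the pipeline on its own output with `ProperlyPaired=False`
must reproduce it record-for-record.  These sizes keep the whole suite
in a few seconds while each random input still mixes several rule
triggers.

## Known limitations

* Indels are passed through but not reconciled across mates; merging is
  column-wise on reference-aligned bases.
* No CRAM input, no name-sorted input, no UMI- or optical-duplicate
  awareness; pre-set duplicate flags (0x400) from upstream tools are
  ignored — the pipeline performs its own duplicate collapse.
* RNA-editing sites are not excluded; downstream filtering is the
  caller's or the analyst's responsibility.
* The duplicate-key uniqueness guarantee applies to the units the
  collapse operates on (pairs and singles before splitting); two
  non-duplicate fragments may still coincidentally share a start
  coordinate after splitting.
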