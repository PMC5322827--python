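# rnaprep

Pre-processing of spliced RNA-seq alignments for reliable SNP calling.

RNA-seq reads can reveal DNA variants in expressed genes, but
haplotype-based variant callers (Platypus, GATK HaplotypeCaller) assume
DNA-like input: reads spanning multi-kilobase introns disrupt local
haplotype assembly, and naive intron splitting destroys the read-level
information — mate overlap, read-end context — that callers rely on.
`rnaprep` turns a position-sorted BAM from a splice-aware aligner
(TopHat, STAR, ...) into a cleaned, splice-free BAM a haplotype caller
can consume with minimal settings and no base-quality recalibration:

1. **QC filters** — drops secondary/supplementary alignments, reads with
   MAPQ below a cutoff (default 40), pairs on the same strand, pairs
   pointing outwards, and cross-contig pairs.  MAPQ 255 ("unavailable",
   STAR's unique-mapping value) is reassigned to 50 first.
2. **Duplicate collapse** — duplicates are pairs sharing both mates'
   unclipped 5′ coordinates and orientations; the copy with the highest
   base-quality sum survives.  Disagreeing bases are reconciled into the
   survivor: a conflict where either quality is < 10 keeps the
   higher-quality base, a conflict between two credible bases (both
   ≥ 10) keeps the primary base at quality 0.
3. **Flank masking** — the first `MinFlankStart` and last `MinFlankEnd`
   base qualities of each read (in sequencing order) are zeroed to
   silence random-hexamer priming errors at read starts and late-cycle
   errors at read ends; with `--SoftClipsExist True` only soft-clipped
   reads are masked.
4. **Overlap merging** — overlapping mates become one forward-strand,
   unpaired read so the overlap is counted once; agreeing bases take
   the higher quality, disagreeing overlaps are discarded unless
   `--KeepMismatches True` (then reconciled like duplicates).  Mates
   that disagree about the exon structure inside their overlap are
   discarded as untrustworthy mappings.
5. **Intron splitting** — every read spanning an `N` CIGAR operation is
   split into its exonic fragments (`name/1`, `name/2`, ...), and the
   output is coordinate-sorted and indexed.

A companion profiler (`rnaprep-profile`) measures the per-cycle mismatch
rate against the reference (MD tags or a FASTA) at both read ends and
suggests `MinFlankStart`/`MinFlankEnd`: the first cycle at which the
rate falls below a chosen threshold (default 1%).

## Worked example

The package ships a fixture generator; this builds a two-record SAM with
one read pair whose first mate spans a 100 bp intron (CIGAR
`30M100N46M` at position 701) and whose second mate covers the
downstream exon:

```sh
python -c "
from rnaprep.fixtures import make_scenario
open('demo.sam', 'w').write(make_scenario('spliced_pair').sam_text)"
rnaprep --BamFile demo.sam --OutFile demo_clean.bam
```

which prints

```
records in: 2  qc-discarded: 0  duplicate-discarded: 0  merge-discarded: 0  fragments out: 2
```

and `samtools view demo_clean.bam | cut -f1-9` shows

```
splA/1	0	chr1	701	50	30M	*	0	0
splA/2	0	chr1	831	50	76M	*	0	0
```

The pair was merged (the mates overlapped on the downstream exon, so the
overlap is counted once at the higher of the two base qualities) and
then split at the intron: fragment `splA/1` is the 30 bp upstream exon
piece, `splA/2` the 76 bp downstream piece starting right after the
100 bp skip (701 + 30 + 100 = 831).  Both fragments are unpaired, on the
forward strand, and carry no `N` operation, so a haplotype caller treats
them as ordinary DNA reads.

To choose masking lengths for a real sample:

```sh
rnaprep-profile --BamFile sample.bam --Reference genome.fa --K 10 --Threshold 0.01
```

prints a per-cycle table of aligned-base counts and mismatch rates and a
line such as `suggested MinFlankStart=3 MinFlankEnd=3 (threshold 0.01)`
— the rate fell below 1% at the third cycle from either end, so the
first/last three base qualities should be masked.

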