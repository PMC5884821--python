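# midel

Intermediate-size indel (50 bp – 10 kb) detection from short-read alignments,
plus a desk-scale paired-end simulator and benchmarking metrics.

Standard gapped aligners recover short indels directly, but events of
50 bp – 10 kb mostly surface as soft-clipped read tails and unmapped mates.
`midel` calls them in five stages:

1. **Classify & extract** (`clip_extraction`) — reads are sorted into
   high-quality soft-clipped reads (mapping quality > 20, clip length > 5,
   clip mean base quality > 20), unmapped reads with mapped mates, and plain
   mapped reads; clipped tails become breakpoint-oriented fragments (FWD =
   clip on the 3' end, BWD = clip on the 5' end).
2. **Cluster** (`clustering`) — same-orientation fragments sharing a
   breakpoint within 3 bp are grouped; unmapped reads are placed near their
   mates using the insert-size model and attached to nearby clusters.
3. **Consensus** (`consensus`) — each cluster's sequences are
   multiple-aligned (internal star alignment, or external MAFFT via
   `msa_mode: external`) and reduced to a majority-vote consensus fragment.
   Leftover unmapped reads are assembled with a greedy highest-count k-mer
   extender; contigs replace consensus fragments they contain.
4. **Pair, join & call** (`pairing_caller`) — FWD/BWD consensus fragments
   with compatible breakpoints are joined through their overlap into one
   sequence spanning the event, then aligned to the reference window
   (±5,000 bp around the forward breakpoint) with a glocal aligner — global
   in the query, local in the target, affine gaps with zero gap-extension so
   a multi-kilobase deletion costs a single gap opening.  Gap runs of
   50–10,000 bp with supporting depth ≥ 10 become calls; genotypes come from
   the variant allele fraction (hom at VAF ≥ 0.8).
5. **Evaluate** (`evaluation`) — calls are matched one-to-one against a
   truth table (position tolerance 10 bp, length tolerance 10%) and
   summarised as precision, recall and F-measure.

The simulator (`simulator`) plants insertions/deletions of configurable sizes
into 10 kb bins of a toy genome, draws paired-end reads
(Normal(500, 50) fragments, 2% base error, configurable point mutation rate,
75/150 bp reads at 100×/200×), and writes an *analytically mapped* SAM: read
origins are known, so match/soft-clip CIGARs, unmapped-mate records and
aligner-like extension through chance matches are emitted without running an
external aligner.  An `insert_mode: flank` switch copies the downstream flank
as the inserted sequence, reproducing the repetitive-insertion regime where
greedy assembly and clip anchoring degrade.

## CLI

```sh
# generate a dataset: ref.fa, truth.tsv, reads_1/2.fq, mapped.sam
midel simulate --out simdir --config sim.yaml --seed 1

# call indels (SAM/BAM + FASTA in, VCF 4.2 out)
midel call --bam simdir/mapped.sam --ref simdir/ref.fa --out calls.vcf

# score against the truth table
midel evaluate --calls calls.vcf --truth simdir/truth.tsv --out metrics.json
```

`midel call --config cfg.yaml` accepts any `midel.config.CallerConfig` key
(scoring parameters, flank size, size bounds, depth threshold, VAF cutoff,
clustering linkage, MSA mode, ...).

## Notes

- Internal coordinates are 0-based half-open; the one conversion to 1-based
  happens when writing VCF.
- The genotype rule (hom iff VAF ≥ 0.8) and the evaluation matching
  tolerances are configurable defaults; they are engineering choices, not
  published constants.
- Real-sample headline counts from the original benchmark (whole-exome
  datasets) are out of scope: only the metric arithmetic is reproduced.
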