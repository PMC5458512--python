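# srtail

Detection and quantification of **non-templated 3′ nucleotides ("tails")
on Argonaute-bound small RNAs**, modelled on fission-yeast RNAi: a
simulator with complete ground truth, a tail-calling aligner, a
strand-aware sRNA classifier, summary statistics, and between-genotype
comparison of siRNA gains and their silencing effect.

It is written for people analysing small-RNA sequencing libraries
(Argonaute immunoprecipitations or total size-selected sRNA) who need to
ask: *what fraction of reads carry 3′ additions, of which nucleotide, on
which sRNA classes, and what changes when a nucleotidyl transferase is
deleted?*

## The measurement

A non-templated 3′ nucleotide is a terminal read base that does not match
the genome at its aligned position. For a read *r* of length *L*, the
default **exact-prefix** caller finds the longest prefix *r*[0..*n*) with
a perfect genomic placement (over both strands); the residual suffix
*r*[*n*..*L*) is the tail, accepted when *n* ≥ 18 and *L* − *n* ≤ 3. By
maximality the first tail base always mismatches the templated base, which
is precisely what "non-templated" means operationally. A second mode,
**terminal-mismatch**, reproduces the conventional mapper-first pipeline:
full-length alignment with ≤ 2 substitutions, the tail being the maximal
run of mismatches ending at the 3′ terminus. Multimapping reads (e.g. from
identical centromeric dg/dh-like repeat copies) are assigned uniformly at
random, reproducibly from one seed.

Downstream, reads are classified by annotation overlap
(centromeric > tRNA > rRNA > mRNA exon > intronic > ncRNA > intergenic,
sense/antisense by strand), and summarised as per-class tailing fractions,
per-read and per-nucleotide tail composition (A-tail / U-tail / other),
length histograms, 5′-base preference and RPM (reads per million mapped).
Genotype comparisons use per-feature counts, pseudocounted fold changes
(a + ½)/(b + ½), threshold-based ectopic siRNA-gain calls, and the
two-sided Welch unequal-variance *t*-test for expression shifts.

The simulator generates a toy genome (2 × 50 kb, four byte-identical 3 kb
centromeric copies, mRNAs with introns, tRNA/rRNA/ncRNA loci), a GFF3
annotation and FASTQ reads with truth for every read: 20–30 nt (mode
22 nt), 5′-U preference 0.8, class-specific tailing (≈25 % for
centromeric/mRNA/ncRNA-derived reads, ≈5 % for tRNA and sense rRNA in wild
type), 1–2 nt adenine-dominant tails, and genotype presets in which
deleting the adenylating or uridylating transferase removes the
corresponding tails.

## Worked example

```sh
python analysis/01_simulate_samples.py   # genomes + 5 libraries -> scratch/samples/
python analysis/02_profile_tailing.py    # -> results/tailing_profile.tsv
```

which prints (20,000 reads per library, seed 1):

```
wt_ago           tailed=0.231 A=0.716 U=0.248 cen=0.604
wt_total         tailed=0.107 A=0.713 U=0.249 cen=0.255
cid14_ago        tailed=0.065 A=0.016 U=0.858 cen=0.600
cid16_ago        tailed=0.173 A=0.944 U=0.006 cen=0.601
cid14cid16_ago   tailed=0.010 A=0.108 U=0.091 cen=0.603

tailing loss across genotypes: wt 0.231 >= cid14 0.065 >= cid14cid16 0.010
```

Reading the wild-type Argonaute-bound row: 23 % of mapped reads carry a
called tail; 72 % of tail nucleotides are adenine and 25 % uridine; 60 %
of reads are centromeric siRNAs, against 25 % in the total-sRNA library.
Deleting the adenylating transferase (`cid14`) leaves mostly uridine
tails, deleting the uridylating one (`cid16`) leaves adenine tails, and
the double deletion abolishes tailing. Steps 03–04 then call ectopic
siRNA-gain genes between genotypes (0 calls in the matched null; 5/5
seeded genes recovered) and show that genes seeded with siRNA gains shift
down in expression (median log2 fold change −1.09 vs −0.02 for all genes,
Welch p ≈ 5 × 10⁻¹⁷).

The same stages are scriptable via the CLI:

```sh
srtail simulate --preset wt --n-reads 20000 --seed 1 --out-dir demo
srtail align --genome demo/genome.fa --reads demo/reads.fastq --out demo/aln.tsv
srtail classify --table demo/aln.tsv --annotation demo/annotation.gff3 --out demo/cls.tsv
srtail stats --table demo/cls.tsv --out-dir demo/stats
srtail run-all --preset wt --n-reads 20000 --seed 1 --out-dir demo_all
```

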