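# Methods

## Problem and model

Small RNAs bound to Argonaute in fission yeast — centromeric siRNAs and
Dicer-independent priRNAs — can carry one or a few extra 3′ nucleotides
that are not encoded in the genome. These additions are enzymatic
(an adenylating poly(A) polymerase of the TRAMP family and a separate
uridylyl transferase), mark sRNAs for removal from Argonaute, and their
loss lets "noise" sRNAs accumulate and trigger ectopic RNAi at
euchromatic genes. The package implements the sequence-analysis side of
that biology: calling the non-templated 3′ tail of each read, attributing
reads to sRNA classes, summarising tailing per class and genotype, and
testing for siRNA gains and their expression consequences.

The measurement model treats a read as `genomic span + tail + errors`:

* the genomic span matches the genome exactly (or with isolated internal
  substitutions from sequencing error),
* the tail is a 3′-terminal run of bases that mismatch the templated
  continuation of the span on the read's strand,
* tails are short (1–3 nt), dominated by A, with U second.

There is no kinetic model of sRNA turnover anywhere in the package; all
statements are about read counts and fractions.

## Tail calling: two conventions

`exact_prefix` (default) defines the tail as the residue after the
*longest exact genomic prefix*. It is the cleanest reading of
"non-templated": the first tail base mismatches by construction, and no
mismatch budget interacts with tail length. A read is reported unmapped
when no prefix of at least `max(min_prefix, L - max_tail)` nt places
exactly (defaults `min_prefix=18`, `max_tail=3`).

`terminal_mismatch` emulates the mapper-first pipeline used with
conventional short-read aligners: align the full read allowing up to
`max_mm=2` substitutions anywhere, then read the tail off as the maximal
contiguous mismatch run ending at the 3′ terminus. Internal mismatches
never count toward the tail; the tail length is bounded by the mismatch
allowance, so 1–2 nt tails are visible but a 3 nt tail is not.

The two modes bracket the defensible interpretations of a
mismatch-tolerant mapping step followed by 3′-mismatch extraction; both
are exposed, both are oracle-tested against brute-force scans, and the
per-read output records which mode produced it.

A deliberate consequence of the prefix definition: a 3′ addition whose
base happens to equal the next templated base is *invisible* — the prefix
absorbs it. The simulator therefore only emits detectable tails (below),
and a templated addition is tested to be absorbed, not called.

### Alignment machinery

The k-mer index (default k = 12, valid 8–16) stores every k-mer of both
strands; minus-strand hits are reported in forward coordinates with
strand `−`. Exact-prefix search seeds on the read's first k-mer, which is
complete for this purpose: any exact prefix ≥ `min_prefix` ≥ k contains
that k-mer. Full-read ≤ 2-mismatch search instead scans every genome
position on both strands with a vectorised mismatch count — for 20–30 nt
reads two substitutions can break every 12-mer, so no 12-mer-seeded
search can be complete, and on the ≤ 100 kb genomes this package targets
the exact scan costs only a few milliseconds per read.

Reads are matched against the reverse-complemented chromosome for
minus-strand placements, and the tail is always defined at the read's
biological 3′ end. Coordinates are 0-based half-open internally; GFF3 I/O
converts to 1-based inclusive. Multimapping reads (equal best placements)
are assigned uniformly at random; the generator is seeded by
`(global seed, read ordinal)`, so reruns are reproducible and the choice
is independent of candidate input order (candidates are canonically
sorted first). Reordering the input reads changes assignments only
because ordinals change.

## Classification

Features load from GFF3 (via gffutils) into an interval-tree database;
introns are synthesised as the gaps between each mRNA's exons, and an
exonless mRNA is treated as single-exon. A mapped read takes the class of
the highest-priority feature type it overlaps by at least half its length
(default priority centromeric > tRNA > rRNA > mRNA exon > intronic >
ncRNA > intergenic; both the priority and the 50 % threshold are
configurable and recorded). Sense/antisense is resolved afterwards by
comparing the read strand to the feature strand; `intronic` additionally
requires full containment within an intron on the mRNA's own strand,
so exon-boundary reads fall to the exonic class by the 50 % rule. The
priority order is a documented choice — annotation-overlap precedence is
not something the data can decide — and permuting annotation file order
never changes a label.

## Summary statistics

"Tailed" means `tail_len ≥ 1` under the configured mode. Tail composition
is reported two ways: per read (all-A tail / all-U tail / other — mixed
tails are rare and need the bucket) and per nucleotide (base shares among
all called tail nucleotides). The per-nucleotide variant is the one
matched to the wild-type composition figures (~72 % A, ~25 % U), since
those are phrased per nucleotide. Length histograms are reported both
tail-included and tail-excluded (the templated span); the 22 nt mode
refers to the tail-excluded length. RPM is `count × 10⁶ / total mapped
reads`; an optional per-sample multiplicative factor rescales RPM to
Argonaute-bound sRNA amounts when samples were calibrated against
pulldown quantifications — it is supplied by the user, never estimated
here.

## Comparison statistics

Per-feature counts partition mapped reads (intergenic reads count in one
pseudo-feature row). Fold changes are `(a + c)/(b + c)` with pseudocount
c = 0.5 to keep ratios finite at zero counts; replicate matrices are
averaged first. Ectopic siRNA-gain calls use two thresholds: mutant RPM ≥
`min_rpm` (default 5) and wild-type RPM ≤ `max_wt_rpm` (default 0.5).
The defaults encode "detectable in the mutant, undetectable in wild
type"; no printed numeric cutoff exists for this selection, so both
thresholds are parameters and are echoed into every output. The
expression-shift summary compares log2 fold changes of gain genes versus
the remaining genes with the two-sided Welch unequal-variance *t*-test
(Welch–Satterthwaite degrees of freedom); Welch is the stated test for
"independent datasets with high variance", and the gain/rest split keeps
the two samples disjoint. Identical inputs return t = 0, p = 1; an empty
gain set yields an explicit notice instead of a test.

## The synthetic-data generator

The generator is first-class, tested code, and its defaults are the study
conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 50 kb, GC 0.5 | i.i.d. random sequence |
| centromeric repeats | 4 copies × 3 kb, byte-identical | forces 4-way multimapping |
| gene complement | 20 mRNAs (half with one 200 nt intron), 5 tRNAs, 1 rRNA, 10 ncRNAs | populates every read class |
| read length | 20–30 nt, mode 22 | mature sRNA length 22 nt |
| 5′-U preference | 0.8 | strong 5′-U bias of Argonaute loading |
| class mixture (Ago-bound) | 60 % centromeric, 15 % mRNA ±, 9 % ncRNA ±, 6 % tRNA, 7 % rRNA ±, 2 % intronic, 1 % intergenic | centromeric-dominated pulldown |
| class mixture (total) | 25 % centromeric, rRNA/tRNA/mRNA degradation products for the rest | the ~25 % centromeric share is the one anchored value; other shares are free parameters chosen once |
| tailing probability | 0.25 (centromeric, mRNA, ncRNA, antisense rRNA, intronic, intergenic), 0.05 (tRNA, sense rRNA) | wild-type Ago-bound per-class rates |
| tail length | 1 nt : 0.7, 2 nt : 0.3 | 1–2 nt tails |
| tail identity | A 0.72, U 0.25, C 0.02, G 0.01 | adenine-dominant composition |
| total-fraction tailing | non-centromeric rates × 0.4 | total sRNAs are tailed less often |
| sequencing error | 0.001 substitutions/base, genomic span only | indels out of scope |

Genotype presets: deleting the adenylating enzyme zeroes the A share,
deleting the uridylating one zeroes the U share, and each class's tailing
probability scales by the surviving identity mass. This makes tailing
decline monotonically wild type ≥ single mutant ≥ double mutant and
leaves the double mutant at ~0.75 % (the residual C/G mass), matching the
qualitative "lost / strongly reduced" genotype descriptions without
inventing numeric mutant rates.

Tail bases are sampled *conditioned on differing from the templated
continuation* at their position — that is what makes every simulated tail
detectable. The rejection is applied to the whole (start position, tail)
draw rather than per base: re-drawing only the offending base would skew
the emitted composition (an A-tail is forbidden wherever the template
continues with A), whereas re-drawing the position leaves the composition
unbiased because the templated neighbour is approximately uniform in an
i.i.d. genome. Centromeric reads additionally keep their tail template
inside the repeat copy, so the non-templated guarantee holds at every
identical copy regardless of which copy the multimapper assignment picks.

What the generator does **not** emulate: Dicer cleavage geometry and
phasing, RNA secondary structure, ligation/PCR sequence biases, indels,
adapter read-through, chromosome-scale heterochromatin domains, and any
temporal dynamics. Passing recovery tests therefore shows the *pipeline*
is correct under the stated statistical structure — not that real
libraries satisfy that structure.

## Numerical and reproducibility choices

* One global seed drives everything; stage-local seeds derive from it by
  mixing with a CRC of the stage name, and per-read assignment seeds by
  `(seed, ordinal)` through numpy `SeedSequence`. Identical configs give
  byte-identical outputs (the config digest embedded in TSV headers
  excludes the output directory).
* Ties: equivalent placements are canonically ordered by
  (chrom, start, strand) before the seeded uniform choice; the
  exact-prefix caller's single-placement return is the canonical first.
* Degenerate inputs: empty read files produce empty tables; zero tailed
  reads produce an empty composition (no division); empty feature classes
  are reported absent rather than zero; N-containing k-mers are skipped
  in the index and never match a read base.
* The 5′-base preference is enforced by rejection sampling over start
  positions (capped at 200 attempts) rather than by editing bases, so
  reads remain genuine genome substrings.

## Problem sizes

The default analyses use the 100 kb toy genome with 100,000 reads for the
headline recoveries (a full simulate–align–classify–summarise pass takes
a few seconds) and 20,000 reads per genotype in the narrative analysis
scripts; brute-force oracle comparisons run 1,000 random reads against a
2 kb genome. These sizes put every binomial 3-SE recovery band well
inside the fractions being tested while keeping each script in the
seconds-to-a-minute range.

## Known limitations

* The exact-prefix caller reports reads with > `max_tail` additions as
  unmapped rather than trimming further; with in-vitro tails of up to
  ~20 nt such reads would be lost — raise `max_tail` for such data.
* Sequencing errors in the last ≤ 3 nt of an untailed read are called as
  short tails (~0.3 % of reads at the default error rate); errors in the
  first 18 nt make a read unmapped in exact-prefix mode (~1.8 %).
* The classifier's 50 %-overlap and intron-containment rules are sharp
  thresholds; boundary reads are deterministic but convention-dependent.
* The expression comparison consumes externally quantified counts — the
  package does not implement mRNA-seq quantification, dispersion
  estimation or multiple-testing control, and reports raw Welch p values
  only.
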