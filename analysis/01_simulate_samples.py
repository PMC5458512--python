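#!/usr/bin/env python
"""Generate the study's synthetic samples: one Argonaute-bound library per
genotype (wt, cid14, cid16, cid14cid16) plus a wild-type total-sRNA
library, all from one shared toy genome, with full ground truth.

Writes scratch/samples/<name>/{genome.fa,annotation.gff3,reads.fastq,truth.tsv}
(bulky intermediates live under scratch/; the downstream scripts put their
summary tables under results/).
"""

import os

from srtail import simulate as sim
from srtail.pipeline import stage_seed

SEED = 1
N_READS = 20_000
OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "samples")

SAMPLES = [
    ("wt_ago", "wt", "ago_bound"),
    ("wt_total", "wt", "total"),
    ("cid14_ago", "cid14", "ago_bound"),
    ("cid16_ago", "cid16", "ago_bound"),
    ("cid14cid16_ago", "cid14cid16", "ago_bound"),
]


def main():
    genome, db = sim.build_toy_genome(sim.SimGenomeSpec(seed=stage_seed(SEED, "genome")))
    print(f"toy genome: {sum(map(len, genome.values()))} nt, "
          f"{len([f for f in db.features if f.ftype not in ('exon', 'intron')])} features")
    for name, geno, fraction in SAMPLES:
        model = sim.preset_model(geno, fraction, n_reads=N_READS,
                                 seed=stage_seed(SEED, name))
        reads, truth = sim.simulate_sample(genome, db, model)
        out_dir = os.path.join(OUT, name)
        sim.write_sample(out_dir, genome, db, reads, truth)
        tailed = (truth["true_tail"] != "").mean()
        print(f"{name:16s} {len(reads)} reads, true tailed fraction {tailed:.3f}")


if __name__ == "__main__":
    main()
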