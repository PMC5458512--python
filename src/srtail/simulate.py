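"""Ground-truthed synthetic data: toy genome, annotation, and small-RNA reads.

The generator emulates the statistical structure of Argonaute-bound and
total small-RNA libraries from a fission-yeast-like genome: 20-30 nt reads
with modal length 22, a strong 5'-U preference, a class mixture dominated
by centromeric siRNAs in the Argonaute-bound fraction (~25% centromeric in
the total fraction), class-specific 3'-tailing probabilities (~25% for
centromeric/mRNA/ncRNA-derived reads, ~5% for tRNA and sense-rRNA reads in
wild type), 1-2 nt tails with adenine-dominant composition, and identical
multi-copy centromeric repeats that force multimapping.

Genotype presets model the two 3' nucleotidyl-transferases: the poly(A)
polymerase (TRAMP component) adds adenines and the uridylyl-transferase
adds uridines; deleting one removes the corresponding tail identity and
proportionally lowers the per-class tailing probability, deleting both
abolishes nearly all tailing.

Tail bases are non-templated *by construction*: each tail base must differ
from the genomic base that would continue the read's strand at its
position. Sampling rejects the whole (start position, tail) draw on a
clash rather than re-drawing the offending base, so the composition of
emitted tails stays unbiased for the requested identity distribution (the
templated neighbour base is ~uniform in an i.i.d. genome). Uridine is
written as T in read sequences (DNA space, as sequencers emit); truth
tables and reports use U.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from srtail.classify import Feature, FeatureDB
from srtail.seq import BASES, revcomp, to_rna, write_fasta, write_fastq

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

GENOTYPES = ("wt", "cid14", "cid16", "cid14cid16")
FRACTIONS = ("ago_bound", "total")

#: read source classes the simulator can draw from
SOURCE_CLASSES = (
    "centromeric",
    "tRNA",
    "rRNA_sense",
    "rRNA_antisense",
    "mRNA_sense",
    "mRNA_antisense",
    "ncRNA_sense",
    "ncRNA_antisense",
    "intronic",
    "intergenic",
)


class LayoutError(ValueError):
    """Requested features do not fit into the requested chromosomes."""


@dataclass(frozen=True)
class SimGenomeSpec:
    """Layout of the toy genome.

    Defaults: 2 chromosomes x 50 kb, 4 byte-identical centromeric repeat
    copies of 3 kb, 20 mRNAs (half with one intron), 5 tRNAs, 1 rRNA locus,
    10 ncRNAs — small enough for brute-force oracles, rich enough to
    populate every read class.
    """

    chromosome_lengths: tuple[int, ...] = (50_000, 50_000)
    n_centromeric_copies: int = 4
    centromeric_copy_length: int = 3_000
    n_mrna: int = 20
    mrna_exon_length: int = 300
    mrna_intron_length: int = 200
    mrna_single_exon_length: int = 800
    n_trna: int = 5
    trna_length: int = 80
    n_rrna: int = 1
    rrna_length: int = 3_000
    n_ncrna: int = 10
    ncrna_length: int = 300
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_centromeric_copies < 2:
            raise ValueError("need >= 2 centromeric copies to exercise multimapping")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if any(n < 10_000 for n in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be >= 10 kb")


def build_toy_genome(spec: SimGenomeSpec) -> tuple[dict[str, str], FeatureDB]:
    """Generate a random genome and its annotation, deterministically.

    Features are laid out round-robin across chromosomes with uniform gaps;
    the centromeric repeat copies share one byte-identical sequence.
    Raises :class:`LayoutError` if the requested features do not fit.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array(
        [
            (1 - spec.gc_fraction) / 2,  # A
            spec.gc_fraction / 2,  # C
            spec.gc_fraction / 2,  # G
            (1 - spec.gc_fraction) / 2,  # T
        ]
    )
    chroms = {
        f"chr{i + 1}": "".join(rng.choice(list(BASES), size=n, p=p))
        for i, n in enumerate(spec.chromosome_lengths)
    }
    names = list(chroms)

    # plan: one entry per top-level feature, (ftype, total_length, payload)
    plan: list[tuple[str, int, dict]] = []
    for i in range(spec.n_centromeric_copies):
        plan.append(("centromeric_repeat", spec.centromeric_copy_length, {"copy": i}))
    for i in range(spec.n_mrna):
        if i % 2 == 0:  # half with one intron
            total = 2 * spec.mrna_exon_length + spec.mrna_intron_length
            plan.append(("mRNA", total, {"introns": 1}))
        else:
            plan.append(("mRNA", spec.mrna_single_exon_length, {"introns": 0}))
    for _ in range(spec.n_trna):
        plan.append(("tRNA", spec.trna_length, {}))
    for _ in range(spec.n_rrna):
        plan.append(("rRNA", spec.rrna_length, {}))
    for _ in range(spec.n_ncrna):
        plan.append(("ncRNA", spec.ncrna_length, {}))

    # round-robin assignment to chromosomes, then sequential placement
    margin = 100  # keep reads and tail templates clear of chromosome ends
    per_chrom: dict[str, list[tuple[str, int, dict]]] = {c: [] for c in names}
    for i, item in enumerate(plan):
        per_chrom[names[i % len(names)]].append(item)

    for chrom in names:
        total = sum(length for _, length, _ in per_chrom[chrom])
        items = len(per_chrom[chrom])
        free = len(chroms[chrom]) - 2 * margin - total
        if items and free < 40 * items:
            raise LayoutError(
                f"{chrom}: {total} nt of features (+gaps) exceed the "
                f"{len(chroms[chrom])} nt chromosome"
            )

    cen_seq = "".join(rng.choice(list(BASES), size=spec.centromeric_copy_length, p=p))
    features: list[Feature] = []
    counters: dict[str, int] = {}

    for chrom in names:
        items = per_chrom[chrom]
        if not items:
            continue
        total = sum(length for _, length, _ in items)
        gap = (len(chroms[chrom]) - 2 * margin - total) // (len(items) + 1)
        pos = margin + gap
        seq = chroms[chrom]
        for ftype, length, payload in items:
            counters[ftype] = counters.get(ftype, 0) + 1
            strand = "+" if rng.random() < 0.5 else "-"
            if ftype == "centromeric_repeat":
                fid = f"cen_{payload['copy'] + 1}"
                seq = seq[:pos] + cen_seq + seq[pos + length :]
                features.append(Feature(fid, chrom, pos, pos + length, "+", ftype))
            elif ftype == "mRNA":
                fid = f"gene_{counters['mRNA']:03d}"
                features.append(Feature(fid, chrom, pos, pos + length, strand, "mRNA"))
                if payload["introns"]:
                    e = spec.mrna_exon_length
                    iv = spec.mrna_intron_length
                    features.append(
                        Feature(f"{fid}.e1", chrom, pos, pos + e, strand, "exon", fid)
                    )
                    features.append(
                        Feature(
                            f"{fid}.e2", chrom, pos + e + iv, pos + length, strand, "exon", fid
                        )
                    )
                else:
                    features.append(
                        Feature(f"{fid}.e1", chrom, pos, pos + length, strand, "exon", fid)
                    )
            else:
                short = {"tRNA": "trna", "rRNA": "rrna", "ncRNA": "ncrna"}[ftype]
                fid = f"{short}_{counters[ftype]:02d}"
                features.append(Feature(fid, chrom, pos, pos + length, strand, ftype))
            pos += length + gap
        chroms[chrom] = seq

    lengths = {c: len(s) for c, s in chroms.items()}
    return chroms, FeatureDB(features, chrom_lengths=lengths)


# ----------------------------------------------------------------- ReadModel


@dataclass(frozen=True)
class ReadModel:
    """Generative model for one small-RNA sample."""

    n_reads: int = 100_000
    class_mixture: dict[str, float] = field(default_factory=dict)
    tail_prob_by_class: dict[str, float] = field(default_factory=dict)
    tail_length_dist: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    tail_identity_dist: dict[str, float] = field(
        default_factory=lambda: {"A": 0.72, "U": 0.25, "C": 0.02, "G": 0.01}
    )
    p_5prime_U: float = 0.8
    length_dist: dict[int, float] = field(default_factory=dict)
    modal_length: int = 22
    seq_error_rate: float = 0.001
    genotype_preset: str = "wt"
    fraction: str = "ago_bound"
    seed: int = 0

    def validate(self) -> None:
        for name, dist in (
            ("class_mixture", self.class_mixture),
            ("tail_length_dist", self.tail_length_dist),
            ("length_dist", self.length_dist),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative weight")
        ident_total = sum(self.tail_identity_dist.values())
        tailing = any(v > 0 for v in self.tail_prob_by_class.values())
        if tailing and abs(ident_total - 1.0) > 1e-9:
            raise ValueError("tail_identity_dist must sum to 1 when tailing is on")
        if set(self.tail_length_dist) - {1, 2, 3}:
            raise ValueError("tail lengths must be in {1, 2, 3}")
        if not all(20 <= n <= 30 for n in self.length_dist):
            raise ValueError("read lengths must be in 20..30")
        if max(self.length_dist, key=self.length_dist.get) != self.modal_length:
            raise ValueError("mode of length_dist must equal modal_length")
        for c, p in self.tail_prob_by_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"tail_prob_by_class[{c}] outside [0,1]")
        if not 0.0 <= self.p_5prime_U <= 1.0:
            raise ValueError("p_5prime_U outside [0,1]")
        unknown = set(self.class_mixture) - set(SOURCE_CLASSES)
        if unknown:
            raise ValueError(f"unknown source classes: {sorted(unknown)}")


#: default read-length distribution, modal at the mature 22 nt sRNA length
DEFAULT_LENGTH_DIST = {
    20: 0.05, 21: 0.15, 22: 0.40, 23: 0.15, 24: 0.08,
    25: 0.06, 26: 0.04, 27: 0.03, 28: 0.02, 29: 0.01, 30: 0.01,
}

# Argonaute-bound libraries are dominated by centromeric siRNAs; the total
# fraction carries ~25% centromeric reads plus abundant rRNA/tRNA/mRNA
# degradation products. Exact shares beyond the 25% figure are free
# parameters of the generator.
_MIX_AGO = {
    "centromeric": 0.60, "tRNA": 0.06, "rRNA_sense": 0.05, "rRNA_antisense": 0.02,
    "mRNA_sense": 0.10, "mRNA_antisense": 0.05, "ncRNA_sense": 0.06,
    "ncRNA_antisense": 0.03, "intronic": 0.02, "intergenic": 0.01,
}
_MIX_TOTAL = {
    "centromeric": 0.25, "tRNA": 0.15, "rRNA_sense": 0.30, "rRNA_antisense": 0.01,
    "mRNA_sense": 0.15, "mRNA_antisense": 0.02, "ncRNA_sense": 0.05,
    "ncRNA_antisense": 0.01, "intronic": 0.03, "intergenic": 0.03,
}

# wild-type per-class tailing probabilities (Argonaute-bound): ~25% for
# centromeric/mRNA/ncRNA-derived sRNAs, ~5% for tRNA and sense rRNA;
# antisense-rRNA reads are tailed like mRNA-derived priRNAs.
_TAIL_PROB_AGO = {
    "centromeric": 0.25, "tRNA": 0.05, "rRNA_sense": 0.05, "rRNA_antisense": 0.25,
    "mRNA_sense": 0.25, "mRNA_antisense": 0.25, "ncRNA_sense": 0.25,
    "ncRNA_antisense": 0.25, "intronic": 0.25, "intergenic": 0.25,
}

#: identity removed by each nucleotidyl-transferase deletion
_LOST_IDENTITY = {"wt": (), "cid14": ("A",), "cid16": ("U",), "cid14cid16": ("A", "U")}

#: total-fraction tailing is reduced for non-centromeric classes
_TOTAL_TAIL_SCALE = 0.4


def preset_model(
    genotype: str, fraction: str = "ago_bound", n_reads: int = 100_000, seed: int = 0
) -> ReadModel:
    """Build the ReadModel for a genotype/fraction preset.

    ``genotype`` is one of wt, cid14, cid16, cid14cid16 (also accepted with a
    ``_ago``/``_total`` suffix, e.g. ``wt_ago``); ``fraction`` is ago_bound or
    total. Deleting a transferase zeroes its tail identity and scales every
    class's tailing probability by the surviving identity mass, so tailing
    drops monotonically wt >= single mutant >= double mutant.
    """
    if genotype.endswith("_ago"):
        genotype, fraction = genotype[:-4], "ago_bound"
    elif genotype.endswith("_total"):
        genotype, fraction = genotype[:-6], "total"
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype preset {genotype!r}; expected one of {GENOTYPES}")
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")

    mixture = dict(_MIX_AGO if fraction == "ago_bound" else _MIX_TOTAL)
    tail_prob = dict(_TAIL_PROB_AGO)
    if fraction == "total":
        for c in tail_prob:
            if c != "centromeric":
                tail_prob[c] = round(tail_prob[c] * _TOTAL_TAIL_SCALE, 10)

    identity = {"A": 0.72, "U": 0.25, "C": 0.02, "G": 0.01}
    lost = _LOST_IDENTITY[genotype]
    survive = 1.0 - sum(identity[b] for b in lost)
    for b in lost:
        identity[b] = 0.0
    if survive > 0:
        identity = {b: v / survive for b, v in identity.items()}
    tail_prob = {c: p * survive for c, p in tail_prob.items()}

    return ReadModel(
        n_reads=n_reads,
        class_mixture=mixture,
        tail_prob_by_class=tail_prob,
        tail_identity_dist=identity,
        length_dist=dict(DEFAULT_LENGTH_DIST),
        modal_length=22,
        genotype_preset=genotype,
        fraction=fraction,
        seed=seed,
    )


# ------------------------------------------------------------ read sampling


def _source_pools(genome: dict[str, str], db: FeatureDB) -> dict[str, list]:
    """Per-class lists of (feature_id, chrom, start, end, read_strand | None)."""

    def entries(feats, antisense=False, strand=None):
        out = []
        for f in feats:
            if strand is not None:
                s = strand
            else:
                s = {"+": "-", "-": "+"}[f.strand] if antisense else f.strand
            out.append((f.feature_id, f.chrom, f.start, f.end, s))
        return out

    exons = db.by_type("exon")
    pools = {
        "centromeric": [
            (f.feature_id, f.chrom, f.start, f.end, None)  # None: strand drawn per read
            for f in db.by_type("centromeric_repeat")
        ],
        "tRNA": entries(db.by_type("tRNA")),
        "rRNA_sense": entries(db.by_type("rRNA")),
        "rRNA_antisense": entries(db.by_type("rRNA"), antisense=True),
        "mRNA_sense": entries(exons),
        "mRNA_antisense": entries(exons, antisense=True),
        "ncRNA_sense": entries(db.by_type("ncRNA")),
        "ncRNA_antisense": entries(db.by_type("ncRNA"), antisense=True),
        "intronic": entries(db.by_type("intron")),
        "intergenic": [
            (f"intergenic:{c}:{s}", c, s, e, None)
            for c, s, e in db.intergenic_intervals(min_length=60)
        ],
    }
    return pools


def simulate_sample(
    genome: dict[str, str], db: FeatureDB, model: ReadModel
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads from the genome under ``model``; return (reads, truth table).

    Reads are (read_id, sequence) pairs in DNA space. The truth table has one
    row per read: read_id, source_feature_id, true_class, chrom, start0 (of
    the templated span, forward coordinates), strand, true_length (full read),
    true_tail (RNA letters, empty if untailed), n_copies_of_origin.
    """
    model.validate()
    rng = np.random.default_rng(model.seed)
    pools = _source_pools(genome, db)

    classes = [c for c in SOURCE_CLASSES if model.class_mixture.get(c, 0.0) > 0]
    weights = np.array([model.class_mixture[c] for c in classes])
    weights = weights / weights.sum()
    for c in classes:
        if not pools.get(c):
            raise ValueError(f"class {c!r} has mixture weight > 0 but no source features")

    lengths = sorted(model.length_dist)
    length_p = np.array([model.length_dist[n] for n in lengths])
    tail_lens = sorted(model.tail_length_dist)
    tail_len_p = np.array([model.tail_length_dist[t] for t in tail_lens])
    ident_bases = ["A", "U", "C", "G"]
    ident_p = np.array([model.tail_identity_dist.get(b, 0.0) for b in ident_bases])
    if ident_p.sum() > 0:
        ident_p = ident_p / ident_p.sum()
    n_cen = len(pools["centromeric"])

    # vectorised per-read draws
    n = model.n_reads
    class_idx = rng.choice(len(classes), size=n, p=weights)
    read_len = rng.choice(lengths, size=n, p=length_p)
    tailed = np.zeros(n, dtype=bool)
    for i, c in enumerate(classes):
        mask = class_idx == i
        tailed[mask] = rng.random(mask.sum()) < model.tail_prob_by_class.get(c, 0.0)
    tail_len = np.where(tailed, rng.choice(tail_lens, size=n, p=tail_len_p), 0)
    want_u = rng.random(n) < model.p_5prime_U

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n):
        c = classes[class_idx[i]]
        pool = pools[c]
        fid, chrom, fs, fe, strand = pool[rng.integers(len(pool))]
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        L = int(read_len[i])
        t = int(tail_len[i])
        glen = L - t
        seq = genome[chrom]
        lo, hi = fs, fe - glen  # start0 range (inclusive) within the feature
        # keep the tail template inside the chromosome
        if strand == "+":
            hi = min(hi, len(seq) - glen - t)
        else:
            lo = max(lo, t)
        if c == "centromeric":
            # keep the tail template inside the repeat copy, so the
            # non-templated guarantee holds at every identical copy
            if strand == "+":
                hi = min(hi, fe - glen - t)
            else:
                lo = max(lo, fs + t)
        if hi < lo:
            raise ValueError(f"feature {fid} too short for a {glen} nt read")

        tail = ""
        start = lo
        for _attempt in range(200):
            start = int(rng.integers(lo, hi + 1))
            five = seq[start] if strand == "+" else _COMP1[seq[start + glen - 1]]
            if (five == "T") != bool(want_u[i]):
                continue
            # draw tail bases; reject the whole position+tail draw if any
            # tail base matches its templated continuation (non-templated
            # by construction, composition unbiased)
            if t:
                draw = rng.choice(4, size=t, p=ident_p)
                tail_rna = "".join(ident_bases[j] for j in draw)
                tail = tail_rna.replace("U", "T")
                clash = False
                for j in range(t):
                    if strand == "+":
                        templ = seq[start + glen + j]
                    else:
                        templ = _COMP1[seq[start - 1 - j]]
                    if tail[j] == templ:
                        clash = True
                        break
                if clash:
                    continue
            break
        else:
            # pathological corner (tiny feature / extreme parameters): keep
            # the last position, force tail bases off-template
            if t:
                forced = []
                for j in range(t):
                    templ = (
                        seq[start + glen + j]
                        if strand == "+"
                        else _COMP1[seq[start - 1 - j]]
                    )
                    choices = [b for b in "ACGT" if b != templ]
                    forced.append(choices[int(rng.integers(3))])
                tail = "".join(forced)

        core = seq[start : start + glen]
        if strand == "-":
            core = revcomp(core)
        # substitution errors on the templated span only
        if model.seq_error_rate > 0:
            n_err = rng.binomial(glen, model.seq_error_rate)
            if n_err:
                core_l = list(core)
                for pos in rng.choice(glen, size=n_err, replace=False):
                    alt = [b for b in "ACGT" if b != core_l[pos]]
                    core_l[pos] = alt[int(rng.integers(3))]
                core = "".join(core_l)

        rid = f"read_{i:06d}"
        reads.append((rid, core + tail))
        truth_rows.append(
            (
                rid, fid, c, chrom, start, strand, L, to_rna(tail),
                n_cen if c == "centromeric" else 1,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "source_feature_id", "true_class", "chrom", "start0",
            "strand", "true_length", "true_tail", "n_copies_of_origin",
        ],
    )
    return reads, truth


def write_sample(out_dir, genome, db: FeatureDB, reads, truth: pd.DataFrame) -> dict:
    """Write genome.fa, annotation.gff3, reads.fastq and truth.tsv to a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "annotation": os.path.join(out_dir, "annotation.gff3"),
        "reads": os.path.join(out_dir, "reads.fastq"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_fasta(paths["genome"], genome)
    db.to_gff3(paths["annotation"])
    write_fastq(paths["reads"], reads)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------- expression simulation


def simulate_expression_counts(
    n_genes: int = 500,
    mean: float = 200.0,
    dispersion: float = 0.1,
    n_reps: int = 3,
    fold_changes: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition negative-binomial count matrices (genes x replicates).

    ``fold_changes`` maps gene index -> multiplicative change of the mean in
    condition B (e.g. {0: 0.25} models a 4-fold reduction of gene 0).
    Variance follows var = mu + dispersion * mu^2.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    mu_a = np.full(n_genes, float(mean))
    mu_b = mu_a.copy()
    for idx, fc in (fold_changes or {}).items():
        mu_b[idx] *= fc

    def draw(mu):
        size = 1.0 / dispersion  # NB "number of successes" parameter
        p = size / (size + mu)
        return rng.negative_binomial(size, p[:, None], size=(n_genes, n_reps))

    a = pd.DataFrame(draw(mu_a), index=genes, columns=[f"A{r + 1}" for r in range(n_reps)])
    b = pd.DataFrame(draw(mu_b), index=genes, columns=[f"B{r + 1}" for r in range(n_reps)])
    return a, b
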