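"""Read placement and non-templated 3'-tail calling.

Two calling conventions are provided, bracketing the defensible readings of
a mapper-based tailing pipeline:

``exact_prefix`` (default)
    Find the longest read prefix with an exact (0-mismatch) genomic
    placement; the residual 3' suffix is the tail, provided the prefix is
    at least ``min_prefix`` nt and the suffix at most ``max_tail`` nt. By
    maximality the first tail base always differs from the templated base.

``terminal_mismatch``
    Map the full read allowing up to ``max_mm`` substitutions (the
    conventional 2-mismatch short-read setting); the tail is the maximal
    contiguous run of mismatches ending at the read's 3' terminus.
    Internal mismatches never contribute to the tail.

Reverse-strand placements are found by matching the read against the
reverse-complemented chromosome; tails are always defined at the read's
biological 3' end. Reads mapping to several equally good placements are
assigned uniformly at random, reproducibly from a global seed plus the
read's ordinal.

The full-read aligner scans every genome position on both strands with a
vectorised mismatch count — exact by construction, and affordable on the
<= 100 kb genomes this package targets (a seeded search cannot guarantee
completeness for 2 mismatches in 20-30 nt reads with 12-mer seeds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from srtail import seq as sq

TAIL_CATEGORIES = ("none", "A_tail", "U_tail", "other")


@dataclass(frozen=True)
class AlignmentCall:
    """One read placement; coordinates are forward-strand, 0-based half-open.

    ``start``/``aligned_span`` describe the templated span only (the called
    tail is excluded), so start + aligned_span never exceeds the chromosome
    and aligned_span + tail_length equals the read length.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    aligned_span: int
    mismatch_positions: tuple[int, ...] = ()
    n_equivalent_placements: int = 1

    @property
    def end(self) -> int:
        return self.start + self.aligned_span


@dataclass(frozen=True)
class TailCall:
    """The called non-templated 3' tail of one read (RNA letters)."""

    tail_length: int
    tail_seq: str
    tail_category: str
    calling_mode: str

    @staticmethod
    def from_seq(tail_dna: str, mode: str) -> "TailCall":
        tail = sq.to_rna(tail_dna)
        if not tail:
            cat = "none"
        elif set(tail) == {"A"}:
            cat = "A_tail"
        elif set(tail) == {"U"}:
            cat = "U_tail"
        else:
            cat = "other"
        return TailCall(len(tail), tail, cat, mode)


class GenomeIndex:
    """k-mer seed index over both strands of a genome.

    Reverse-strand k-mers are indexed on the reverse-complemented
    chromosome; public lookups report forward coordinates with strand '-'.
    """

    def __init__(self, genome: dict[str, str], k: int = 12):
        if not genome:
            raise ValueError("genome is empty")
        if not 8 <= k <= 16:
            raise ValueError("seed length k must be in 8..16")
        for name, s in genome.items():
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: unsupported bases {sorted(bad)}")
        self.k = k
        self.genome = {name: s.upper() for name, s in genome.items()}
        self.chrom_lengths = {name: len(s) for name, s in self.genome.items()}
        # strand sequences: '-' holds the reverse complement
        self._strand_seq: dict[tuple[str, str], str] = {}
        self._strand_enc: dict[tuple[str, str], np.ndarray] = {}
        self._kmers: dict[str, list[tuple[str, str, int]]] = {}
        for name in sorted(self.genome):
            for strand in "+-":
                s = self.genome[name] if strand == "+" else sq.revcomp(self.genome[name])
                self._strand_seq[(name, strand)] = s
                self._strand_enc[(name, strand)] = sq.encode(s)
                for p in range(len(s) - k + 1):
                    kmer = s[p : p + k]
                    if "N" in kmer:
                        continue
                    self._kmers.setdefault(kmer, []).append((name, strand, p))

    def _to_forward(self, chrom: str, strand: str, pos: int, span: int) -> int:
        """Strand-sequence position -> forward-strand start of the span."""
        if strand == "+":
            return pos
        return self.chrom_lengths[chrom] - pos - span

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All placements of ``kmer``: (chrom, forward start, strand)."""
        if len(kmer) != self.k:
            raise ValueError(f"lookup needs a {self.k}-mer")
        hits = [
            (chrom, self._to_forward(chrom, strand, p, self.k), strand)
            for chrom, strand, p in self._kmers.get(kmer.upper(), [])
        ]
        return sorted(hits)

    def _seed_hits(self, kmer: str) -> list[tuple[str, str, int]]:
        """Internal: raw (chrom, strand, strand-seq position) seed hits."""
        return self._kmers.get(kmer, [])


def build_index(genome: dict[str, str], k: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, k=k)


# ------------------------------------------------------------- full aligner


def align_full(
    read: str, index: GenomeIndex, max_mm: int = 2, read_id: str = ""
) -> list[AlignmentCall]:
    """All full-length placements of ``read`` with <= max_mm substitutions.

    Exhaustive over every position of both strands; minimal-mismatch
    placements sort first, then canonically by (chrom, start, strand).
    """
    read = read.upper()
    L = len(read)
    enc_read = sq.encode(read)
    found: list[tuple[int, str, int, str, tuple[int, ...]]] = []
    for (chrom, strand), arr in index._strand_enc.items():
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        neq = windows != enc_read
        counts = neq.sum(axis=1)
        for p in np.nonzero(counts <= max_mm)[0]:
            mism = tuple(int(i) for i in np.nonzero(neq[p])[0])
            fwd = index._to_forward(chrom, strand, int(p), L)
            found.append((len(mism), chrom, fwd, strand, mism))
    found.sort()
    if not found:
        return []
    calls = []
    for n_mm, chrom, fwd, strand, mism in found:
        n_equiv = sum(1 for f in found if f[0] == n_mm)
        calls.append(
            AlignmentCall(
                read_id=read_id, chrom=chrom, start=fwd, strand=strand,
                aligned_span=L, mismatch_positions=mism,
                n_equivalent_placements=n_equiv,
            )
        )
    return calls


# ------------------------------------------------------- exact-prefix mode


def _exact_prefix_placements(
    read: str, index: GenomeIndex
) -> tuple[int, list[tuple[str, str, int]]]:
    """Longest exact-prefix length and the strand-space placements achieving it.

    Complete for prefixes >= k: any exact prefix of length >= k contains the
    read's exact first k-mer, so seeding on that k-mer finds every placement.
    """
    k = index.k
    L = len(read)
    if L < k:
        return 0, []
    best = 0
    best_hits: list[tuple[str, str, int]] = []
    for chrom, strand, p in index._seed_hits(read[:k]):
        s = index._strand_seq[(chrom, strand)]
        limit = min(L, len(s) - p)
        if s[p : p + limit] == read[:limit]:
            ext = limit
        else:
            ext = k
            while ext < limit and s[p + ext] == read[ext]:
                ext += 1
        if ext > best:
            best, best_hits = ext, [(chrom, strand, p)]
        elif ext == best:
            best_hits.append((chrom, strand, p))
    return best, best_hits


def call_tail_exact_prefix(
    read: str,
    index: GenomeIndex,
    min_prefix: int = 18,
    max_tail: int = 3,
    read_id: str = "",
) -> tuple[AlignmentCall, TailCall] | None:
    """Call the tail as the residual after the longest exact genomic prefix.

    Returns None (unmapped) when no prefix of at least
    ``max(min_prefix, len(read) - max_tail)`` nt places exactly. Among
    equivalent placements the canonical (chrom, start, strand)-first one is
    reported; use :func:`align_sample` for seeded random assignment.
    """
    read = read.upper()
    L = len(read)
    if min_prefix < index.k:
        raise ValueError("min_prefix must be >= the index seed length")
    best, hits = _exact_prefix_placements(read, index)
    if best < max(min_prefix, L - max_tail) or not hits:
        return None
    placements = sorted(
        (chrom, index._to_forward(chrom, strand, p, best), strand)
        for chrom, strand, p in hits
    )
    chrom, fwd, strand = placements[0]
    call = AlignmentCall(
        read_id=read_id, chrom=chrom, start=fwd, strand=strand,
        aligned_span=best, mismatch_positions=(),
        n_equivalent_placements=len(placements),
    )
    return call, TailCall.from_seq(read[best:], "exact_prefix")


# -------------------------------------------------- terminal-mismatch mode


def call_tail_mismatch(
    read: str, index: GenomeIndex, max_mm: int = 2, read_id: str = ""
) -> tuple[AlignmentCall, TailCall] | None:
    """Full-length 2-mismatch placement; tail = terminal run of mismatches.

    The fewest-mismatch placement wins; reads whose mismatches are all
    internal get tail_length 0.
    """
    read = read.upper()
    L = len(read)
    calls = align_full(read, index, max_mm=max_mm, read_id=read_id)
    if not calls:
        return None
    best = calls[0]  # canonical first among minimal-mismatch placements
    mism = set(best.mismatch_positions)
    t = 0
    while (L - 1 - t) in mism:
        t += 1
    # shrink the reported span to the templated part; keep internal mismatches
    internal = tuple(p for p in best.mismatch_positions if p < L - t)
    if best.strand == "+":
        start = best.start
    else:
        start = best.start + t  # drop the tail bases from the forward interval
    call = AlignmentCall(
        read_id=read_id, chrom=best.chrom, start=start, strand=best.strand,
        aligned_span=L - t, mismatch_positions=internal,
        n_equivalent_placements=best.n_equivalent_placements,
    )
    return call, TailCall.from_seq(read[L - t :], "terminal_mismatch")


# ------------------------------------------------------------- multimapper


def _read_rng(seed: int, ordinal: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, ordinal]))


def resolve_multimapper(
    candidates: list[AlignmentCall], seed: int, ordinal: int = 0
) -> AlignmentCall:
    """Uniform random choice among equally good placements, reproducibly.

    Candidates are put in canonical (chrom, start, strand) order first, so
    the choice depends only on (seed, ordinal), not input order.
    """
    if not candidates:
        raise ValueError("no candidates to resolve")
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.start, c.strand))
    i = int(_read_rng(seed, ordinal).integers(len(ordered)))
    return ordered[i]


# ------------------------------------------------------------ sample level

TABLE_COLUMNS = [
    "read_id", "mapped", "chrom", "start0", "end0", "strand", "aligned_span",
    "n_mismatch", "n_placements", "tail_len", "tail_seq", "tail_category",
    "read_len", "five_prime", "mode",
]


def align_sample(
    reads: list[tuple[str, str]],
    index: GenomeIndex,
    mode: str = "exact_prefix",
    max_mm: int = 2,
    max_tail: int = 3,
    min_prefix: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Align and tail-call every read; one row per input read.

    Multimapping reads are assigned uniformly among equivalent placements,
    seeded by (seed, read ordinal). Unmapped reads keep their row with
    ``mapped=False``.
    """
    if mode not in ("exact_prefix", "terminal_mismatch"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact_prefix" and min_prefix < index.k:
        raise ValueError("min_prefix must be >= the index seed length")
    rows = []
    for ordinal, (rid, read) in enumerate(reads):
        read = read.upper()
        L = len(read)
        placements: list[tuple[str, int, str]] = []
        span = 0
        tail = None
        if mode == "exact_prefix":
            if L >= min_prefix:
                best, hits = _exact_prefix_placements(read, index)
                if best >= max(min_prefix, L - max_tail) and hits:
                    span = best
                    placements = [
                        (c, index._to_forward(c, s, p, best), s) for c, s, p in hits
                    ]
                    tail = TailCall.from_seq(read[best:], mode)
            if tail is not None and placements:
                placements = sorted(set(placements))
                chosen = placements[
                    int(_read_rng(seed, ordinal).integers(len(placements)))
                    if len(placements) > 1 else 0
                ]
                chrom, start, strand = chosen
                rows.append(
                    (rid, True, chrom, start, start + span, strand, span,
                     0, len(placements), tail.tail_length, tail.tail_seq,
                     tail.tail_category, L, sq.to_rna(read[0]), mode)
                )
                continue
        else:
            full = align_full(read, index, max_mm=max_mm, read_id=rid) if 15 <= L <= 40 else []
            if full:
                n_best_mm = len(full[0].mismatch_positions)
                eq = [c for c in full if len(c.mismatch_positions) == n_best_mm]
                chosen = (
                    resolve_multimapper(eq, seed, ordinal) if len(eq) > 1 else eq[0]
                )
                # tail = terminal run of mismatches of the assigned placement
                mism = set(chosen.mismatch_positions)
                t = 0
                while (L - 1 - t) in mism:
                    t += 1
                tail = TailCall.from_seq(read[L - t :], mode)
                span = L - t
                start = chosen.start if chosen.strand == "+" else chosen.start + t
                internal = sum(1 for p in chosen.mismatch_positions if p < L - t)
                rows.append(
                    (rid, True, chosen.chrom, start, start + span, chosen.strand,
                     span, internal, len(eq), tail.tail_length, tail.tail_seq,
                     tail.tail_category, L, sq.to_rna(read[0]), mode)
                )
                continue

        rows.append(
            (rid, False, "", -1, -1, "", 0, 0, 0, 0, "", "none",
             L, sq.to_rna(read[0]) if read else "", mode)
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
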