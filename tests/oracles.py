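"""Brute-force reference implementations used only by the test suite.

These scan every genome position on both strands with plain Python string
comparison and early exits; they share no code with srtail.align.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _strands(genome: dict[str, str]):
    for chrom in sorted(genome):
        yield chrom, "+", genome[chrom]
        yield chrom, "-", _revcomp(genome[chrom])


def bf_full_placements(read: str, genome: dict[str, str], max_mm: int = 2):
    """All full-length placements with <= max_mm substitutions.

    Returns a sorted list of (n_mm, chrom, forward_start, strand,
    mismatch_positions tuple).
    """
    L = len(read)
    out = []
    for chrom, strand, s in _strands(genome):
        n = len(s)
        for p in range(n - L + 1):
            mm = []
            for i in range(L):
                if s[p + i] != read[i]:
                    mm.append(i)
                    if len(mm) > max_mm:
                        break
            if len(mm) <= max_mm:
                fwd = p if strand == "+" else n - p - L
                out.append((len(mm), chrom, fwd, strand, tuple(mm)))
    return sorted(out)


def bf_longest_exact_prefix(read: str, genome: dict[str, str]):
    """(longest exact prefix length, placements achieving it).

    Placements are (chrom, forward_start_of_prefix, strand), sorted.
    """
    L = len(read)
    best = 0
    hits = []
    for chrom, strand, s in _strands(genome):
        n = len(s)
        for p in range(n):
            ext = 0
            limit = min(L, n - p)
            while ext < limit and s[p + ext] == read[ext]:
                ext += 1
            if ext > best:
                best = ext
                hits = [(chrom, strand, p)]
            elif ext == best and ext > 0:
                hits.append((chrom, strand, p))
    fwd = sorted(
        (chrom, (p if strand == "+" else len(genome[chrom]) - p - best), strand)
        for chrom, strand, p in hits
    )
    return best, fwd


def bf_exact_prefix_tail(read: str, genome: dict[str, str], min_prefix=18, max_tail=3):
    """Tail called by the longest-exact-prefix rule, or None if unmapped."""
    best, hits = bf_longest_exact_prefix(read, genome)
    if best < max(min_prefix, len(read) - max_tail) or not hits:
        return None
    return read[best:]


def bf_terminal_mismatch_tail(read: str, genome: dict[str, str], max_mm: int = 2):
    """Tail of the canonical fewest-mismatch full-length placement, or None."""
    found = bf_full_placements(read, genome, max_mm=max_mm)
    if not found:
        return None
    n_mm, chrom, fwd, strand, mm = found[0]
    L = len(read)
    mm = set(mm)
    t = 0
    while (L - 1 - t) in mm:
        t += 1
    return read[L - t :]
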