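"""Summary statistics over a classified per-read table.

All functions operate on the per-read DataFrame produced by
``align.align_sample`` + ``classify.classify_sample`` (columns: mapped,
read_class, tail_len, tail_seq, tail_category, read_len, aligned_span,
five_prime, ...). "Tailed" means tail_len >= 1 under the configured
calling mode; mixed-composition tails fall in the "other" category.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: classes the wild type tails at ~25% (centromeric siRNAs plus the
#: mRNA/ncRNA-derived priRNAs — the high-tailing group)
HIGH_TAILING_CLASSES = (
    "centromeric", "mRNA_sense", "mRNA_antisense", "ncRNA_sense", "ncRNA_antisense",
)
#: classes tailed at only ~5% in wild type
LOW_TAILING_CLASSES = ("tRNA", "rRNA_sense")


def _mapped(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["mapped"].astype(bool)]


def class_composition(table: pd.DataFrame) -> pd.Series:
    """Fraction of mapped reads per class (sums to 1)."""
    m = _mapped(table)
    if len(m) == 0:
        return pd.Series(dtype=float)
    return (m["read_class"].value_counts() / len(m)).sort_index()


def tailing_fraction(table: pd.DataFrame, by: str = "class"):
    """n_tailed / n_reads, globally or per class.

    ``by='global'`` returns a float over all mapped reads; ``by='class'``
    returns a Series indexed by class (empty classes are absent, not zero).
    A tuple/list of class labels pools those classes into one fraction.
    """
    m = _mapped(table)
    tailed = m["tail_len"] >= 1
    if by == "global":
        return float(tailed.mean()) if len(m) else float("nan")
    if by == "class":
        grp = tailed.groupby(m["read_class"])
        return grp.mean().sort_index()
    if isinstance(by, (tuple, list, set)):
        sub = m[m["read_class"].isin(by)]
        return float((sub["tail_len"] >= 1).mean()) if len(sub) else float("nan")
    raise ValueError(f"by must be 'global', 'class' or a class list, got {by!r}")


def tail_composition(table: pd.DataFrame, per_nucleotide: bool = False) -> dict[str, float]:
    """Composition of called tails.

    Per-read (default): fractions of tailed reads whose tail is all-A,
    all-U, or mixed/other -> keys A_tail, U_tail, other. Per-nucleotide:
    base shares among all called tail nucleotides -> keys A, U, C, G.
    Returns {} when there are no tailed reads (no division error).
    """
    m = _mapped(table)
    tails = m.loc[m["tail_len"] >= 1, "tail_seq"]
    if len(tails) == 0:
        return {}
    if per_nucleotide:
        counts = {b: 0 for b in "AUCG"}
        for t in tails:
            for b in t:
                counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}
    cats = m.loc[m["tail_len"] >= 1, "tail_category"].value_counts()
    n = int(cats.sum())
    return {cat: int(cats.get(cat, 0)) / n for cat in ("A_tail", "U_tail", "other")}


def length_distribution(table: pd.DataFrame, by: str | None = None) -> dict:
    """Read-length histograms, with the tail included and excluded.

    Returns {'with_tail': Series, 'without_tail': Series, 'mode_with_tail',
    'mode_without_tail'}; with ``by='class'``, a dict of such dicts keyed by
    class. Tail-excluded lengths are the aligned (templated) spans.
    """
    m = _mapped(table)
    if by == "class":
        return {
            cls: length_distribution(m[m["read_class"] == cls])
            for cls in sorted(m["read_class"].unique())
        }
    with_tail = m["read_len"].value_counts().sort_index()
    without = m["aligned_span"].value_counts().sort_index()
    return {
        "with_tail": with_tail,
        "without_tail": without,
        "mode_with_tail": int(with_tail.idxmax()) if len(with_tail) else None,
        "mode_without_tail": int(without.idxmax()) if len(without) else None,
    }


def five_prime_composition(table: pd.DataFrame) -> pd.Series:
    """Base frequencies at read position 1 (RNA letters; sums to 1)."""
    m = _mapped(table)
    if len(m) == 0:
        return pd.Series(dtype=float)
    return (m["five_prime"].value_counts() / len(m)).sort_index()


def rpm(counts, total_reads: int):
    """Reads-per-million normalisation: count * 1e6 / total_reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return counts * 1.0e6 / total_reads


def ago_scale(rpm_values, scale_factor: float):
    """Scale RPM values by a per-sample Argonaute-pulldown factor (> 0)."""
    if scale_factor <= 0:
        raise ValueError("scale factor must be > 0")
    return rpm_values * scale_factor


@dataclass
class TailingSummary:
    """Per-class and global tailing statistics of one sample."""

    per_class: pd.DataFrame  # n_reads, n_tailed, tailing_fraction, A/U/other, rpm
    total_reads: int
    mapped_reads: int
    global_tailing_fraction: float
    tail_composition_per_read: dict[str, float]
    tail_composition_per_nt: dict[str, float]
    five_prime: pd.Series
    length_hist: dict

    def to_tsv(self, path) -> None:
        self.per_class.to_csv(path, sep="\t", float_format="%.6f")


def summarize(table: pd.DataFrame, scale_factor: float = 1.0) -> TailingSummary:
    """Full per-class + global summary of a classified per-read table."""
    m = _mapped(table)
    total = len(table)
    rows = []
    for cls, sub in m.groupby("read_class"):
        tailed = sub[sub["tail_len"] >= 1]
        cats = tailed["tail_category"].value_counts()
        n_t = len(tailed)
        rows.append(
            {
                "read_class": cls,
                "n_reads": len(sub),
                "n_tailed": n_t,
                "tailing_fraction": n_t / len(sub),
                "frac_A_tail": (cats.get("A_tail", 0) / n_t) if n_t else 0.0,
                "frac_U_tail": (cats.get("U_tail", 0) / n_t) if n_t else 0.0,
                "frac_other_tail": (cats.get("other", 0) / n_t) if n_t else 0.0,
                "rpm": ago_scale(rpm(len(sub), total), scale_factor),
            }
        )
    per_class = pd.DataFrame(rows).set_index("read_class").sort_index() if rows else pd.DataFrame()
    return TailingSummary(
        per_class=per_class,
        total_reads=total,
        mapped_reads=len(m),
        global_tailing_fraction=tailing_fraction(table, by="global"),
        tail_composition_per_read=tail_composition(table),
        tail_composition_per_nt=tail_composition(table, per_nucleotide=True),
        five_prime=five_prime_composition(table),
        length_hist=length_distribution(table),
    )
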