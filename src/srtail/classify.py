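"""Strand-aware annotation of small-RNA reads.

A :class:`FeatureDB` holds genomic features (centromeric repeats, tRNAs,
rRNAs, mRNAs with exon children, ncRNAs) plus introns synthesised from the
gaps between each mRNA's exons. :func:`classify` assigns a mapped read to
exactly one small-RNA class:

    centromeric, tRNA, rRNA_sense, rRNA_antisense, mRNA_sense,
    mRNA_antisense, ncRNA_sense, ncRNA_antisense, intronic, intergenic

Type priority is configurable (default: centromeric > tRNA > rRNA >
mRNA exon > intronic > ncRNA > intergenic); sense/antisense is resolved
after the feature type by comparing the read strand with the feature
strand. A read takes a feature's class only if it overlaps the feature by
at least ``min_overlap_frac`` of its own length; "intronic" additionally
requires full containment within an intron on the mRNA's own strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

#: class labels, in no particular order
CLASSES = (
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

#: default feature-type priority for reads overlapping several features
DEFAULT_PRIORITY = ("centromeric", "tRNA", "rRNA", "mRNA", "intronic", "ncRNA")

#: feature types whose classes carry a sense/antisense suffix
_STRANDED_TYPES = {"rRNA", "mRNA", "ncRNA"}

_GFF_TYPE_TO_KIND = {
    "centromeric_repeat": "centromeric",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "exon": "mRNA",
    "intron": "intronic",
    "ncRNA": "ncRNA",
}


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 0-based half-open coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    ftype: str  # centromeric_repeat | tRNA | rRNA | mRNA | exon | intron | ncRNA
    parent_id: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.feature_id}: empty interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


class FeatureDB:
    """Annotation container with per-chromosome interval lookup.

    Parameters
    ----------
    features : iterable of Feature
        Top-level features plus exon children of mRNAs. Intron features are
        synthesised here (one per within-mRNA exon gap); an exonless mRNA is
        treated as single-exon.
    chrom_lengths : dict, optional
        Chromosome sizes; if given, features are validated against them.
    """

    def __init__(self, features, chrom_lengths: dict[str, int] | None = None):
        feats = list(features)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        by_id = {}
        for f in feats:
            if f.feature_id in by_id:
                raise ValueError(f"duplicate feature id {f.feature_id}")
            by_id[f.feature_id] = f
            if self.chrom_lengths is not None:
                n = self.chrom_lengths.get(f.chrom)
                if n is None or f.start < 0 or f.end > n:
                    raise ValueError(
                        f"{f.feature_id}: interval [{f.start},{f.end}) outside {f.chrom}"
                    )

        # group exons under parents, validate, synthesise introns
        exons_by_parent: dict[str, list[Feature]] = {}
        for f in feats:
            if f.ftype == "exon":
                if f.parent_id is None:
                    raise ValueError(f"exon {f.feature_id} has no parent mRNA")
                exons_by_parent.setdefault(f.parent_id, []).append(f)

        introns: list[Feature] = []
        for parent_id, exons in exons_by_parent.items():
            exons = sorted(exons, key=lambda e: e.start)
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping exons {a.feature_id}/{b.feature_id} in {parent_id}"
                    )
                if b.start > a.end:
                    introns.append(
                        Feature(
                            feature_id=f"{parent_id}.intron{len(introns) + 1}",
                            chrom=a.chrom,
                            start=a.end,
                            end=b.start,
                            strand=a.strand,
                            ftype="intron",
                            parent_id=parent_id,
                        )
                    )
        # an mRNA without exon children acts as its own single exon
        for f in feats:
            if f.ftype == "mRNA" and f.feature_id not in exons_by_parent:
                exons_by_parent[f.feature_id] = [
                    Feature(
                        feature_id=f"{f.feature_id}.exon1",
                        chrom=f.chrom,
                        start=f.start,
                        end=f.end,
                        strand=f.strand,
                        ftype="exon",
                        parent_id=f.feature_id,
                    )
                ]
                feats.append(exons_by_parent[f.feature_id][0])

        self.features: list[Feature] = feats + introns
        self._by_id = {f.feature_id: f for f in self.features}
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            if f.ftype == "mRNA":
                continue  # mRNA bodies are represented by their exons/introns
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def by_type(self, ftype: str) -> list[Feature]:
        out = [f for f in self.features if f.ftype == ftype]
        return sorted(out, key=lambda f: (f.chrom, f.start, f.feature_id))

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda f: (f.start, f.end, f.feature_id))

    def intergenic_intervals(self, min_length: int = 1) -> list[tuple[str, int, int]]:
        """Maximal intervals covered by no feature, per chromosome."""
        if self.chrom_lengths is None:
            raise ValueError("chromosome lengths unknown")
        out = []
        for chrom, n in sorted(self.chrom_lengths.items()):
            ivs = sorted(
                (f.start, f.end)
                for f in self.features
                if f.chrom == chrom and f.ftype != "exon" and f.ftype != "intron"
            )
            pos = 0
            for s, e in ivs:
                if s - pos >= min_length:
                    out.append((chrom, pos, s))
                pos = max(pos, e)
            if n - pos >= min_length:
                out.append((chrom, pos, n))
        return out

    # ------------------------------------------------------------------ GFF3

    def to_gff3(self, path) -> None:
        """Write the annotation as GFF3 (1-based inclusive; introns omitted)."""
        rows = []
        for f in sorted(self.features, key=lambda f: (f.chrom, f.start, f.feature_id)):
            if f.ftype == "intron":
                continue  # derived, not written
            attrs = f"ID={f.feature_id}"
            if f.parent_id is not None:
                attrs += f";Parent={f.parent_id}"
            rows.append(
                f"{f.chrom}\tsrtail\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}"
            )
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write("\n".join(rows))
            if rows:
                fh.write("\n")


def load_annotation(gff3_path) -> FeatureDB:
    """Parse a GFF3 file into a :class:`FeatureDB` (introns synthesised).

    Raises ``ValueError`` with the offending line number on malformed input.
    """
    import gffutils

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff3_path}: line {lineno}: expected 9 columns, got {len(cols)}")
            try:
                s, e = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{gff3_path}: line {lineno}: non-integer coordinates") from exc
            if s < 1 or e < s:
                raise ValueError(f"{gff3_path}: line {lineno}: bad interval {s}..{e}")

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for rec in db.all_features():
        parents = rec.attributes.get("Parent")
        feats.append(
            Feature(
                feature_id=rec.id,
                chrom=rec.seqid,
                start=rec.start - 1,
                end=rec.end,
                strand=rec.strand,
                ftype=rec.featuretype,
                parent_id=parents[0] if parents else None,
            )
        )
    return FeatureDB(feats)


# ---------------------------------------------------------------- classifier


def classify(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    db: FeatureDB,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    min_overlap_frac: float = 0.5,
) -> tuple[str, str]:
    """Assign one class label to a mapped read interval.

    Returns ``(class_label, feature_id)``; intergenic reads get feature_id "".
    The read interval should be the templated (tail-excluded) span.
    """
    read_len = end - start
    hits = db.overlapping(chrom, start, end)
    by_kind: dict[str, list[Feature]] = {}
    for f in hits:
        kind = _GFF_TYPE_TO_KIND.get(f.ftype)
        if kind is not None:
            by_kind.setdefault(kind, []).append(f)

    for kind in priority:
        cands = by_kind.get(kind, [])
        if kind == "intronic":
            # full containment within an intron, read on the mRNA's strand
            cands = [
                f for f in cands if f.start <= start and end <= f.end and f.strand == strand
            ]
            if cands:
                return "intronic", cands[0].feature_id
            continue
        cands = [
            f
            for f in cands
            if min(end, f.end) - max(start, f.start) >= min_overlap_frac * read_len
        ]
        if not cands:
            continue
        if kind in _STRANDED_TYPES:
            sense = [f for f in cands if f.strand == strand]
            chosen = sense[0] if sense else cands[0]
            label = f"{kind}_{'sense' if sense else 'antisense'}"
        else:
            chosen = cands[0]
            label = kind
        fid = chosen.parent_id if chosen.ftype == "exon" else chosen.feature_id
        return label, fid
    return "intergenic", ""


def classify_sample(
    table: pd.DataFrame,
    db: FeatureDB,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Add ``read_class`` and ``feature_id`` columns to a per-read table.

    Unmapped rows get class "unmapped" and an empty feature id; row count and
    order are preserved.
    """
    out = table.copy()
    labels, fids = [], []
    for row in out.itertuples(index=False):
        if not row.mapped:
            labels.append("unmapped")
            fids.append("")
            continue
        label, fid = classify(
            row.chrom, int(row.start0), int(row.end0), row.strand, db,
            priority=priority, min_overlap_frac=min_overlap_frac,
        )
        labels.append(label)
        fids.append(fid)
    out["read_class"] = labels
    out["feature_id"] = fids
    return out
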