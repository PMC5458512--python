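"""Low-level sequence helpers shared across modules.

All sequences are DNA-space uppercase strings (uridine is written T in read
sequences, as in sequencer output); user-facing reports convert T -> U.
Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
1-based inclusive.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# numeric encoding used by the vectorised scanner
_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def to_rna(seq: str) -> str:
    """DNA-space read bases to RNA-space for reporting (T -> U)."""
    return seq.replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{wrap_fasta(seq, width)}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, records: list[tuple[str, str]], qual_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_reads(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (sniffed from the first byte) as (id, seq) pairs."""
    from Bio import SeqIO

    with open(path) as fh:
        first = fh.read(1)
    if first == "":
        return []
    fmt = {">": "fasta", "@": "fastq"}.get(first)
    if fmt is None:
        raise ValueError(f"{path}: not FASTA or FASTQ (first byte {first!r})")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
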