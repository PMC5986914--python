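"""FASTA input/output (thin wrappers over Bio.SeqIO)."""

from __future__ import annotations

from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into ``(id, uppercase sequence)`` tuples."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [sid for sid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 70) -> None:
    """Write ``(id, sequence)`` tuples as wrapped FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records),
        str(path),
        "fasta",
    )
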