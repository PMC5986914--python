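"""Position weight matrices: parsing, regularization and consensus calls.

A motif is stored as a ``width x 4`` matrix of per-position nucleotide
probabilities over A, C, G, T.  Matrices read from flat files (JASPAR or
TRANSFAC-style count blocks) are regularized with a small additive
pseudocount so that every cell is strictly positive and log-odds scores
stay finite.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
#: additive pseudocount applied to every cell of a parsed count matrix
PSEUDOCOUNT = 0.01


class MotifParseError(ValueError):
    """Raised when a motif flat file cannot be parsed."""


@dataclasses.dataclass(frozen=True)
class MotifMatrix:
    """One position weight matrix.

    Parameters
    ----------
    motif_id :
        Unique identifier (e.g. ``MA0003.1`` or ``DECOY_004``).
    name :
        Human-readable factor name; may equal ``motif_id``.
    probs :
        ``(width, 4)`` array of per-position probabilities over A, C, G, T.
        Every row sums to 1 and every cell is strictly positive.
    score_threshold :
        Optional per-motif match-score cut-off on the min-max normalized
        log-odds scale in [0, 1]; ``None`` defers to the run configuration.
    """

    motif_id: str
    name: str
    probs: np.ndarray
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: probs must be (width, 4)")
        if not np.all(probs > 0):
            raise ValueError(f"{self.motif_id}: probabilities must be > 0")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        if self.score_threshold is not None and not 0 <= self.score_threshold <= 1:
            raise ValueError(f"{self.motif_id}: score_threshold outside [0, 1]")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return consensus(self)


def _regularize(counts: np.ndarray, motif_id: str) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise MotifParseError(f"{motif_id}: negative matrix entry")
    row_sums = counts.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = int(np.nonzero(row_sums <= 0)[0][0])
        raise MotifParseError(f"{motif_id}: row {bad + 1} sums to zero")
    counts = counts + PSEUDOCOUNT
    return counts / counts.sum(axis=1, keepdims=True)


def motif_from_counts(
    motif_id: str,
    counts: np.ndarray,
    name: str | None = None,
    score_threshold: float | None = None,
) -> MotifMatrix:
    """Build a :class:`MotifMatrix` from raw counts (or probabilities).

    A pseudocount of 0.01 is added to every cell before row normalization.
    """
    return MotifMatrix(
        motif_id=motif_id,
        name=name or motif_id,
        probs=_regularize(counts, motif_id),
        score_threshold=score_threshold,
    )


def read_motifs(path, fmt: str = "jaspar") -> list[MotifMatrix]:
    """Read a PWM library from a flat file.

    Parameters
    ----------
    path :
        Path to the motif file.
    fmt :
        ``"jaspar"`` (JASPAR 2016 flat format) or ``"transfac"``
        (``P0``/``01..XX`` count blocks).

    Returns
    -------
    list of MotifMatrix
        Counts are pseudocount-regularized (0.01 per cell) and row
        normalized.  An empty file yields an empty list.

    Raises
    ------
    MotifParseError
        On malformed records, duplicate identifiers, or all-zero count rows.
    """
    fmt = fmt.lower()
    if fmt not in {"jaspar", "transfac"}:
        raise ValueError(f"unknown motif format: {fmt!r}")
    with open(path) as handle:
        text = handle.read()
    if not text.strip():
        return []
    try:
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, "jaspar" if fmt == "jaspar" else "TRANSFAC")
    except Exception as exc:  # Bio raises bare ValueError/KeyError on bad input
        raise MotifParseError(f"{path}: cannot parse as {fmt}: {exc}") from exc

    out: list[MotifMatrix] = []
    seen: set[str] = set()
    for m in parsed:
        if fmt == "jaspar":
            motif_id = m.matrix_id or m.name
            name = m.name or motif_id
        else:  # transfac motifs behave like dicts of field -> value
            motif_id = m.get("AC") or m.get("ID") or m.name
            name = m.get("ID") or motif_id
        if motif_id in seen:
            raise MotifParseError(f"{path}: duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T
        out.append(motif_from_counts(motif_id, counts, name=name))
    return out


def write_motifs_jaspar(motifs: Iterable[MotifMatrix], path, scale: float = 100.0) -> None:
    """Write motifs as JASPAR count blocks (probabilities scaled by ``scale``)."""
    records = []
    for m in motifs:
        counts = {b: (m.probs[:, i] * scale).tolist() for i, b in enumerate(BASES)}
        rec = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        rec.matrix_id = m.motif_id
        rec.name = m.name
        records.append(rec)
    with open(path, "w") as handle:
        handle.write(bio_motifs.write(records, "jaspar"))


def consensus(motif: MotifMatrix) -> str:
    """Consensus sequence: per position the most probable base.

    Ties are broken in fixed order A < C < G < T (``argmax`` convention).
    """
    return "".join(BASES[i] for i in np.argmax(motif.probs, axis=1))


def reverse_complement_probs(probs: np.ndarray) -> np.ndarray:
    """PWM for the reverse strand: reverse positions, swap A<->T, C<->G."""
    return probs[::-1, ::-1]
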