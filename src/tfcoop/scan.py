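"""Log-odds PWM scanning of promoter sequences.

Every window on both strands is scored as a log2-odds ratio of the motif
model against a per-sequence mononucleotide background (frequencies
floored at 0.01).  Raw scores are min-max normalized onto [0, 1] using the
motif's attainable score range under that same background, so a fractional
threshold (default 0.85) means "within the top 15% of the attainable
log-odds range".  Windows overlapping an ``N`` are unmatchable.

The inner loop is compiled with numba because background-correction runs
re-scan many shuffled copies of the input set.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .motifs import MotifMatrix, reverse_complement_probs

# A=0 C=1 G=2 T=3 N=4; anything else is rejected
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_BG_FLOOR = 0.01


@dataclasses.dataclass(frozen=True)
class BindingSite:
    """One predicted TFBS occurrence, in forward coordinates.

    ``start``/``end`` are 0-based half-open; ``score`` is the min-max
    normalized log-odds match score in [0, 1]; ``center`` is the midpoint
    ``start + (width - 1) / 2`` used for pair distances.
    """

    sequence_id: str
    motif_id: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid site interval")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return self.start + (self.width - 1) / 2


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N (case-insensitive) as int8 codes 0..4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if np.any(codes < 0):
        bad = seq[int(np.nonzero(codes < 0)[0][0])]
        raise ValueError(f"non-IUPAC character in sequence: {bad!r}")
    return codes


def _background_log2(codes_list: Sequence[np.ndarray]) -> np.ndarray:
    """Per-sequence log2 background frequencies, shape (n_seqs, 5).

    Frequencies are computed over non-N positions, floored at 0.01 and
    renormalized; the N column is 0 so that the motif term alone decides
    the fate of N windows (it is NaN there).
    """
    out = np.zeros((len(codes_list), 5))
    for s, codes in enumerate(codes_list):
        counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
        total = counts.sum()
        freqs = counts / total if total > 0 else np.full(4, 0.25)
        freqs = np.maximum(freqs, _BG_FLOOR)
        freqs /= freqs.sum()
        out[s, :4] = np.log2(freqs)
    return out


@njit(cache=True)
def _score_kernel(codes, lengths, lpm, lbg):
    """Raw log-odds scores.

    codes : (n_seq, Lmax) int8, padded with 4 (N)
    lengths : (n_seq,) int64 true lengths
    lpm : (w, 5) float64 log2 motif probabilities, lpm[:, 4] = NaN
    lbg : (n_seq, 5) float64 log2 background, lbg[:, 4] = 0
    returns (n_seq, Lmax - w + 1) float64, NaN = unmatchable window
    """
    n_seq, Lmax = codes.shape
    w = lpm.shape[0]
    n_win = Lmax - w + 1
    out = np.full((n_seq, n_win if n_win > 0 else 0), np.nan)
    for s in range(n_seq):
        n_here = lengths[s] - w + 1
        for i in range(n_here):
            acc = 0.0
            for p in range(w):
                b = codes[s, i + p]
                acc += lpm[p, b] - lbg[s, b]
            out[s, i] = acc
    return out


def _attainable_range(lpm4: np.ndarray, lbg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence (min, max) attainable raw score for a motif.

    ``lpm4``: (w, 4) log2 motif probs; ``lbg``: (n_seq, 5) log2 background.
    """
    diff = lpm4[None, :, :] - lbg[:, None, :4]  # (n_seq, w, 4)
    return diff.min(axis=2).sum(axis=1), diff.max(axis=2).sum(axis=1)


def _scan_prepared(
    codes: np.ndarray,
    lengths: np.ndarray,
    lbg: np.ndarray,
    seq_ids: Sequence[str],
    motif: MotifMatrix,
    threshold: float,
) -> list[BindingSite]:
    w = motif.width
    sites: list[BindingSite] = []
    if codes.shape[1] < w:
        return sites
    lpm4_fwd = np.log2(motif.probs)
    lpm4_rev = np.log2(reverse_complement_probs(motif.probs))

    # each strand is normalized over its own attainable range; this keeps
    # scores exactly mirror-symmetric under reverse complementation
    per_strand = {}
    for strand, lpm4 in (("+", lpm4_fwd), ("-", lpm4_rev)):
        smin, smax = _attainable_range(lpm4, lbg)
        span = smax - smin
        degenerate = span < 1e-12
        span = np.where(degenerate, 1.0, span)
        lpm = np.full((w, 5), np.nan)
        lpm[:, :4] = lpm4
        raw = _score_kernel(codes, lengths, lpm, lbg)
        norm = (raw - smin[:, None]) / span[:, None]
        norm[degenerate, :] = np.nan
        per_strand[strand] = norm

    # merge the two strands preserving ascending start order, '+' first
    for s, seq_id in enumerate(seq_ids):
        hits: list[tuple[int, int, float]] = []  # (start, strand_rank, score)
        for rank, strand in enumerate("+-"):
            norm = per_strand[strand][s]
            idx = np.nonzero(norm >= threshold - 1e-9)[0]
            for i in idx:
                hits.append((int(i), rank, float(min(norm[i], 1.0))))
        hits.sort()
        for start, rank, score in hits:
            sites.append(
                BindingSite(
                    sequence_id=seq_id,
                    motif_id=motif.motif_id,
                    start=start,
                    end=start + w,
                    strand="+-"[rank],
                    score=score,
                )
            )
    return sites


def _prepare(seqs: Sequence[tuple[str, str]]):
    codes_list = [encode_sequence(seq) for _, seq in seqs]
    lengths = np.array([len(c) for c in codes_list], dtype=np.int64)
    Lmax = int(lengths.max()) if len(lengths) else 0
    codes = np.full((len(seqs), Lmax), 4, dtype=np.int8)
    for i, c in enumerate(codes_list):
        codes[i, : len(c)] = c
    lbg = _background_log2(codes_list)
    return codes, lengths, lbg


def scan_sequences(
    seqs: Sequence[tuple[str, str]],
    motifs: Iterable[MotifMatrix],
    threshold: float = 0.85,
) -> list[BindingSite]:
    """Scan a set of ``(id, sequence)`` records with a motif library.

    Both strands are scanned at every offset; reverse-strand hits are
    reported in forward coordinates.  A motif's own ``score_threshold``
    overrides ``threshold``.  Sites are returned grouped by sequence in
    input order, then ascending start.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    seq_ids = [sid for sid, _ in seqs]
    if len(set(seq_ids)) != len(seq_ids):
        raise ValueError("duplicate sequence ids")
    if not seqs:
        return []
    codes, lengths, lbg = _prepare(seqs)
    per_seq: dict[str, list[BindingSite]] = {sid: [] for sid in seq_ids}
    for motif in motifs:
        t = motif.score_threshold if motif.score_threshold is not None else threshold
        for site in _scan_prepared(codes, lengths, lbg, seq_ids, motif, t):
            per_seq[site.sequence_id].append(site)
    out: list[BindingSite] = []
    for sid in seq_ids:
        out.extend(sorted(per_seq[sid], key=lambda x: (x.start, x.end, x.motif_id, x.strand)))
    return out


def scan_sequence(
    seq: str, seq_id: str, motif: MotifMatrix, threshold: float = 0.85
) -> list[BindingSite]:
    """Scan a single sequence with a single motif (see :func:`scan_sequences`)."""
    if len(seq) < motif.width:
        encode_sequence(seq)  # still validate the alphabet
        return []
    return scan_sequences([(seq_id, seq)], [motif], threshold=threshold)


def write_bed(sites: Iterable[BindingSite], path) -> None:
    """Export sites as BED6 (chrom = sequence id, score = 1000 x match score)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.sequence_id}\t{s.start}\t{s.end}\t{s.motif_id}\t"
                f"{round(1000 * s.score)}\t{s.strand}\n"
            )
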