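"""Synthetic promoter sets with planted motif-pair co-occurrences.

The generator emulates a simulation benchmark: random background
sequences (default 200 x 1000 bp, i.i.d. bases) each carrying one
planted pair of motif *consensus* strings at a random center-to-center
spacing of 5-20 bp, in random order and strand.  A library of random
decoy matrices stands in for the rest of a PWM collection, so that
non-planted pairs exist and the column filter sees a realistic spread
of site densities.

The default planted motifs are width 5 so that the smallest spacing
(5 bp, centers) never makes the two planted blocks overlap: the
consensus strings then survive insertion verbatim, which is what the
truth table promises.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import BASES, MotifMatrix, motif_from_counts

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _strong_motif(motif_id: str, consensus: str, weight: float = 85.0) -> MotifMatrix:
    counts = np.full((len(consensus), 4), 5.0)
    for i, b in enumerate(consensus):
        counts[i, BASES.index(b)] = weight
    return motif_from_counts(motif_id, counts)


def default_planted_motifs() -> tuple[MotifMatrix, MotifMatrix]:
    """The bundled pair of sharp width-5 motifs used for planting."""
    return (
        _strong_motif("PLANT_A", "TGACG"),
        _strong_motif("PLANT_B", "GGAAT"),
    )


@dataclasses.dataclass
class PlantSpec:
    """Parameters of the planted-pair benchmark.

    Defaults mirror the simulation design: 200 sequences of 1000 bp,
    one planted consensus pair per sequence at center-to-center spacing
    uniform on [5, 20] bp, uniform base composition, 20 decoy motifs.
    """

    n_sequences: int = 200
    length: int = 1000
    motif_a: MotifMatrix | None = None
    motif_b: MotifMatrix | None = None
    spacing_min: float = 5.0
    spacing_max: float = 20.0
    insertions_per_sequence: int = 1
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    decoys: int = 20

    def __post_init__(self) -> None:
        if self.motif_a is None or self.motif_b is None:
            a, b = default_planted_motifs()
            self.motif_a = self.motif_a or a
            self.motif_b = self.motif_b or b
        if self.spacing_min > self.spacing_max:
            raise ValueError("spacing_min must be <= spacing_max")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp <= 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 positive probabilities summing to 1")
        # 0 insertions = pure background sequences (null calibration sets)
        if self.insertions_per_sequence < 0:
            raise ValueError("insertions_per_sequence must be >= 0")


def generate_dataset(spec: PlantSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate the planted benchmark: (records, truth table).

    Records are ``(id, sequence)`` tuples.  The truth table (BED-like)
    records every planted interval: sequence, start, end, strand,
    motif_id, pair_index and the realized center spacing.  Runs are
    byte-reproducible for a fixed spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    a, b = spec.motif_a, spec.motif_b
    wa, wb = a.width, b.width
    cons = {a.motif_id: a.consensus, b.motif_id: b.consensus}

    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    bases = np.array(list(BASES))
    for i in range(spec.n_sequences):
        sid = f"seq_{i:04d}"
        seq = rng.choice(bases, size=spec.length, p=spec.base_composition)
        occupied: list[tuple[int, int]] = []
        for pair_index in range(spec.insertions_per_sequence):
            left, right = (a, b) if rng.integers(2) == 0 else (b, a)
            wl, wr = left.width, right.width
            # center spacing s = d + (wr - wl) / 2 for integer start offset d
            d_lo = int(np.ceil(spec.spacing_min - (wr - wl) / 2))
            d_hi = int(np.floor(spec.spacing_max - (wr - wl) / 2))
            if d_lo > d_hi:
                raise ValueError("no integer start offset realizes the spacing window")
            block = d_hi + wr
            if block > spec.length:
                raise ValueError("spacing window infeasible for sequence length")
            for _ in range(200):
                d = int(rng.integers(d_lo, d_hi + 1))
                start_l = int(rng.integers(0, spec.length - (d + wr) + 1))
                start_r = start_l + d
                span = (start_l, max(start_l + wl, start_r + wr))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    break
            else:
                raise ValueError("could not place non-overlapping insertions")
            occupied.append(span)
            spacing = d + (wr - wl) / 2
            for m, start in ((left, start_l), (right, start_r)):
                strand = "+" if rng.integers(2) == 0 else "-"
                text = cons[m.motif_id]
                if strand == "-":
                    text = _reverse_complement(text)
                seq[start : start + m.width] = list(text)
                truth_rows.append(
                    {
                        "sequence": sid,
                        "start": start,
                        "end": start + m.width,
                        "strand": strand,
                        "motif_id": m.motif_id,
                        "pair_index": pair_index,
                        "spacing": spacing,
                    }
                )
        records.append((sid, "".join(seq)))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sequence", "start", "end", "strand", "motif_id", "pair_index", "spacing"],
    )
    return records, truth


def random_decoy_motifs(
    count: int,
    width_range: tuple[int, int] = (4, 12),
    sharpness: float = 1000.0,
    seed: int = 0,
    exclude_consensus: Sequence[str] = (),
) -> list[MotifMatrix]:
    """Random peaked PWMs standing in for the rest of a matrix library.

    Each column is Dirichlet with concentration ``sharpness`` on one
    uniformly chosen preferred base and 1 elsewhere; larger sharpness
    gives crisper columns (degenerate in the limit).  The first two
    decoys take the shortest width of ``width_range`` — every real
    matrix library contains short, degenerate, hit-dense profiles and
    they shape the column-total spectrum — and the rest draw widths
    uniformly from the remainder of the (inclusive) range.  Ids are
    ``DECOY_001``...

    ``exclude_consensus`` lists strings (e.g. the planted consensi)
    that no decoy consensus may contain on either strand, keeping the
    benchmark's ground truth unambiguous.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    lo, hi = width_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid width_range")
    banned = [e.upper() for e in exclude_consensus]
    banned += [_reverse_complement(e) for e in banned]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[MotifMatrix] = []
    for i in range(count):
        width = lo if i < 2 else int(rng.integers(min(lo + 2, hi), hi + 1))
        for _ in range(100):
            probs = np.empty((width, 4))
            for p in range(width):
                alpha = np.ones(4)
                alpha[int(rng.integers(4))] = sharpness
                probs[p] = rng.dirichlet(alpha)
            # Dirichlet draws are already strictly positive probabilities
            m = MotifMatrix(
                motif_id=f"DECOY_{i + 1:03d}", name=f"DECOY_{i + 1:03d}", probs=probs
            )
            cons = m.consensus
            if not any(b in cons for b in banned):
                break
        else:
            raise RuntimeError("could not draw a decoy avoiding the excluded consensi")
        out.append(m)
    return out


def default_motif_library(spec: PlantSpec) -> list[MotifMatrix]:
    """The benchmark's scanning library: planted pair + screened decoys."""
    decoys = random_decoy_motifs(
        spec.decoys,
        seed=spec.seed,
        exclude_consensus=(spec.motif_a.consensus, spec.motif_b.consensus),
    )
    return [spec.motif_a, spec.motif_b] + decoys


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Write the truth table as a BED-like TSV."""
    truth.to_csv(path, sep="\t", index=False)
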