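"""Core co-occurrence scoring: from predicted sites to z-scored motif pairs.

The pipeline proceeds in six phases:

1. tally predicted sites into a sequence x motif count matrix and drop
   columns with extreme totals (over/under-represented motifs);
2. keep only sites whose sequence/motif pointwise mutual information
   (PMI) is strictly positive — the "important" sites of each sequence;
3. resolve overlapping same-motif sites, keeping the one closest to the
   transcription start site;
4. form unordered site pairs whose center distance lies within
   [d_min, d_max] (defaults 5 and 20 bp);
5. score every motif pair with a weighted cumulative PMI, sequences
   weighted by their share of the total pair count;
6. apply the average product correction (APC) and transform the
   corrected scores to z-scores; pairs with z >= 3 are significant.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scan import BindingSite

logger = logging.getLogger(__name__)

LABEL_SIGNIFICANT = "significant"
LABEL_NOT_SIGNIFICANT = "not_significant"
LABEL_SPECIFIC = "specific"
LABEL_COMMON = "common"


class DegenerateScoresError(ValueError):
    """Raised when the pair-score distribution cannot support a correction."""


@dataclasses.dataclass
class SiteSequenceMatrix:
    """Sequence x motif frequency matrix; entry (i, j) counts sites of motif j in sequence i."""

    seq_ids: list[str]
    motif_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.seq_ids), len(self.motif_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")


@dataclasses.dataclass(frozen=True)
class PairOccurrence:
    """One within-sequence co-occurrence of two sites (canonical start order)."""

    sequence_id: str
    site_a: BindingSite
    site_b: BindingSite
    center_distance: float


@dataclasses.dataclass
class PairRecord:
    """One unordered motif pair with its full score trail."""

    motif_a: str
    motif_b: str
    count_per_sequence: dict[str, int]
    pmi_pc: float = math.nan
    pmi_pc_apc: float = math.nan
    z: float = math.nan
    avg_background: float = math.nan
    pmi_specific: float = math.nan
    label: str = LABEL_NOT_SIGNIFICANT

    @property
    def key(self) -> tuple[str, str]:
        return (self.motif_a, self.motif_b)


@dataclasses.dataclass
class PairCollection:
    """All scored pairs of one run plus the per-sequence weights."""

    records: list[PairRecord]
    seq_weights: dict[str, float]
    total_pairs: int

    def record_map(self) -> dict[tuple[str, str], PairRecord]:
        return {r.key: r for r in self.records}

    def significant(self) -> list[PairRecord]:
        return [
            r
            for r in self.records
            if r.label in (LABEL_SIGNIFICANT, LABEL_SPECIFIC, LABEL_COMMON)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "motif_a": r.motif_a,
                    "motif_b": r.motif_b,
                    "pmi_pc": r.pmi_pc,
                    "pmi_pc_apc": r.pmi_pc_apc,
                    "z": r.z,
                    "avg_background": r.avg_background,
                    "pmi_specific": r.pmi_specific,
                    "label": r.label,
                }
                for r in self.records
            ],
            columns=[
                "motif_a",
                "motif_b",
                "pmi_pc",
                "pmi_pc_apc",
                "z",
                "avg_background",
                "pmi_specific",
                "label",
            ],
        )


def pair_key(motif_a: str, motif_b: str) -> tuple[str, str]:
    """Canonical unordered pair key (lexicographic)."""
    return (motif_a, motif_b) if motif_a <= motif_b else (motif_b, motif_a)


# ---------------------------------------------------------------- phase 1


def build_matrix(
    sites: Sequence[BindingSite],
    seq_ids: Sequence[str],
    motif_ids: Sequence[str] | None = None,
) -> SiteSequenceMatrix:
    """Tally sites into the sequence x motif frequency matrix.

    ``motif_ids`` defaults to the sorted set of motifs present in
    ``sites``; sequences and motifs without sites keep zero rows/columns.
    """
    seq_ids = list(seq_ids)
    seq_index = {s: i for i, s in enumerate(seq_ids)}
    if len(seq_index) != len(seq_ids):
        raise ValueError("duplicate sequence ids")
    if motif_ids is None:
        motif_ids = sorted({s.motif_id for s in sites})
    motif_ids = list(motif_ids)
    motif_index = {m: j for j, m in enumerate(motif_ids)}
    counts = np.zeros((len(seq_ids), len(motif_ids)), dtype=np.int64)
    for s in sites:
        i = seq_index.get(s.sequence_id)
        if i is None:
            raise ValueError(f"site references unknown sequence {s.sequence_id!r}")
        j = motif_index.get(s.motif_id)
        if j is None:
            raise ValueError(f"site references unknown motif {s.motif_id!r}")
        counts[i, j] += 1
    return SiteSequenceMatrix(seq_ids, motif_ids, counts)


def filter_columns(
    M: SiteSequenceMatrix, low_q: float = 0.05, high_q: float = 0.95
) -> SiteSequenceMatrix:
    """Drop motif columns with extreme total counts.

    Quantiles (linear interpolation) are computed over the totals of
    columns with at least one site; zero-total columns are always
    dropped.  A column survives iff its total lies inside the closed
    [low_q, high_q] quantile interval.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    totals = M.counts.sum(axis=0)
    nonzero = totals > 0
    if not np.any(nonzero):
        raise ValueError(
            "all motif columns are empty; relax the scan threshold or filter quantiles"
        )
    lo = np.quantile(totals[nonzero], low_q)
    hi = np.quantile(totals[nonzero], high_q)
    keep = nonzero & (totals >= lo) & (totals <= hi)
    if not np.any(keep):
        raise ValueError(
            "column filter removed every motif; relax low_q/high_q"
        )
    kept = [m for m, k in zip(M.motif_ids, keep) if k]
    return SiteSequenceMatrix(M.seq_ids, kept, M.counts[:, keep])


def subset_sites(
    sites: Sequence[BindingSite], motif_ids: Iterable[str]
) -> list[BindingSite]:
    """Restrict a site list to the given motifs (after column filtering)."""
    allowed = set(motif_ids)
    return [s for s in sites if s.motif_id in allowed]


# ---------------------------------------------------------------- phase 2


def pmi_matrix(M: SiteSequenceMatrix) -> np.ndarray:
    """Sequence/motif PMI: log2(p(s,t) / (p(s) p(t))) per cell.

    Joint p(s_i, t_j) = f_ij / F; marginals are row and column sums of
    the joint.  Cells with f_ij = 0 are NaN (never evaluated).
    """
    F = M.counts.sum()
    if F == 0:
        raise ValueError("empty matrix")
    joint = M.counts / F
    ps = joint.sum(axis=1)
    pt = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(joint / (ps[:, None] * pt[None, :]))
    out[M.counts == 0] = np.nan
    return out


def importance_filter(
    M: SiteSequenceMatrix, sites: Sequence[BindingSite]
) -> list[BindingSite]:
    """Keep sites of motif j in sequence i iff PMI(s_i; t_j) > 0 strictly.

    Sites of motifs absent from ``M`` (e.g. removed by the column
    filter) are dropped.
    """
    pmi = pmi_matrix(M)
    seq_index = {s: i for i, s in enumerate(M.seq_ids)}
    motif_index = {m: j for j, m in enumerate(M.motif_ids)}
    kept = []
    for s in sites:
        j = motif_index.get(s.motif_id)
        if j is None:
            continue
        i = seq_index[s.sequence_id]
        if pmi[i, j] > 0:
            kept.append(s)
    return kept


# ---------------------------------------------------------------- phase 3


def resolve_overlaps(
    sites: Sequence[BindingSite], tss_offset: int = 500
) -> list[BindingSite]:
    """Resolve overlapping same-motif sites, keeping the one nearest the TSS.

    Sites of one motif in one sequence are chained transitively into
    overlap clusters; within a cluster the site minimizing
    ``|center - tss_offset|`` survives (ties: smaller start, then '+'
    strand).  Different motifs never compete.  Output is sorted by
    (sequence, start, end, motif, strand).
    """
    groups: dict[tuple[str, str], list[BindingSite]] = defaultdict(list)
    for s in sites:
        groups[(s.sequence_id, s.motif_id)].append(s)
    kept: list[BindingSite] = []
    for group in groups.values():
        group.sort(key=lambda s: (s.start, s.end, s.strand))
        cluster: list[BindingSite] = []
        cluster_end = -1
        for s in group + [None]:  # type: ignore[list-item]
            if s is not None and (not cluster or s.start < cluster_end):
                cluster.append(s)
                cluster_end = max(cluster_end, s.end)
                continue
            if cluster:
                kept.append(
                    min(
                        cluster,
                        key=lambda c: (abs(c.center - tss_offset), c.start, c.strand),
                    )
                )
            if s is not None:
                cluster = [s]
                cluster_end = s.end
    kept.sort(key=lambda s: (s.sequence_id, s.start, s.end, s.motif_id, s.strand))
    return kept


# ---------------------------------------------------------------- phase 4


def build_pairs(
    sites: Sequence[BindingSite],
    d_min: float = 5,
    d_max: float = 20,
    allow_homotypic: bool = False,
) -> list[PairOccurrence]:
    """Enumerate within-sequence site pairs with center distance in [d_min, d_max].

    Bounds are inclusive.  Homotypic pairs (a motif with itself) are
    excluded unless ``allow_homotypic``.
    """
    if d_min > d_max:
        raise ValueError("d_min must be <= d_max")
    by_seq: dict[str, list[BindingSite]] = defaultdict(list)
    for s in sites:
        by_seq[s.sequence_id].append(s)
    pairs: list[PairOccurrence] = []
    for sid in by_seq:
        group = sorted(by_seq[sid], key=lambda s: (s.start, s.end, s.motif_id, s.strand))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if a.motif_id == b.motif_id and not allow_homotypic:
                    continue
                d = abs(a.center - b.center)
                if d_min <= d <= d_max:
                    pairs.append(PairOccurrence(sid, a, b, d))
    return pairs


# ---------------------------------------------------------------- phase 5


def score_pairs(
    pairs: Sequence[PairOccurrence], probability_scope: str = "per-sequence"
) -> PairCollection:
    """Weighted cumulative PMI of every observed motif pair.

    Sequence weights are w_s = N_s / sum(N_s), with N_s the number of
    pair occurrences in sequence s.  With the default per-sequence
    probability scope, the joint p_s(a, b) is the pair's share of the
    N_s occurrences in s and the marginal p_s(a) is motif a's share of
    the 2 N_s pair ends; the pair score is
    sum_s w_s * p_s(a,b) * log2(p_s(a,b) / (p_s(a) p_s(b))), sequences
    without the pair contributing 0.  With ``probability_scope="corpus"``
    the probabilities are pooled over all sequences instead.
    """
    if probability_scope not in ("per-sequence", "corpus"):
        raise ValueError("probability_scope must be 'per-sequence' or 'corpus'")
    if not pairs:
        return PairCollection(records=[], seq_weights={}, total_pairs=0)

    n_s: dict[str, int] = defaultdict(int)
    pair_counts: dict[str, dict[tuple[str, str], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    end_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for p in pairs:
        key = pair_key(p.site_a.motif_id, p.site_b.motif_id)
        n_s[p.sequence_id] += 1
        pair_counts[p.sequence_id][key] += 1
        end_counts[p.sequence_id][p.site_a.motif_id] += 1
        end_counts[p.sequence_id][p.site_b.motif_id] += 1

    total = sum(n_s.values())
    weights = {sid: n / total for sid, n in n_s.items()}

    all_keys = sorted({k for d in pair_counts.values() for k in d})
    per_seq_count: dict[tuple[str, str], dict[str, int]] = {
        k: {} for k in all_keys
    }
    scores: dict[tuple[str, str], float] = {k: 0.0 for k in all_keys}

    if probability_scope == "per-sequence":
        for sid, counts in pair_counts.items():
            N = n_s[sid]
            ends = end_counts[sid]
            for key, c in counts.items():
                per_seq_count[key][sid] = c
                p_ab = c / N
                p_a = ends[key[0]] / (2 * N)
                p_b = ends[key[1]] / (2 * N)
                scores[key] += weights[sid] * p_ab * math.log2(p_ab / (p_a * p_b))
    else:
        pooled_pairs: dict[tuple[str, str], int] = defaultdict(int)
        pooled_ends: dict[str, int] = defaultdict(int)
        for sid, counts in pair_counts.items():
            for key, c in counts.items():
                per_seq_count[key][sid] = c
                pooled_pairs[key] += c
            for m, c in end_counts[sid].items():
                pooled_ends[m] += c
        for key in all_keys:
            p_ab = pooled_pairs[key] / total
            p_a = pooled_ends[key[0]] / (2 * total)
            p_b = pooled_ends[key[1]] / (2 * total)
            scores[key] = p_ab * math.log2(p_ab / (p_a * p_b))

    records = [
        PairRecord(
            motif_a=k[0],
            motif_b=k[1],
            count_per_sequence=dict(per_seq_count[k]),
            pmi_pc=scores[k],
        )
        for k in all_keys
    ]
    return PairCollection(records=records, seq_weights=weights, total_pairs=total)


# ---------------------------------------------------------------- phase 6


def apc_correct(collection: PairCollection) -> PairCollection:
    """Average product correction: subtract mean_a * mean_b / overall_mean.

    ``mean_a`` is the mean raw pair score over the scored pairs that
    involve motif a; the overall mean runs over all scored pairs.
    Pairs never observed are non-entries, not zeros.  Modifies the
    records in place and returns the collection.
    """
    records = collection.records
    if not records:
        return collection
    per_motif: dict[str, list[float]] = defaultdict(list)
    for r in records:
        per_motif[r.motif_a].append(r.pmi_pc)
        per_motif[r.motif_b].append(r.pmi_pc)
    overall = sum(r.pmi_pc for r in records) / len(records)
    if overall == 0:
        raise DegenerateScoresError(
            "mean pair score is zero; APC correction undefined"
        )
    motif_mean = {m: sum(v) / len(v) for m, v in per_motif.items()}
    for r in records:
        r.pmi_pc_apc = r.pmi_pc - motif_mean[r.motif_a] * motif_mean[r.motif_b] / overall
    return collection


def significance(collection: PairCollection, z_threshold: float = 3.0) -> PairCollection:
    """z-transform the APC-corrected scores and label pairs with z >= threshold.

    Uses the sample standard deviation (ddof=1) over all scored pairs.
    A degenerate (zero-spread) distribution yields no significant pair.
    """
    records = collection.records
    if not records:
        return collection
    scores = np.array([r.pmi_pc_apc for r in records])
    if np.any(np.isnan(scores)):
        raise ValueError("run apc_correct before significance")
    mean = scores.mean()
    sd = scores.std(ddof=1) if len(scores) > 1 else 0.0
    if not np.isfinite(sd) or sd == 0:
        logger.warning("zero spread in corrected scores; no pair is significant")
        for r in records:
            r.z = 0.0
            r.label = LABEL_NOT_SIGNIFICANT
        return collection
    for r, z in zip(records, (scores - mean) / sd):
        r.z = float(z)
        r.label = LABEL_SIGNIFICANT if z >= z_threshold else LABEL_NOT_SIGNIFICANT
    return collection
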