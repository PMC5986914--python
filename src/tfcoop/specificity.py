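"""Separating sequence-set-specific motif pairs from ubiquitous ones.

Significant pairs found by the core pipeline mix two populations:
cooperations tied to the particular arrangement of sites in the input
set, and pairings that would co-occur in *any* sequence set with this
nucleotide composition.  To tell them apart, the input sequences are
shuffled l times preserving k-let counts; the full scoring pipeline is
re-run on every shuffled set; and each pair's mean background score

    AVG(a, b) = (1 / l) * sum_i score_i(a, b)

(zero for sets where the pair never forms) is subtracted from its
foreground score, scaled by a factor alpha in [-1, 1]:

    specific(a, b) = score(a, b) - (1 + alpha) * AVG(a, b).

alpha = -1 recovers the uncorrected result, alpha = 0 subtracts the
plain mean, alpha = 1 subtracts twice the mean.  A significant pair with
a positive corrected score is sequence-set specific; otherwise common.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import core
from .config import RunConfig
from .core import PairCollection, DegenerateScoresError
from .motifs import MotifMatrix
from .scan import scan_sequences
from .shuffle import ShuffleSpec, make_background_sets

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BackgroundEstimate:
    """Per-pair background score distribution over l shuffled sets."""

    motif_a: str
    motif_b: str
    values: np.ndarray  # length l; 0.0 where the pair was absent
    avg: float
    mc_stderr: float


@dataclasses.dataclass(frozen=True)
class Alpha:
    """Background scaling factor, bounded to [-1, +1]."""

    alpha: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [-1, 1]")


def _as_alpha(alpha: "Alpha | float") -> float:
    a = alpha.alpha if isinstance(alpha, Alpha) else float(alpha)
    if not -1.0 <= a <= 1.0:
        raise ValueError("alpha must lie in [-1, 1]")
    return a


def score_sequence_set(
    seqs: Sequence[tuple[str, str]],
    motifs: Sequence[MotifMatrix],
    config: RunConfig,
    with_significance: bool = True,
) -> PairCollection:
    """Run scan + the six scoring phases on one sequence set.

    Returns the pair collection with raw, APC-corrected and (optionally)
    z-scored pair scores.  Degenerate sets (no sites, no pairs) yield an
    empty collection.
    """
    sites = scan_sequences(seqs, motifs, threshold=config.scan_threshold)
    if not sites:
        return PairCollection(records=[], seq_weights={}, total_pairs=0)
    seq_ids = [sid for sid, _ in seqs]
    M = core.build_matrix(sites, seq_ids)
    M = core.filter_columns(M, config.low_q, config.high_q)
    sites = core.subset_sites(sites, M.motif_ids)
    sites = core.importance_filter(M, sites)
    sites = core.resolve_overlaps(sites, tss_offset=config.tss_offset)
    pairs = core.build_pairs(
        sites, config.d_min, config.d_max, allow_homotypic=config.allow_homotypic
    )
    collection = core.score_pairs(pairs, probability_scope=config.probability_scope)
    if collection.records:
        collection = core.apc_correct(collection)
    if with_significance and collection.records:
        collection = core.significance(collection, z_threshold=config.z_threshold)
    return collection


def background_pmi(
    seqs: Sequence[tuple[str, str]],
    motifs: Sequence[MotifMatrix],
    spec: ShuffleSpec,
    config: RunConfig,
) -> dict[tuple[str, str], BackgroundEstimate]:
    """Estimate each pair's background score from shuffled sequence sets.

    For every one of ``spec.n_sets`` k-let-preserving shuffles of
    ``seqs`` the full pipeline (scan through APC, no significance cut)
    is re-run with the same configuration.  A pair absent from a
    background set contributes 0 for that set; the average divides by
    the full number of sets l.
    """
    l = spec.n_sets
    values: dict[tuple[str, str], np.ndarray] = {}
    for set_index, shuffled in enumerate(make_background_sets(seqs, spec)):
        try:
            coll = score_sequence_set(shuffled, motifs, config, with_significance=False)
        except (DegenerateScoresError, ValueError) as exc:
            logger.warning("background set %d degenerate (%s); counted as 0", set_index, exc)
            continue
        for r in coll.records:
            v = r.pmi_pc_apc if config.background_use_apc else r.pmi_pc
            arr = values.get(r.key)
            if arr is None:
                arr = np.zeros(l)
                values[r.key] = arr
            arr[set_index] = v
    out: dict[tuple[str, str], BackgroundEstimate] = {}
    for key, arr in values.items():
        stderr = float(arr.std(ddof=1) / math.sqrt(l)) if l > 1 else math.nan
        out[key] = BackgroundEstimate(
            motif_a=key[0],
            motif_b=key[1],
            values=arr,
            avg=float(arr.mean()),
            mc_stderr=stderr,
        )
    return out


def pmi_specific(pmi_pc_apc: float, avg: float, alpha: "Alpha | float") -> float:
    """Background-corrected pair score: score - (1 + alpha) * AVG."""
    return pmi_pc_apc - (1.0 + _as_alpha(alpha)) * avg


def classify(
    collection: PairCollection,
    backgrounds: Mapping[tuple[str, str], BackgroundEstimate],
    alpha: "Alpha | float",
) -> PairCollection:
    """Split significant pairs into sequence-set specific vs common.

    Every significant pair receives its background average and corrected
    score; the label becomes ``specific`` when the corrected score is
    strictly positive and ``common`` otherwise.  Non-significant pairs
    are untouched.  A significant pair without a background estimate is
    treated as background 0 (with a warning).  Modifies records in place
    and returns the collection.
    """
    a = _as_alpha(alpha)
    for r in collection.significant():
        est = backgrounds.get(r.key)
        if est is None:
            logger.warning("no background estimate for pair %s; assuming 0", r.key)
            avg = 0.0
        else:
            avg = est.avg
        r.avg_background = avg
        r.pmi_specific = pmi_specific(r.pmi_pc_apc, avg, a)
        r.label = core.LABEL_SPECIFIC if r.pmi_specific > 0 else core.LABEL_COMMON
    return collection


def alpha_sweep(
    collection: PairCollection,
    backgrounds: Mapping[tuple[str, str], BackgroundEstimate],
    alphas: Iterable[float],
    tracked_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Re-classify at several alphas; count specific pairs, rank a tracked pair.

    The rank is the tracked pair's 1-based position among specific pairs
    ordered by decreasing z (ties by pair key); NaN when the pair is not
    specific at that alpha.
    """
    if tracked_pair is not None:
        tracked_pair = core.pair_key(*tracked_pair)
    rows = []
    for a in alphas:
        classify(collection, backgrounds, a)
        specific = [r for r in collection.records if r.label == core.LABEL_SPECIFIC]
        specific.sort(key=lambda r: (-r.z, r.key))
        rank = math.nan
        if tracked_pair is not None:
            for pos, r in enumerate(specific, start=1):
                if r.key == tracked_pair:
                    rank = pos
                    break
        rows.append(
            {"alpha": a, "n_specific": len(specific), "rank_of_tracked_pair": rank}
        )
    return pd.DataFrame(rows, columns=["alpha", "n_specific", "rank_of_tracked_pair"])
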