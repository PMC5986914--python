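"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (dictionaries, double loops,
per-offset rescoring) and shares no code with the package internals, so
each pipeline phase can be checked against a second, independently
written route.
"""

from __future__ import annotations

import math
import statistics
from collections import Counter, defaultdict

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def kmer_counter(seq, k):
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


# ---------------------------------------------------------------- scanning


def naive_background(seq):
    counts = Counter(b for b in seq if b != "N")
    total = sum(counts.values())
    freqs = {}
    for b in "ACGT":
        f = counts[b] / total if total else 0.25
        freqs[b] = max(f, 0.01)
    norm = sum(freqs.values())
    return {b: f / norm for b, f in freqs.items()}


def naive_scan(seq, motif, threshold):
    """Per-offset rescoring oracle; returns {(start, strand, round(score, 6))}."""
    seq = seq.upper()
    w = motif.width
    bg = naive_background(seq)
    probs = {"+": motif.probs, "-": motif.probs[::-1, ::-1]}
    bounds = {}
    for strand, mat in probs.items():
        bounds[strand] = (
            sum(
                min(math.log2(mat[p][i] / bg[b]) for i, b in enumerate("ACGT"))
                for p in range(w)
            ),
            sum(
                max(math.log2(mat[p][i] / bg[b]) for i, b in enumerate("ACGT"))
                for p in range(w)
            ),
        )
    hits = set()
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        if "N" in window:
            continue
        for strand in "+-":
            score = sum(
                math.log2(probs[strand][p]["ACGT".index(b)] / bg[b])
                for p, b in enumerate(window)
            )
            smin, smax = bounds[strand]
            if smax > smin:
                norm = (score - smin) / (smax - smin)
                if norm >= threshold - 1e-9:
                    hits.add((start, strand, round(min(norm, 1.0), 6)))
    return hits


# ---------------------------------------------------------------- phases


def tally_matrix(sites, seq_ids, motif_ids):
    counts = {(s, m): 0 for s in seq_ids for m in motif_ids}
    for site in sites:
        counts[(site.sequence_id, site.motif_id)] += 1
    return counts


def quantile_survivors(motif_totals, low_q, high_q):
    """Explicit quantile rule: keep nonzero totals inside the closed interval."""
    nonzero = [t for t in motif_totals.values() if t > 0]
    lo = np.quantile(nonzero, low_q)
    hi = np.quantile(nonzero, high_q)
    return {m for m, t in motif_totals.items() if t > 0 and lo <= t <= hi}


def cell_pmi(counts, seq_ids, motif_ids):
    """Per-cell PMI(s_i; t_j) computed with explicit sums."""
    F = sum(counts.values())
    out = {}
    for s in seq_ids:
        row = sum(counts[(s, m)] for m in motif_ids)
        for m in motif_ids:
            col = sum(counts[(s2, m)] for s2 in seq_ids)
            f = counts[(s, m)]
            if f > 0:
                out[(s, m)] = math.log2((f / F) / ((row / F) * (col / F)))
    return out


def overlap_survivors(sites, tss_offset):
    """Cluster-then-argmin oracle: BFS over the overlap graph per (seq, motif)."""
    groups = defaultdict(list)
    for s in sites:
        groups[(s.sequence_id, s.motif_id)].append(s)
    kept = []
    for group in groups.values():
        n = len(group)
        adj = defaultdict(set)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = group[i], group[j]
                if a.start < b.end and b.start < a.end:
                    adj[i].add(j)
                    adj[j].add(i)
        seen = set()
        for i in range(n):
            if i in seen:
                continue
            comp, frontier = {i}, [i]
            while frontier:
                x = frontier.pop()
                for y in adj[x]:
                    if y not in comp:
                        comp.add(y)
                        frontier.append(y)
            seen |= comp
            best = min(
                (group[x] for x in comp),
                key=lambda s: (abs(s.center - tss_offset), s.start, s.strand),
            )
            kept.append(best)
    return set((s.sequence_id, s.motif_id, s.start, s.strand) for s in kept)


def all_pairs(sites, d_min, d_max, allow_homotypic=False):
    """All-pairs double-loop oracle; returns a multiset of canonical keys."""
    by_seq = defaultdict(list)
    for s in sites:
        by_seq[s.sequence_id].append(s)
    out = Counter()
    for sid, group in by_seq.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if a.motif_id == b.motif_id and not allow_homotypic:
                    continue
                d = abs(a.center - b.center)
                if d_min <= d <= d_max:
                    out[(sid, tuple(sorted((a.motif_id, b.motif_id))))] += 1
    return out


def weighted_pmi(pair_occurrences):
    """Straight-line reimplementation of the weighted cumulative PMI.

    ``pair_occurrences``: iterable of (sequence_id, motif_a, motif_b).
    Returns ({pair_key: score}, {sequence_id: weight}).
    """
    per_seq = defaultdict(list)
    for sid, a, b in pair_occurrences:
        per_seq[sid].append(tuple(sorted((a, b))))
    total = sum(len(v) for v in per_seq.values())
    weights = {sid: len(v) / total for sid, v in per_seq.items()}
    scores = defaultdict(float)
    for sid, occ in per_seq.items():
        N = len(occ)
        pair_counts = Counter(occ)
        end_counts = Counter()
        for a, b in occ:
            end_counts[a] += 1
            end_counts[b] += 1
        for (a, b), c in pair_counts.items():
            p_ab = c / N
            p_a = end_counts[a] / (2 * N)
            p_b = end_counts[b] / (2 * N)
            scores[(a, b)] += weights[sid] * p_ab * math.log2(p_ab / (p_a * p_b))
    return dict(scores), weights


def apc(scores):
    """Explicit-loop average product correction on a {pair: score} table."""
    motifs = sorted({m for pair in scores for m in pair})
    mean_of = {}
    for m in motifs:
        vals = [v for pair, v in scores.items() if m in pair]
        mean_of[m] = sum(vals) / len(vals)
    overall = sum(scores.values()) / len(scores)
    return {
        (a, b): v - mean_of[a] * mean_of[b] / overall for (a, b), v in scores.items()
    }


def zscores(values):
    mean = statistics.fmean(values)
    sd = statistics.stdev(values)
    return [(v - mean) / sd for v in values]
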