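"""k-let-preserving sequence shuffling (Euler-trail method).

A k-let-preserving shuffle permutes a sequence so that the multiset of
i-mer counts is exactly conserved for every i <= k.  This is done on the
de Bruijn multigraph whose vertices are the (k-1)-mers of the sequence
and whose edges are its k-mers: any Eulerian trail from the first to the
last (k-1)-mer spells a valid shuffle.  We draw a uniform random
arborescence toward the end vertex with Wilson's loop-erased random walk
(edge multiplicities as weights), fix each vertex's arborescence edge as
its last exit, randomly permute the remaining exits, and walk the trail.
This is the classic Altschul-Erikson construction generalized to k-lets,
and it samples uniformly among admissible trails.

With k = 3 (the default used for background sets) mono-, di- and
trinucleotide counts — hence GC content and the cores of binding sites —
are preserved while longer-range arrangement is randomized.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Iterator, Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class ShuffleSpec:
    """Background-set construction parameters.

    k : k-mer size preserved by the shuffle (default 3).
    n_sets : number of shuffled background sets l (default 1000).
    seed : root seed; (set index, sequence id) select a substream, so
        results are reproducible and independent of processing order.
    """

    k: int = 3
    n_sets: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


def shuffle_klet(seq: str, k: int, rng: np.random.Generator) -> str:
    """Return a random shuffle of ``seq`` preserving all i-mer counts, i <= k.

    The first (k-1)-mer is preserved (it anchors the Euler trail).  For
    ``len(seq) <= k`` the input is returned unchanged.  ``N`` (or any
    other letter) is treated as an ordinary fifth symbol, so k-mers
    containing it are preserved like any other.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) <= k:
        return seq
    if k == 1:
        chars = np.array(list(seq))
        return "".join(chars[rng.permutation(len(chars))])

    # vertices: (k-1)-mers; edges: k-mers (vertex -> next char)
    km1 = k - 1
    vertex_index: dict[str, int] = {}
    verts: list[str] = []

    def vid(v: str) -> int:
        i = vertex_index.get(v)
        if i is None:
            i = len(verts)
            vertex_index[v] = i
            verts.append(v)
        return i

    n_steps = len(seq) - km1  # edges in the trail
    out_char: list[list[str]] = []
    out_to: list[list[int]] = []
    prev = vid(seq[:km1])
    for i in range(km1, len(seq)):
        c = seq[i]
        nxt = vid(seq[i - km1 + 1 : i + 1])
        while len(out_char) < len(verts):
            out_char.append([])
            out_to.append([])
        out_char[prev].append(c)
        out_to[prev].append(nxt)
        prev = nxt
    while len(out_char) < len(verts):
        out_char.append([])
        out_to.append([])

    start = vertex_index[seq[:km1]]
    root = prev  # last (k-1)-mer
    n_vert = len(verts)

    # Wilson's algorithm: random arborescence toward `root`
    in_tree = [False] * n_vert
    nxt_edge = [-1] * n_vert  # chosen out-edge index per vertex
    in_tree[root] = True
    for v0 in range(n_vert):
        if in_tree[v0]:
            continue
        v = v0
        while not in_tree[v]:
            e = int(rng.integers(len(out_to[v])))
            nxt_edge[v] = e
            v = out_to[v][e]
        v = v0
        while not in_tree[v]:  # retrace, keeping only the loop-erased path
            in_tree[v] = True
            v = out_to[v][nxt_edge[v]]

    # permute each vertex's exits; the arborescence edge goes last
    order: list[np.ndarray] = []
    for v in range(n_vert):
        deg = len(out_to[v])
        perm = rng.permutation(deg) if deg else np.empty(0, dtype=int)
        if v != root and deg:
            keep = nxt_edge[v]
            pos = int(np.nonzero(perm == keep)[0][0])
            perm[pos], perm[-1] = perm[-1], perm[pos]
        order.append(perm)

    # walk the Euler trail
    ptr = [0] * n_vert
    chars = [seq[:km1]]
    v = start
    for _ in range(n_steps):
        e = int(order[v][ptr[v]])
        ptr[v] += 1
        chars.append(out_char[v][e])
        v = out_to[v][e]
    result = "".join(chars)
    if len(result) != len(seq):  # pragma: no cover - internal invariant
        raise RuntimeError("Euler walk did not consume all edges")
    return result


def _substream(seed: int, set_index: int, seq_id: str) -> np.random.Generator:
    tag = zlib.crc32(seq_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, set_index, tag]))


def make_background_sets(
    seqs: Sequence[tuple[str, str]], spec: ShuffleSpec
) -> Iterator[list[tuple[str, str]]]:
    """Yield ``spec.n_sets`` independently shuffled copies of ``seqs``.

    Each sequence in each set is shuffled with its own RNG substream
    keyed by (root seed, set index, sequence id), so output is byte
    reproducible and independent of iteration order.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    for set_index in range(spec.n_sets):
        yield [
            (sid, shuffle_klet(s, spec.k, _substream(spec.seed, set_index, sid)))
            for sid, s in seqs
        ]


def kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Multiset of k-mer counts (plain dictionary tally)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts
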