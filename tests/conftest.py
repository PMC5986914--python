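import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from tfcoop import BindingSite, MotifMatrix, motif_from_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_motif_factory(rng):
    """Random, strictly positive PWMs of a given width."""

    def make(width, motif_id="M", concentration=1.0):
        probs = rng.dirichlet(np.full(4, concentration), size=width)
        probs = np.maximum(probs, 1e-4)
        probs /= probs.sum(axis=1, keepdims=True)
        return MotifMatrix(motif_id=motif_id, name=motif_id, probs=probs)

    return make


@pytest.fixture
def sharp_motif():
    """A crisp width-5 motif whose consensus is TGACG."""
    counts = np.full((5, 4), 1.0)
    for i, b in enumerate("TGACG"):
        counts[i, "ACGT".index(b)] = 50.0
    return motif_from_counts("SHARP", counts)


def random_sites(rng, n, seq_ids, motif_ids, seq_len=200, width=8):
    """Helper shared by several modules' tests."""
    sites = []
    for _ in range(n):
        start = int(rng.integers(0, seq_len - width + 1))
        sites.append(
            BindingSite(
                sequence_id=str(rng.choice(seq_ids)),
                motif_id=str(rng.choice(motif_ids)),
                start=start,
                end=start + width,
                strand="+" if rng.integers(2) else "-",
                score=float(rng.uniform(0.85, 1.0)),
            )
        )
    return sites
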