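"""Run configuration: every tunable of the pipeline in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml


@dataclasses.dataclass
class RunConfig:
    """Tunables for a full run.

    scan_threshold : min-max normalized log-odds cut-off for site calls.
    d_min, d_max : inclusive center-distance window for pair formation (bp).
    z_threshold : significance cut-off on z-scored corrected pair scores.
    low_q, high_q : column-filter quantiles on motif total counts.
    allow_homotypic : score pairs of a motif with itself.
    tss_offset : 0-based index of the TSS within each sequence (500 for
        -500..+100 promoters).
    alpha : background scaling factor in [-1, 1]; the subtracted
        background is (1 + alpha) * AVG.
    k : k-mer size preserved by the background shuffle.
    n_background : number of shuffled background sets (l).
    seed : root RNG seed.
    background_use_apc : average APC-corrected scores over background
        sets (default) rather than uncorrected ones.
    probability_scope : 'per-sequence' or 'corpus' probabilities in the
        weighted cumulative PMI.
    """

    scan_threshold: float = 0.85
    d_min: float = 5.0
    d_max: float = 20.0
    z_threshold: float = 3.0
    low_q: float = 0.05
    high_q: float = 0.95
    allow_homotypic: bool = False
    tss_offset: int = 500
    alpha: float = 0.2
    k: int = 3
    n_background: int = 1000
    seed: int = 0
    background_use_apc: bool = True
    probability_scope: str = "per-sequence"

    def __post_init__(self) -> None:
        if not -1.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [-1, 1]")
        if not 0.0 <= self.scan_threshold <= 1.0:
            raise ValueError("scan_threshold must lie in [0, 1]")
        if self.d_min > self.d_max:
            raise ValueError("d_min must be <= d_max")
        if not 0.0 <= self.low_q < self.high_q <= 1.0:
            raise ValueError("need 0 <= low_q < high_q <= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.probability_scope not in ("per-sequence", "corpus"):
            raise ValueError("probability_scope must be 'per-sequence' or 'corpus'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
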