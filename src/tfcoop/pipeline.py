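"""End-to-end runs: scan -> score -> background -> classify -> export."""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .core import PairCollection
from .io import read_fasta
from .motifs import MotifMatrix, read_motifs
from .network import export_network
from .scan import write_bed
from .shuffle import ShuffleSpec
from .specificity import (
    BackgroundEstimate,
    alpha_sweep,
    background_pmi,
    classify,
    score_sequence_set,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    """Everything a finished run produced."""

    collection: PairCollection
    backgrounds: dict[tuple[str, str], BackgroundEstimate]
    sweep: pd.DataFrame
    out_dir: pathlib.Path
    config: RunConfig


def run(
    seqs: Sequence[tuple[str, str]],
    motifs: Sequence[MotifMatrix],
    config: RunConfig,
    alphas: Sequence[float] | None = None,
    tracked_pair: tuple[str, str] | None = None,
) -> tuple[PairCollection, dict, pd.DataFrame]:
    """In-memory pipeline: returns (classified collection, backgrounds, sweep)."""
    collection = score_sequence_set(seqs, motifs, config)
    spec = ShuffleSpec(k=config.k, n_sets=config.n_background, seed=config.seed)
    backgrounds = background_pmi(seqs, motifs, spec, config)
    sweep_alphas = list(alphas) if alphas else [config.alpha]
    sweep = alpha_sweep(collection, backgrounds, sweep_alphas, tracked_pair=tracked_pair)
    classify(collection, backgrounds, config.alpha)
    return collection, backgrounds, sweep


def run_pipeline(config_path) -> PipelineResult:
    """Execute a full run described by a YAML config file.

    Beyond :class:`RunConfig` keys the file must name ``fasta`` and
    ``motifs`` (with optional ``motif_format``, ``alphas``,
    ``tracked_pair`` and ``out_dir``).  Writes the pair table, the
    alpha-sweep table, a GraphML network, the site BED and a JSON run
    log; partial outputs are removed if any stage fails.
    """
    import yaml

    config_path = pathlib.Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("fasta", "motifs"):
        if key not in raw:
            raise ValueError(f"config is missing required key {key!r}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    config = RunConfig(**{k: v for k, v in raw.items() if k in known})
    alphas = raw.get("alphas") or [config.alpha]
    for a in alphas:
        if not -1.0 <= a <= 1.0:
            raise ValueError(f"alpha {a} outside [-1, 1]")
    tracked = tuple(raw["tracked_pair"]) if raw.get("tracked_pair") else None
    out_dir = pathlib.Path(raw.get("out_dir", "tfcoop_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    written: list[pathlib.Path] = []

    def _target(name: str) -> pathlib.Path:
        p = out_dir / name
        written.append(p)
        return p

    try:
        stage = "input"
        seqs = read_fasta(pathlib.Path(raw["fasta"]))
        motifs = read_motifs(pathlib.Path(raw["motifs"]), raw.get("motif_format", "jaspar"))

        stage = "scan+score"
        collection = score_sequence_set(seqs, motifs, config)

        stage = "background"
        spec = ShuffleSpec(k=config.k, n_sets=config.n_background, seed=config.seed)
        backgrounds = background_pmi(seqs, motifs, spec, config)

        stage = "classify"
        sweep = alpha_sweep(collection, backgrounds, list(alphas), tracked_pair=tracked)
        classify(collection, backgrounds, config.alpha)

        stage = "export"
        from .scan import scan_sequences

        write_bed(
            scan_sequences(seqs, motifs, threshold=config.scan_threshold),
            _target("sites.bed"),
        )
        collection.to_frame().to_csv(_target("pairs.tsv"), sep="\t", index=False)
        sweep.to_csv(_target("alpha_sweep.tsv"), sep="\t", index=False)
        export_network(
            collection,
            _target("network.graphml"),
            "graphml",
            provenance=f"config={config.digest()} seed={config.seed}",
        )
        log = {
            "version": __version__,
            "config_digest": config.digest(),
            "config": dataclasses.asdict(config),
            "alphas": list(alphas),
            "n_sequences": len(seqs),
            "n_motifs": len(motifs),
            "n_pairs_scored": len(collection.records),
            "n_significant": len(collection.significant()),
        }
        with open(_target("run.json"), "w") as fh:
            json.dump(log, fh, indent=2)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    return PipelineResult(
        collection=collection,
        backgrounds=backgrounds,
        sweep=sweep,
        out_dir=out_dir,
        config=config,
    )
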