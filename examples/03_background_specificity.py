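"""Separate sequence-set-specific pairs from ubiquitous ones.

Shuffles every promoter 20 times preserving all trinucleotide counts
(so the cores of binding sites survive but their arrangement does not),
re-scores every shuffled set, and subtracts each pair's mean background
score scaled by (1 + alpha).  A significant pair whose corrected score
stays positive depends on this particular arrangement of sites — it is
sequence-set specific; otherwise it is a common (generally occurring)
co-occurrence.
"""

from tfcoop import (
    PlantSpec,
    RunConfig,
    ShuffleSpec,
    background_pmi,
    classify,
    default_motif_library,
    generate_dataset,
    score_sequence_set,
)

spec = PlantSpec(n_sequences=80, length=500, seed=3, decoys=12)
seqs, _ = generate_dataset(spec)
motifs = default_motif_library(spec)
config = RunConfig(seed=3, n_background=20, alpha=0.2)

collection = score_sequence_set(seqs, motifs, config)
backgrounds = background_pmi(
    seqs, motifs, ShuffleSpec(k=3, n_sets=20, seed=3), config
)
classify(collection, backgrounds, config.alpha)

print("significant pairs at alpha = 0.2:\n")
print("pair                     pmi_pc_apc   AVG(bg)   pmi_specific  label")
for r in sorted(collection.significant(), key=lambda r: -r.z):
    print(
        f"{r.motif_a}/{r.motif_b:<15} {r.pmi_pc_apc: .4f}    {r.avg_background: .4f}"
        f"   {r.pmi_specific: .4f}      {r.label}"
    )
print(
    "\nAVG(bg) is the pair's mean APC-corrected score over the 20 shuffled"
    "\nsets; the planted pair's background is near zero because shuffling"
    "\ndestroys its co-occurrence, so it stays specific."
)
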