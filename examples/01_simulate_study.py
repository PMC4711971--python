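"""Generate a synthetic multi-mutant H3K27me3 study with known truth.

The generator emits a small genome, per-sample ChIP-seq tag tracks
(wild type plus four Polycomb-mutant-like samples), RNA-seq counts
coupled to the chromatin truth, and the truth tables every downstream
stage can be scored against.
"""

from k27compare import SimulationConfig, generate_genome, simulate_tracks
from k27compare.synthetic_data import simulate_expression

config = SimulationConfig(seed=1)
genome = generate_genome(config)
tracks, truth = simulate_tracks(genome, config)
counts = simulate_expression(genome, truth, config)

print(f"genome: {sum(genome.chrom_sizes.values()):,} bp, "
      f"{len(genome.genes)} genes, {len(truth.peaks)} peaks")
print("peak classes (truth):")
print(truth.peaks["class_name"].value_counts().to_string())
print("tags per track:")
for name in sorted(tracks):
    print(f"  {name}: {tracks[name].total:,}")
print(f"expression table: {counts.shape[0]} genes x {counts.shape[1]} samples")
# Each "set_I" peak loses H3K27me3 in its flanks in clf/lhp1; its target
# gene is up-regulated 4-fold there — that coupling is what the
# downstream integration steps are meant to recover.
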