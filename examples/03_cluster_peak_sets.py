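"""Cluster differential regions across mutants into peak sets.

Regions differential in at least one mutant-vs-wild-type comparison are
assembled into an M-profile matrix (regions x mutants) and partitioned
by k-means; the clusters recover the planted effect classes (reduced in
clf/lhp1, reduced in bmi1/ring1, increased).
"""

import numpy as np
import pandas as pd

from k27compare import SimulationConfig, call_peaks, compare_samples
from k27compare.differential import assemble_m_matrix, kmeans_cluster
from k27compare.peak_calling import TagTrack
from k27compare.synthetic_data import generate_genome, simulate_tracks

config = SimulationConfig(seed=3)
genome = generate_genome(config)
tracks, truth = simulate_tracks(genome, config)


def pool(sample):
    merged = {}
    for rep in (1, 2):
        for c, p in tracks[f"{sample}_rep{rep}"].positions.items():
            merged[c] = np.concatenate([merged.get(c, p[:0]), p])
    return TagTrack(merged)


pooled = {s: pool(s) for s in ("wt",) + config.samples}
peaks = {s: call_peaks(pooled[s], None, genome.chrom_sizes) for s in pooled}
comparisons = {
    m: compare_samples(peaks[m], peaks["wt"], pooled[m], pooled["wt"])
    for m in config.samples
}
pair_tracks = {m: (pooled[m], pooled["wt"]) for m in config.samples}

matrix = assemble_m_matrix(comparisons, pair_tracks)
labels, centroids = kmeans_cluster(matrix, k=3, seed=7)

print(f"differential regions (>=1 comparison): {len(matrix)}")
print("cluster centroids (mean normalized M per mutant):")
print(pd.DataFrame(centroids, columns=list(config.samples)).round(2).to_string())
print("cluster sizes:", np.bincount(labels).tolist())
# Cluster 0 (lowest mean M) collects the reduced regions; rows within a
# cluster share the same across-mutant M signature, i.e. the same
# Polycomb dependency.
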