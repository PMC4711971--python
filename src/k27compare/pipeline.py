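"""End-to-end orchestration: simulate -> call peaks -> normalize ->
classify & cluster -> annotate -> spreading -> motifs -> expression ->
QC -> summary report.

Every stage derives its seed from the single master seed by a fixed
offset, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    assemble_m_matrix,
    classify_regions,
    kmeans_cluster,
    m_value_bins,
)
from .expression_analysis import (
    cluster_expression_groups,
    de_test,
    gsea,
    sample_correlation_clustering,
)
from .gene_annotation import (
    assign_targets,
    group_target_enrichment,
    spreading_classifier,
)
from .genomic_io import write_bedgraph
from .intervals import GenomicInterval
from .motif_analysis import PWM, motif_enrichment
from .normalization import compare_samples, track_scale_factor
from .peak_calling import TagTrack, call_peaks
from .replicate_qc import foldchange_concordance, robust_index
from .synthetic_data import (
    SimulationConfig,
    generate_genome,
    implant_motifs,
    simulate_expression,
    simulate_tracks,
    write_bundle,
)

# seed offsets per stage, derived from the master seed
STAGE_SEEDS = {
    "simulate": 11,
    "cluster": 23,
    "motif": 37,
    "expression_cluster": 41,
    "gsea": 53,
}


def carg_box_pwm() -> PWM:
    """A synthetic CArG-box-like motif (consensus CCAAATAAGG) used by
    the bundled demo; built in code, not taken from any database."""
    consensus = "CCAAATAAGG"
    w = len(consensus)
    counts = np.full((4, w), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 100.0
    return PWM.from_counts("CArG_demo", counts, pseudocount=1.0)


@dataclass
class PipelineConfig:
    outdir: str = "k27_run"
    seed: int = 7
    simulation: SimulationConfig | None = None
    peak_window: int = 300
    peak_step: int = 100
    peak_pvalue: float = 1e-5
    peak_min_gap: int = 200
    m_cut: float = 1.0
    p_cut: float = 1e-3
    n_m_bins: int = 8
    k_regions: int = 3
    k_expression: int = 3
    summit_halfwidth: int = 250
    motif_implant_rate: float = 0.5
    n_random_motif: int = 500
    n_perm_gsea: int = 200
    de_fc_cut: float = 1.0
    de_p_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed + STAGE_SEEDS["simulate"])


def _pool(tracks: dict[str, TagTrack], sample: str) -> TagTrack:
    """Pool a sample's replicates into one track."""
    merged: dict[str, np.ndarray] = {}
    for name, track in sorted(tracks.items()):
        if not name.startswith(sample + "_rep"):
            continue
        for chrom, pos in track.positions.items():
            merged[chrom] = (
                np.concatenate([merged[chrom], pos])
                if chrom in merged
                else pos.copy()
            )
    return TagTrack(merged)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data; returns the summary
    dict also written to ``<outdir>/summary.json``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    summary: dict = {"seed": config.seed, "version": __version__}

    # -- simulate ----------------------------------------------------------
    genome = generate_genome(sim)
    tracks, truth = simulate_tracks(genome, sim)
    # implant a demo motif into set_I peaks before emitting sequences
    pwm = carg_box_pwm()
    set1_ivs = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in truth.peaks.itertuples()
        if r.class_name == "set_I"
    ]
    genome.sequences, motif_flags = implant_motifs(
        genome.sequences,
        set1_ivs,
        pwm,
        config.motif_implant_rate,
        seed=config.seed + STAGE_SEEDS["motif"],
    )
    counts = simulate_expression(genome, truth, sim)
    write_bundle(out / "data", genome, tracks, truth, counts)
    summary["n_genes"] = len(genome.genes)
    summary["n_true_peaks"] = len(truth.peaks)

    # -- peak calling ------------------------------------------------------
    samples = ("wt",) + tuple(sim.samples)
    pooled = {s: _pool(tracks, s) for s in samples}
    peaks = {
        s: call_peaks(
            pooled[s],
            None,
            genome.chrom_sizes,
            window=config.peak_window,
            step=config.peak_step,
            p_cutoff=config.peak_pvalue,
            min_gap=config.peak_min_gap,
        )
        for s in samples
    }
    summary["peak_counts"] = {s: len(p) for s, p in peaks.items()}

    # -- normalization / comparisons --------------------------------------
    comparisons: dict[str, pd.DataFrame] = {}
    pair_tracks = {}
    for mut in sim.samples:
        comp = compare_samples(peaks[mut], peaks["wt"], pooled[mut], pooled["wt"])
        comp.to_csv(out / f"comparison_{mut}.tsv", sep="\t", index=False)
        comparisons[mut] = comp
        pair_tracks[mut] = (pooled[mut], pooled["wt"])
        common = comp[comp["class"] == "common"]
        s = track_scale_factor(
            pooled["wt"],
            pooled[mut],
            [GenomicInterval(r.chrom, r.start, r.end)
             for r in common.itertuples()],
        )
        write_bedgraph(
            pooled[mut], out / f"track_{mut}.bedgraph",
            scale=s, chrom_sizes=genome.chrom_sizes,
        )
    write_bedgraph(
        pooled["wt"], out / "track_wt.bedgraph",
        chrom_sizes=genome.chrom_sizes,
    )

    # -- classification + clustering --------------------------------------
    region_counts = {}
    for mut, comp in comparisons.items():
        cls = classify_regions(comp, config.m_cut, config.p_cut)
        region_counts[mut] = {
            "down": int((cls == "down").sum()),
            "up": int((cls == "up").sum()),
        }
    summary["region_class_counts"] = region_counts

    matrix = assemble_m_matrix(
        comparisons, pair_tracks, config.m_cut, config.p_cut
    )
    summary["n_differential_regions"] = int(len(matrix))
    if len(matrix) >= config.k_regions:
        labels, centroids = kmeans_cluster(
            matrix, k=config.k_regions,
            seed=config.seed + STAGE_SEEDS["cluster"],
        )
        matrix_out = matrix.copy()
        matrix_out["cluster"] = labels
        matrix_out.to_csv(out / "m_matrix_clusters.tsv", sep="\t")
        summary["peak_set_sizes"] = {
            f"set_{i}": int((labels == i).sum())
            for i in range(config.k_regions)
        }

    # -- targeting + M bins + spreading ------------------------------------
    targets = assign_targets(peaks["wt"], genome.genes)
    target_df = pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in peaks["wt"]],
            "start": [p.interval.start for p in peaks["wt"]],
            "end": [p.interval.end for p in peaks["wt"]],
            "gene_id": [t.gene_id for t in targets],
            "relation": [t.relation for t in targets],
        }
    )
    target_df.to_csv(out / "targets_wt.tsv", sep="\t", index=False)
    summary["n_assigned_targets"] = int(
        sum(t.gene_id is not None for t in targets)
    )

    spreading = {}
    for mut, comp in comparisons.items():
        cls = classify_regions(comp, config.m_cut, config.p_cut)
        down = comp[cls == "down"]
        common_ivs = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in comp[comp["class"] == "common"].itertuples()
        ]
        scale = track_scale_factor(pooled["wt"], pooled[mut], common_ivs)
        n_flank = n_eval = 0
        for r in down.itertuples():
            region = GenomicInterval(r.chrom, r.start, r.end)
            if len(region) <= 2 * config.summit_halfwidth:
                continue
            call = spreading_classifier(
                region, r.summit, pooled["wt"], pooled[mut],
                config.summit_halfwidth, scale,
            )
            n_eval += 1
            n_flank += call.flank_biased
        spreading[mut] = {
            "evaluated": n_eval,
            "flank_biased": n_flank,
            "fraction": n_flank / n_eval if n_eval else float("nan"),
        }
    summary["spreading"] = spreading

    # -- motif enrichment ---------------------------------------------------
    if set1_ivs:
        enr = motif_enrichment(
            set1_ivs,
            [pwm],
            genome.sequences,
            genome.chrom_sizes,
            n_random=config.n_random_motif,
            seed=config.seed + STAGE_SEEDS["motif"],
        )
        summary["motif_enrichment"] = enr[0]

    # -- expression ---------------------------------------------------------
    log2fc = {}
    de_sets = {}
    wt_cols = [c for c in counts.columns if c.startswith("wt_")]
    for mut in sim.samples:
        mut_cols = [c for c in counts.columns if c.startswith(mut + "_")]
        res = de_test(
            counts[mut_cols], counts[wt_cols],
            fc_cut=config.de_fc_cut, p_cut=config.de_p_cut,
        )
        res.table.to_csv(out / f"de_{mut}.tsv", sep="\t")
        log2fc[mut] = res.table["log2fc"]
        de_sets[mut] = set(res.table.index[res.table["de"]])
    fc_matrix = pd.DataFrame(log2fc)
    summary["de_counts"] = {m: len(s) for m, s in de_sets.items()}

    de_any = fc_matrix.index[
        fc_matrix.index.isin(set().union(*de_sets.values()))
    ]
    if len(de_any) >= config.k_expression:
        groups, _ = cluster_expression_groups(
            fc_matrix.loc[de_any], k=config.k_expression,
            seed=config.seed + STAGE_SEEDS["expression_cluster"],
        )
        summary["expression_group_sizes"] = (
            groups.value_counts().sort_index().to_dict()
        )
    link, corr = sample_correlation_clustering(fc_matrix)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")

    # -- M-bin target enrichment (per mutant, first mutant reported) -------
    first = sim.samples[0]
    comp = comparisons[first]
    bins = m_value_bins(comp, config.n_m_bins)
    targets_by_peak = {
        i: t.gene_id for i, t in enumerate(targets) if t.gene_id
    }
    # map comparison rows to wt-peak targets via overlap with wt peaks
    wt_ivs = [p.interval for p in peaks["wt"]]
    bin_groups = {}
    for b, idx in enumerate(bins):
        genes_in_bin = set()
        for ri in idx:
            row = comp.loc[ri]
            riv = GenomicInterval(row.chrom, int(row.start), int(row.end))
            for j, wiv in enumerate(wt_ivs):
                if riv.overlaps(wiv) and j in targets_by_peak:
                    genes_in_bin.add(targets_by_peak[j])
        if genes_in_bin:
            bin_groups[f"bin{b}"] = genes_in_bin
    universe = {g.gene_id for g in genome.genes}
    if bin_groups:
        enrich = group_target_enrichment(bin_groups, de_sets[first], universe)
        summary["m_bin_enrichment"] = {
            k: {"score": v["score"], "pvalue": v["pvalue"], "stars": v["stars"]}
            for k, v in enrich.items()
        }

    # -- GSEA: are set_I targets enriched among genes up in the first mutant
    set1_targets = set(
        truth.peaks.loc[truth.peaks["class_name"] == "set_I", "target_gene"]
    )
    ranked = fc_matrix[first].sort_values(ascending=False, kind="mergesort")
    if set1_targets & set(ranked.index):
        g = gsea(
            ranked, set1_targets, n_perm=config.n_perm_gsea,
            seed=config.seed + STAGE_SEEDS["gsea"],
        )
        summary["gsea_set_I"] = {
            "es": g.es, "nes": g.nes, "pvalue": g.pvalue,
            "leading_edge_size": len(g.leading_edge),
        }

    # -- replicate QC -------------------------------------------------------
    first_cols = [c for c in counts.columns if c.startswith(first + "_")]
    fc1 = np.log2(
        (counts[first_cols[0]] + 0.5) / (counts[wt_cols[0]] + 0.5)
    )
    fc2 = np.log2(
        (counts[first_cols[1]] + 0.5) / (counts[wt_cols[1]] + 0.5)
    )
    ri = robust_index(np.exp2(fc1.to_numpy()), np.exp2(fc2.to_numpy()))
    summary["qc"] = {
        "foldchange_pearson_r": foldchange_concordance(fc1, fc2),
        "median_robust_index": float(np.median(ri[np.isfinite(ri)])),
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    with open(out / "run_manifest.json", "w") as fh:
        cfg = asdict(config)
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
    return summary
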