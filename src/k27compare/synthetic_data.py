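"""Synthetic genomes, ChIP-seq tag tracks and RNA-seq counts with known
ground truth.

The generator emulates the structure of a multi-mutant H3K27me3
comparison: a Poisson tag background, enriched peak regions with a
triangular summit profile, mutant-specific effects (uniform reduction,
flank-only reduction that preserves the summit, or increase), replicate
redraws, negative-binomial expression counts coupled to the chromatin
truth (a gene losing H3K27me3 is de-repressed), and motif instances
implanted into peak sequences at a controlled rate.

Everything is deterministic under the configured seed; independent
streams are derived per product so outputs do not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    write_bed,
    write_counts_tsv,
    write_fasta,
    write_gff3_genes,
)
from .intervals import GeneModel, GenomicInterval
from .peak_calling import TagTrack

RES = 25  # bp; rate-profile discretization

EFFECT_KINDS = ("none", "uniform_reduction", "flank_reduction", "increase")


@dataclass(frozen=True)
class EffectSpec:
    """A mutant-specific modification of the wild-type tag rate over a peak."""

    kind: str = "none"
    fold: float = 1.0
    summit_halfwidth: int = 250

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.fold <= 0:
            raise ValueError("effect fold must be positive")
        if self.kind in ("uniform_reduction", "flank_reduction"):
            if self.fold <= 1:
                raise ValueError("reduction folds must be > 1")
        if self.summit_halfwidth <= 0:
            raise ValueError("summit halfwidth must be positive")


@dataclass(frozen=True)
class PeakClassSpec:
    """A named fraction of peaks sharing the same per-mutant effects."""

    name: str
    fraction: float
    effects: dict[str, EffectSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.fraction <= 1):
            raise ValueError("fraction must lie in [0, 1]")


def default_peak_classes() -> list[PeakClassSpec]:
    """Three effect classes mirroring the biology under study: a
    flank-reduced set shared by the PRC2/LHP1-like mutants, a uniformly
    reduced set shared by the PRC1-like mutants, and an increased set;
    the remainder is stable."""
    return [
        PeakClassSpec(
            "set_I",
            0.15,
            {
                "clf": EffectSpec("flank_reduction", 6.0, 100),
                "lhp1": EffectSpec("flank_reduction", 6.0, 100),
            },
        ),
        PeakClassSpec(
            "set_II",
            0.12,
            {
                "bmi1": EffectSpec("uniform_reduction", 4.0),
                "ring1": EffectSpec("uniform_reduction", 4.0),
            },
        ),
        PeakClassSpec(
            "set_III",
            0.08,
            {
                "clf": EffectSpec("increase", 2.5),
                "lhp1": EffectSpec("increase", 2.5),
            },
        ),
    ]


@dataclass
class SimulationConfig:
    """All tunables of the synthetic study.

    Default sizes are desk scale: two chromosomes totalling 1 Mb, 250
    genes, 120 peaks of 1.5 kb at 10x mean enrichment (per-peak folds
    drawn uniformly within +/-50%) over a 0.02 tags/bp background,
    two replicates, NB expression with dispersion 0.05 and a 4-fold
    de-repression of genes that lose the mark.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    n_genes: int = 250
    gene_length: int = 2_000
    n_peaks: int = 120
    peak_width: int = 1_500
    background_rate: float = 0.02  # tags per bp
    enrichment_fold: float = 10.0
    # per-peak enrichment is drawn uniformly in fold*(1 +/- spread) so
    # peaks span a realistic intensity (A-value) range; without this the
    # M-on-A normalization fit would be degenerate
    enrichment_spread: float = 0.5
    samples: tuple[str, ...] = ("clf", "lhp1", "bmi1", "ring1")
    peak_classes: list[PeakClassSpec] = field(
        default_factory=default_peak_classes
    )
    n_replicates: int = 2
    library_sizes: dict[str, int] | int | None = None  # None -> Poisson totals
    expression_mean: float = 100.0
    expression_dispersion: float = 0.05
    expression_fold: float = 4.0
    # per-column RNA-seq depth factors, keyed "<sample>_rep<i>"; absent
    # columns get 1.0
    expression_library_factors: dict[str, float] = field(default_factory=dict)
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for name, value in (
            ("gene_length", self.gene_length),
            ("peak_width", self.peak_width),
            ("background_rate", self.background_rate),
            ("enrichment_fold", self.enrichment_fold),
            ("n_replicates", self.n_replicates),
            ("expression_mean", self.expression_mean),
            ("expression_dispersion", self.expression_dispersion),
            ("expression_fold", self.expression_fold),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_genes < 0 or self.n_peaks < 0:
            raise ValueError("counts must be non-negative")
        if not np.isclose(sum(self.base_freqs), 1.0):
            raise ValueError("base frequencies must sum to 1")
        if sum(c.fraction for c in self.peak_classes) > 1 + 1e-9:
            raise ValueError("peak class fractions exceed 1")
        for cls in self.peak_classes:
            for sample in cls.effects:
                if sample not in self.samples:
                    raise ValueError(
                        f"effect for unknown sample {sample!r}"
                    )

    def rng(self, stream: str) -> np.random.Generator:
        # one independent, order-insensitive stream per product
        return np.random.default_rng([self.seed, *stream.encode()])


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    sequences: dict[str, str]
    genes: list[GeneModel]


@dataclass
class TruthTable:
    """Ground truth emitted alongside the simulated data.

    ``peaks``: one row per peak (chrom, start, end, summit, class_name,
    target_gene, enrichment, effect_<sample>, fold_<sample>).
    ``genes``: one row per gene (de_<sample> in {up, down, none}).
    Motif-implant flags are returned by :func:`implant_motifs`.
    """

    peaks: pd.DataFrame
    genes: pd.DataFrame


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> Genome:
    """Random sequences plus uniformly placed non-overlapping genes."""
    rng = config.rng("genome")
    sequences = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        bases = rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8),
            size=length,
            p=np.asarray(config.base_freqs),
        )
        sequences[chrom] = bases.tobytes().decode()

    # allocate genes to chromosomes proportional to length (largest
    # remainder), then place each chromosome's genes uniformly without
    # overlap via the spacings construction
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    exact = config.n_genes * lengths / lengths.sum()
    alloc = np.floor(exact).astype(int)
    rem = config.n_genes - alloc.sum()
    for i in np.argsort(-(exact - alloc), kind="stable")[:rem]:
        alloc[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_c in zip(chroms, alloc):
        length = config.chrom_lengths[chrom]
        free = length - n_c * config.gene_length
        if free < 0:
            raise ValueError(
                f"{n_c} genes of {config.gene_length} bp do not fit on "
                f"{chrom} ({length} bp)"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=n_c)) if n_c else []
        for i in range(n_c):
            start = int(gaps[i]) + i * config.gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    f"g{gid:04d}",
                    GenomicInterval(
                        chrom, start, start + config.gene_length, strand
                    ),
                )
            )
            gid += 1
    return Genome(dict(config.chrom_lengths), sequences, genes)


# ---------------------------------------------------------------------------
# tag tracks
# ---------------------------------------------------------------------------

def _assign_classes(
    config: SimulationConfig, n_peaks: int, rng: np.random.Generator
) -> list[str]:
    counts = [int(round(c.fraction * n_peaks)) for c in config.peak_classes]
    labels = []
    for cls, cnt in zip(config.peak_classes, counts):
        labels.extend([cls.name] * cnt)
    labels.extend(["stable"] * (n_peaks - len(labels)))
    labels = labels[:n_peaks]
    rng.shuffle(labels)
    return labels


def _rate_profiles(
    config: SimulationConfig,
    genome: Genome,
    peaks: pd.DataFrame,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-sample, per-chromosome expected tag counts per RES-bp bin."""
    class_by_name = {c.name: c for c in config.peak_classes}
    all_samples = ("wt",) + tuple(config.samples)
    profiles: dict[str, dict[str, np.ndarray]] = {}
    base: dict[str, np.ndarray] = {}
    for chrom, size in genome.chrom_sizes.items():
        n_bins = -(-size // RES)
        w = np.full(n_bins, config.background_rate * RES, dtype=float)
        # last bin may be short
        w[-1] = config.background_rate * (size - (n_bins - 1) * RES)
        base[chrom] = w

    for sample in all_samples:
        prof = {c: b.copy() for c, b in base.items()}
        for row in peaks.itertuples():
            w = prof[row.chrom]
            lo_bin = row.start // RES
            hi_bin = -(-row.end // RES)
            centers = (np.arange(lo_bin, hi_bin) + 0.5) * RES
            half = (row.end - row.start) / 2
            tri = 1.0 + (row.enrichment - 1.0) * np.clip(
                1.0 - np.abs(centers - row.summit) / half, 0.0, 1.0
            )
            rate = base[row.chrom][lo_bin:hi_bin] * tri
            if sample != "wt":
                effect = class_by_name.get(row.class_name)
                spec = (
                    effect.effects.get(sample, EffectSpec())
                    if effect is not None
                    else EffectSpec()
                )
                if spec.kind == "uniform_reduction":
                    rate = rate / spec.fold
                elif spec.kind == "increase":
                    rate = rate * spec.fold
                elif spec.kind == "flank_reduction":
                    in_summit = (
                        np.abs(centers - row.summit) < spec.summit_halfwidth
                    )
                    rate = np.where(in_summit, rate, rate / spec.fold)
            w[lo_bin:hi_bin] = rate
        profiles[sample] = prof
    return profiles


def _draw_track(
    profile: dict[str, np.ndarray],
    library_size: int | None,
    rng: np.random.Generator,
) -> TagTrack:
    chroms = sorted(profile)
    weights = np.concatenate([profile[c] for c in chroms])
    if library_size is None:
        counts = rng.poisson(weights)
    else:
        counts = rng.multinomial(library_size, weights / weights.sum())
    positions: dict[str, np.ndarray] = {}
    offset = 0
    for chrom in chroms:
        n_bins = len(profile[chrom])
        c = counts[offset : offset + n_bins]
        offset += n_bins
        nz = np.nonzero(c)[0]
        pos = np.concatenate(
            [
                b * RES + rng.integers(0, RES, size=c[b])
                for b in nz
            ]
        ) if len(nz) else np.empty(0, dtype=np.int64)
        positions[chrom] = np.sort(pos).astype(np.int64)
    return TagTrack(positions)


def simulate_tracks(
    genome: Genome, config: SimulationConfig
) -> tuple[dict[str, TagTrack], TruthTable]:
    """Simulate per-sample, per-replicate tag tracks plus the truth table.

    Peaks are centred on randomly chosen genes (defining the true
    target), with a triangular enrichment profile peaking at the true
    summit. Returns tracks keyed ``"<sample>_rep<i>"`` (wild type is
    sample ``wt``).
    """
    rng = config.rng("tracks")
    if config.n_peaks > len(genome.genes):
        raise ValueError("more peaks requested than genes available")
    host_idx = rng.choice(
        len(genome.genes), size=config.n_peaks, replace=False
    )
    hosts = [genome.genes[i] for i in sorted(host_idx)]
    rows = []
    for g in hosts:
        iv = g.interval
        centre = (iv.start + iv.end) // 2
        start = max(0, centre - config.peak_width // 2)
        end = min(genome.chrom_sizes[iv.chrom], start + config.peak_width)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": start,
                "end": end,
                "summit": (start + end) // 2,
                "target_gene": g.gene_id,
            }
        )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "target_gene"]
    )
    # requested peaks must not overlap (hosts are distinct, but wide
    # peaks on short genes could touch)
    for i in range(1, len(peaks)):
        a, b = peaks.iloc[i - 1], peaks.iloc[i]
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"peak placement overlap at {a.chrom}:{a.end}"
            )
    peaks["peak_id"] = [f"p{i:04d}" for i in range(len(peaks))]
    peaks["class_name"] = _assign_classes(config, len(peaks), rng)
    lo = config.enrichment_fold * (1 - config.enrichment_spread)
    hi = config.enrichment_fold * (1 + config.enrichment_spread)
    peaks["enrichment"] = np.maximum(
        rng.uniform(lo, hi, size=len(peaks)), 1.0 + 1e-9
    )

    class_by_name = {c.name: c for c in config.peak_classes}
    for sample in config.samples:
        kinds, folds = [], []
        for cname in peaks["class_name"]:
            spec = (
                class_by_name[cname].effects.get(sample, EffectSpec())
                if cname in class_by_name
                else EffectSpec()
            )
            kinds.append(spec.kind)
            folds.append(spec.fold)
        peaks[f"effect_{sample}"] = kinds
        peaks[f"fold_{sample}"] = folds

    profiles = _rate_profiles(config, genome, peaks)
    tracks: dict[str, TagTrack] = {}
    for sample in ("wt",) + tuple(config.samples):
        if isinstance(config.library_sizes, dict):
            lib = config.library_sizes.get(sample)
        else:
            lib = config.library_sizes
        for rep in range(1, config.n_replicates + 1):
            rep_rng = config.rng(f"tags:{sample}:{rep}")
            tracks[f"{sample}_rep{rep}"] = _draw_track(
                profiles[sample], lib, rep_rng
            )

    # gene-level expression truth: losing the mark de-represses the
    # target; gaining it represses
    gene_rows = []
    peak_by_gene = {r.target_gene: r for r in peaks.itertuples()}
    for g in genome.genes:
        row = {"gene_id": g.gene_id}
        pk = peak_by_gene.get(g.gene_id)
        for sample in config.samples:
            if pk is None:
                row[f"de_{sample}"] = "none"
            else:
                kind = getattr(pk, f"effect_{sample}")
                row[f"de_{sample}"] = {
                    "uniform_reduction": "up",
                    "flank_reduction": "up",
                    "increase": "down",
                }.get(kind, "none")
        gene_rows.append(row)
    gene_cols = ["gene_id"] + [f"de_{s}" for s in config.samples]
    genes_df = pd.DataFrame(gene_rows, columns=gene_cols).set_index("gene_id")
    truth = TruthTable(
        peaks=peaks[
            ["peak_id", "chrom", "start", "end", "summit", "class_name",
             "target_gene", "enrichment"]
            + [f"effect_{s}" for s in config.samples]
            + [f"fold_{s}" for s in config.samples]
        ].copy(),
        genes=genes_df,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genome: Genome, truth: TruthTable, config: SimulationConfig
) -> pd.DataFrame:
    """Negative-binomial counts (genes x sample-replicates).

    Gene base means are log-normal around ``expression_mean``; genes
    flagged DE in the truth have their mean multiplied (up) or divided
    (down) by ``expression_fold`` in that mutant. Dispersion below 1e-8
    falls back to the Poisson limit.
    """
    if config.expression_dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = config.rng("expression")
    gene_ids = [g.gene_id for g in genome.genes]
    base = rng.lognormal(np.log(config.expression_mean), 0.5, len(gene_ids))
    disp = config.expression_dispersion
    data = {}
    for sample in ("wt",) + tuple(config.samples):
        mult = np.ones(len(gene_ids))
        if sample != "wt":
            de = truth.genes[f"de_{sample}"].reindex(gene_ids).fillna("none")
            mult = np.where(
                de == "up",
                config.expression_fold,
                np.where(de == "down", 1.0 / config.expression_fold, 1.0),
            )
        for rep in range(1, config.n_replicates + 1):
            rep_rng = config.rng(f"expr:{sample}:{rep}")
            factor = config.expression_library_factors.get(
                f"{sample}_rep{rep}", 1.0
            )
            mu = base * mult * factor
            if disp < 1e-8:
                counts = rep_rng.poisson(mu)
            else:
                r = 1.0 / disp
                counts = rep_rng.negative_binomial(r, r / (r + mu))
            data[f"{sample}_rep{rep}"] = counts
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# motif implantation
# ---------------------------------------------------------------------------

def implant_motifs(
    sequences: dict[str, str],
    peaks: list[GenomicInterval],
    pwm,
    rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], list[bool]]:
    """Write one sampled motif instance into a fraction ``rate`` of peaks.

    Each selected peak receives an instance sampled column-wise from
    the motif probabilities, on a uniformly chosen strand, at a uniform
    position inside the peak. Returns the modified sequences and the
    per-peak truth flags.
    """
    from .motif_analysis import BASES  # local to avoid import cycle

    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    w = pwm.width
    if peaks and w > max(len(iv) for iv in peaks):
        raise ValueError("motif wider than every peak")
    rng = np.random.default_rng(seed)
    mutable = {c: bytearray(s.encode()) for c, s in sequences.items()}
    flags: list[bool] = []
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    for iv in peaks:
        if w > len(iv) or rng.random() >= rate:
            flags.append(False)
            continue
        instance = "".join(
            BASES[rng.choice(4, p=pwm.matrix[:, j])] for j in range(w)
        ).encode()
        if rng.random() < 0.5:
            instance = instance.translate(comp)[::-1]
        pos = int(rng.integers(iv.start, iv.end - w + 1))
        mutable[iv.chrom][pos : pos + w] = instance
        flags.append(True)
    return {c: b.decode() for c, b in mutable.items()}, flags


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def write_bundle(
    outdir: str | Path,
    genome: Genome,
    tracks: dict[str, TagTrack],
    truth: TruthTable,
    counts: pd.DataFrame | None = None,
) -> None:
    """Emit the simulated study as FASTA/GFF3/BED/TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.sequences, outdir / "genome.fa")
    write_gff3_genes(genome.genes, outdir / "genes.gff3")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")
    for name, track in tracks.items():
        ivs = [
            GenomicInterval(chrom, int(p), int(p) + 1)
            for chrom in sorted(track.positions)
            for p in track.positions[chrom]
        ]
        write_bed(ivs, outdir / f"tags_{name}.bed")
    truth.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    if counts is not None:
        write_counts_tsv(counts, outdir / "expression_counts.tsv")
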