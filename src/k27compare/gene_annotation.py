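"""Peak-to-gene targeting, interval-overlap statistics and the
summit-vs-flank H3K27me3 spreading classifier.

The target of a peak is the gene whose eligibility window — 1 kb
upstream of the TSS through the TES, strand-aware — overlaps the peak,
choosing the gene whose TSS is closest to the peak summit. Overlap
significance against published binding-site lists uses a
length-preserving permutation null (1,000 genome-wide shuffles by
default) or Fisher's exact test over a region universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GeneModel, GenomicInterval
from .normalization import ma_values
from .peak_calling import Peak, TagTrack


@dataclass(frozen=True)
class TargetAssignment:
    peak_index: int
    gene_id: str | None
    distance: int | None  # |summit - TSS|, bp
    relation: str | None  # 'overlap' (peak touches gene body) or 'upstream-window'


@dataclass(frozen=True)
class SpreadingCall:
    region: GenomicInterval
    m_summit: float
    m_flank: float
    flank_biased: bool


# ---------------------------------------------------------------------------
# targeting
# ---------------------------------------------------------------------------

def assign_targets(
    peaks: list[Peak],
    genes: list[GeneModel],
    upstream: int = 1000,
    rule: str = "tss_window",
) -> list[TargetAssignment]:
    """Assign each peak to its target gene (or None).

    ``rule='tss_window'`` (default): eligibility window [TSS - upstream,
    TES]; candidates overlap the peak by >= 1 bp; the winner minimizes
    |summit - TSS|, ties broken by lexicographic gene id.
    ``rule='peak_window'``: variant where the gene body must lie within
    ``upstream`` bp of the peak region on either side.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if rule == "tss_window":
            win = g.target_window(upstream)
        elif rule == "peak_window":
            iv = g.interval
            win = GenomicInterval(
                iv.chrom, max(0, iv.start - upstream), iv.end + upstream,
                iv.strand,
            )
        else:
            raise ValueError(f"unknown targeting rule {rule!r}")
        trees.setdefault(win.chrom, IntervalTree()).addi(
            win.start, win.end, g
        )

    out: list[TargetAssignment] = []
    for i, pk in enumerate(peaks):
        tree = trees.get(pk.interval.chrom)
        hits = (
            sorted(tree.overlap(pk.interval.start, pk.interval.end),
                   key=lambda h: h.data.gene_id)
            if tree is not None
            else []
        )
        if not hits:
            out.append(TargetAssignment(i, None, None, None))
            continue
        best = min(
            (h.data for h in hits),
            key=lambda g: (abs(pk.summit - g.tss), g.gene_id),
        )
        relation = (
            "overlap"
            if best.interval.overlaps(pk.interval)
            else "upstream-window"
        )
        out.append(
            TargetAssignment(
                i, best.gene_id, abs(pk.summit - best.tss), relation
            )
        )
    return out


# ---------------------------------------------------------------------------
# overlap statistics
# ---------------------------------------------------------------------------

def _build_tree(regions: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def count_overlapping(
    query: list[GenomicInterval], reference: list[GenomicInterval]
) -> int:
    """Number of query regions having >= 1 bp overlap with any reference."""
    trees = _build_tree(reference)
    n = 0
    for iv in query:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            n += 1
    return n


def overlap_fraction(
    query: list[GenomicInterval], reference: list[GenomicInterval]
) -> float:
    if not query:
        raise ValueError("overlap fraction undefined for empty query")
    return count_overlapping(query, reference) / len(query)


def shuffle_regions(
    regions: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Place each region uniformly at random on the genome, preserving
    its length; chromosomes are chosen proportional to length and
    shuffled regions may overlap one another."""
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    for iv in regions:
        size = len(iv)
        feasible = [i for i, c in enumerate(chroms) if chrom_sizes[c] >= size]
        if not feasible:
            raise ValueError(f"region of length {size} exceeds every chromosome")
        p = probs[feasible] / probs[feasible].sum()
        ci = feasible[rng.choice(len(feasible), p=p)]
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - size + 1))
        out.append(GenomicInterval(chroms[ci], start, start + size))
    return out


def permutation_overlap_test(
    query: list[GenomicInterval],
    reference: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    n: int = 1000,
    seed: int = 0,
) -> tuple[float, int, np.ndarray]:
    """Permutation test of query/reference overlap.

    Each iteration re-places every reference region uniformly at random
    (length-preserving shuffle); the statistic is the number of query
    regions overlapped. Empirical P uses the +1 correction:
    P = (1 + #{null >= observed}) / (n + 1), so P >= 1/(n+1) always.

    Returns (P, observed, null distribution).
    """
    rng = np.random.default_rng(seed)
    observed = count_overlapping(query, reference)
    null = np.empty(n, dtype=np.int64)
    for i in range(n):
        shuffled = shuffle_regions(reference, chrom_sizes, rng)
        null[i] = count_overlapping(query, shuffled)
    p = (1 + int(np.sum(null >= observed))) / (n + 1)
    return p, observed, null


def fisher_region_enrichment(
    set_a: set, set_b: set, universe: set
) -> tuple[float, float]:
    """Fisher's exact test of co-membership of two region sets within a
    universe (regions identified by hashable ids).

    Returns (odds ratio, two-sided P); the odds ratio uses the Haldane
    +0.5 correction when any cell is zero.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    both = len(set_a & set_b)
    a_only = len(set_a) - both
    b_only = len(set_b) - both
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if np.any(table == 0):
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds), float(p)


STAR_THRESHOLDS = (5e-2, 1e-2, 1e-3)


def group_target_enrichment(
    groups: dict[str, set],
    de_genes: set,
    universe: set,
) -> dict[str, dict]:
    """Observed/expected enrichment of DE genes in each target-gene group.

    score = observed overlap / expected overlap, where expected =
    |group| * |de| / |universe|; significance by Fisher's exact test
    with stars at P < 5e-2 (*), 1e-2 (**), 1e-3 (***).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    results: dict[str, dict] = {}
    de_in = de_genes & universe
    for name, group in groups.items():
        grp = group & universe
        if not grp:
            warnings.warn(f"group {name!r} empty; skipped", stacklevel=2)
            continue
        observed = len(grp & de_in)
        expected = len(grp) * len(de_in) / len(universe)
        table = [
            [observed, len(grp) - observed],
            [len(de_in) - observed,
             len(universe) - len(grp) - len(de_in) + observed],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        stars = sum(p < t for t in STAR_THRESHOLDS)
        results[name] = {
            "observed": observed,
            "expected": expected,
            "score": observed / expected if expected > 0 else np.nan,
            "pvalue": float(p),
            "stars": "*" * stars,
        }
    return results


# ---------------------------------------------------------------------------
# spreading classifier
# ---------------------------------------------------------------------------

def spreading_classifier(
    region: GenomicInterval,
    summit: int,
    track_wt: TagTrack,
    track_mut: TagTrack,
    summit_halfwidth: int = 250,
    scale: float = 1.0,
    region_class: str = "down",
) -> SpreadingCall:
    """Classify a down-regulated region as flank-biased ("spreading
    defect") or uniformly reduced.

    M values (mutant vs wild type, pseudocount 0.5) are computed
    separately over the summit window [summit +/- halfwidth) and over
    the remaining flanks; the mutant counts are multiplied by ``scale``
    (the common-region track scale factor). The region is flank-biased
    when M_flank <= -1 and M_summit - M_flank >= 1, i.e. the loss is
    concentrated away from the summit.
    """
    if region_class != "down":
        raise ValueError(
            "spreading is evaluated only for regions classified down"
        )
    if len(region) <= 2 * summit_halfwidth:
        raise ValueError("region not wider than the summit window")
    s_lo = max(region.start, summit - summit_halfwidth)
    s_hi = min(region.end, summit + summit_halfwidth)
    summit_iv = GenomicInterval(region.chrom, s_lo, s_hi)

    mut_summit = track_mut.count(summit_iv) * scale
    wt_summit = track_wt.count(summit_iv)
    mut_total = track_mut.count(region) * scale
    wt_total = track_wt.count(region)
    mut_flank = max(mut_total - mut_summit, 0.0)
    wt_flank = max(wt_total - wt_summit, 0.0)

    m_summit, _ = ma_values(mut_summit, wt_summit)
    m_flank, _ = ma_values(mut_flank, wt_flank)
    flag = (m_flank <= -1.0) and (m_summit - m_flank >= 1.0)
    return SpreadingCall(region, float(m_summit), float(m_flank), bool(flag))
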