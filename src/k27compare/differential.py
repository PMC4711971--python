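"""Differential-region classification and multi-mutant clustering.

A region is called down (up) in a mutant when its normalized M is below
-1 (above +1) with Audic-Claverie P < 1e-3, strict inequalities at both
cutoffs. Regions differential in at least one mutant-vs-wild-type
comparison are assembled into an M-profile matrix (regions x
comparisons) and partitioned by k-means into peak sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import GenomicInterval
from .normalization import ma_values

M_CUT = 1.0
P_CUT = 1e-3


def classify_regions(
    comparison: pd.DataFrame, m_cut: float = M_CUT, p_cut: float = P_CUT
) -> pd.Series:
    """Three-way classification of a NormalizedComparison table.

    down  iff M_norm < -m_cut and pvalue < p_cut
    up    iff M_norm > +m_cut and pvalue < p_cut
    otherwise unchanged. Inequalities are strict.
    """
    m = comparison["M_norm"].to_numpy()
    p = comparison["pvalue"].to_numpy()
    cls = np.where(
        (m < -m_cut) & (p < p_cut),
        "down",
        np.where((m > m_cut) & (p < p_cut), "up", "unchanged"),
    )
    return pd.Series(cls, index=comparison.index, name="class")


def _merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge overlapping intervals (sorted output)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
        if merged and merged[-1].overlaps(iv):
            merged[-1] = merged[-1].union(iv)
        else:
            merged.append(iv)
    return merged


def assemble_m_matrix(
    comparisons: dict[str, pd.DataFrame],
    tracks: dict[str, tuple] | None = None,
    m_cut: float = M_CUT,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """Assemble the regions x comparisons matrix of normalized M values.

    Rows are the union (overlap-merged) of regions differential in at
    least one comparison; each row is projected onto every comparison by
    >= 1 bp overlap with that comparison's peaks (overlapping peak's
    normalized M). Where a comparison has no overlapping peak, the cell
    is filled with the raw M recomputed from tag counts over the region
    when ``tracks`` provides the (mutant, wild-type) TagTrack pair for
    that comparison, else 0.

    Index: "chrom:start-end" region ids; region coordinates in columns
    chrom/start/end of ``df.attrs['regions']``.
    """
    if len(comparisons) < 2 and tracks is not None:
        pass  # a single comparison is permitted for small analyses
    diff_ivs: list[GenomicInterval] = []
    for name, comp in comparisons.items():
        cls = classify_regions(comp, m_cut, p_cut)
        sub = comp[cls != "unchanged"]
        diff_ivs.extend(
            GenomicInterval(r.chrom, r.start, r.end)
            for r in sub.itertuples()
        )
    regions = _merge_intervals(diff_ivs)

    data = {}
    for name, comp in comparisons.items():
        col = np.full(len(regions), np.nan)
        comp_ivs = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in comp.itertuples()
        ]
        m_norm = comp["M_norm"].to_numpy()
        for i, region in enumerate(regions):
            best_ov, best_j = 0, -1
            for j, civ in enumerate(comp_ivs):
                ov = region.overlap_length(civ)
                if ov > best_ov:
                    best_ov, best_j = ov, j
            if best_j >= 0:
                col[i] = m_norm[best_j]
            elif tracks is not None and name in tracks:
                t_mut, t_wt = tracks[name]
                m_raw, _ = ma_values(t_mut.count(region), t_wt.count(region))
                col[i] = float(m_raw)
            else:
                col[i] = 0.0
        data[name] = col

    idx = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    df = pd.DataFrame(data, index=idx)
    df.attrs["regions"] = regions
    return df


def kmeans_cluster(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean k-means, best of ``n_init`` seeded k-means++ restarts.

    Clusters are relabelled in ascending order of centroid mean M, so
    label 0 is the most-reduced peak set; deterministic given the seed.
    Returns (labels, centroids).
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix has missing cells; fill before clustering")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw], km.cluster_centers_[order]


def m_value_bins(comparison: pd.DataFrame, n_bins: int = 8) -> list[pd.Index]:
    """Rank peaks by normalized M descending and cut into consecutive
    near-equal groups (remainder spread over the leading groups).

    Returns the list of row-index groups, highest-M group first.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(comparison)
    if n < n_bins:
        raise ValueError(f"{n} peaks cannot fill {n_bins} bins")
    order = comparison["M_norm"].sort_values(
        ascending=False, kind="mergesort"
    ).index
    base, rem = divmod(n, n_bins)
    groups: list[pd.Index] = []
    pos = 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        groups.append(order[pos : pos + size])
        pos += size
    return groups
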