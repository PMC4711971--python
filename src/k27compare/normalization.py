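"""MA-plot normalization of peak read counts between two ChIP-seq samples.

Implements the MAnorm idea: peaks common to the two samples (which, by
assumption, are mostly not differential) define a robust linear trend of
M on A; subtracting the fitted trend from every peak yields normalized
M values comparable across the genome. Per-peak significance comes from
the Audic-Claverie conditional count model applied to trend-rescaled
counts.

Sign convention: M = log2(mutant / wild-type), so a positive M means a
higher H3K27me3 level in the mutant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .intervals import GenomicInterval
from .peak_calling import Peak, TagTrack

PSEUDOCOUNT = 0.5
HUBER_T = 1.345
MIN_COMMON = 10


# ---------------------------------------------------------------------------
# common / unique partition
# ---------------------------------------------------------------------------

def partition_common_unique(
    peaks_a: list[Peak], peaks_b: list[Peak]
) -> tuple[list[tuple[Peak, Peak]], list[Peak], list[Peak]]:
    """Split two peak lists into matched common pairs and unique peaks.

    A peak is common iff it overlaps (>= 1 bp) a peak of the other list;
    overlapping candidates are matched 1:1 greedily by descending
    overlap length (ties broken by list order, for determinism).
    """
    candidates = []  # (overlap, i, j)
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            ov = pa.interval.overlap_length(pb.interval)
            if ov > 0:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((peaks_a[i], peaks_b[j]))
    unique_a = [p for i, p in enumerate(peaks_a) if i not in used_a]
    unique_b = [p for j, p in enumerate(peaks_b) if j not in used_b]
    return pairs, unique_a, unique_b


# ---------------------------------------------------------------------------
# M / A statistics
# ---------------------------------------------------------------------------

def ma_values(x, y) -> tuple[np.ndarray, np.ndarray]:
    """M and A values for counts x (mutant) and y (wild-type).

    M = log2((x + 0.5) / (y + 0.5));  A = 0.5 * log2((x + 0.5)(y + 0.5)).
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    lx = np.log2(x + PSEUDOCOUNT)
    ly = np.log2(y + PSEUDOCOUNT)
    return lx - ly, 0.5 * (lx + ly)


def fit_normalization(m: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Huber-robust linear fit M = a0 + b0 * A over common peaks.

    Returns the coefficients (a0, b0); the normalized value of any peak
    is then M - (a0 + b0 * A). Requires >= 10 common peaks.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if len(m) < MIN_COMMON:
        raise ValueError(
            f"need >= {MIN_COMMON} common peaks to normalize, got {len(m)}"
        )
    exog = sm.add_constant(a)
    fit = sm.RLM(m, exog, M=sm.robust.norms.HuberT(t=HUBER_T)).fit()
    return float(fit.params[0]), float(fit.params[1])


# ---------------------------------------------------------------------------
# Audic-Claverie differential P-value
# ---------------------------------------------------------------------------

def differential_pvalue(x, y, n1: float, n2: float):
    """Two-sided Audic-Claverie P-value for observing counts (x, y).

    The conditional model p(y | x) = (N2/N1)^y (x+y)! /
    (x! y! (1 + N2/N1)^(x+y+1)) is a negative binomial with r = x + 1
    successes and success probability N1 / (N1 + N2). The two-sided P
    doubles the smaller of the two lower tails P(Y <= y | x) and
    P(X <= x | y) (the latter from the role-swapped model), capped at
    1 — this form is exactly symmetric under swapping (x, N1) with
    (y, N2).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p0 = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p0)  # P(Y <= y | x)
    upper = stats.nbinom.cdf(x, y + 1, 1.0 - p0)  # P(X <= x | y)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    # guard against zero from extreme underflow: P is a tail sum > 0
    p = np.maximum(p, np.finfo(float).tiny)
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# full two-sample comparison
# ---------------------------------------------------------------------------

def compare_samples(
    peaks_mut: list[Peak],
    peaks_wt: list[Peak],
    track_mut: TagTrack,
    track_wt: TagTrack,
) -> pd.DataFrame:
    """Build a NormalizedComparison table for a mutant-vs-wild-type pair.

    Common peak pairs are collapsed to the union interval of the matched
    pair (one row each); unique peaks keep their own interval. Counts
    are taken over the full region in both tracks; the robust M-on-A
    trend is fitted on common rows only and subtracted everywhere.
    P-values are Audic-Claverie on (x, y') where y' is the wild-type
    count rescaled by the fitted trend (equal effective library sizes).

    Columns: chrom, start, end, summit, x, y, A, M_raw, M_norm, pvalue,
    class (common / unique_mut / unique_wt). The fit coefficients are
    stored in ``df.attrs['fit']``.
    """
    pairs, uniq_m, uniq_w = partition_common_unique(peaks_mut, peaks_wt)
    rows = []
    for pm, pw in pairs:
        iv = pm.interval.union(pw.interval)
        rows.append((iv, pm.summit, "common"))
    for p in uniq_m:
        rows.append((p.interval, p.summit, "unique_mut"))
    for p in uniq_w:
        rows.append((p.interval, p.summit, "unique_wt"))
    if not rows:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "summit", "x", "y",
                "A", "M_raw", "M_norm", "pvalue", "class",
            ]
        )

    x = np.array([track_mut.count(iv) for iv, _, _ in rows], dtype=float)
    y = np.array([track_wt.count(iv) for iv, _, _ in rows], dtype=float)
    m_raw, a_val = ma_values(x, y)
    cls = np.array([c for _, _, c in rows])

    common = cls == "common"
    a0, b0 = fit_normalization(m_raw[common], a_val[common])
    m_norm = m_raw - (a0 + b0 * a_val)

    # rescale wild-type counts onto the mutant scale, then test
    y_scaled = np.rint(
        (y + PSEUDOCOUNT) * np.exp2(-(a0 + b0 * a_val)) - PSEUDOCOUNT
    )
    y_scaled = np.maximum(y_scaled, 0)
    pvals = differential_pvalue(x.astype(int), y_scaled.astype(int), 1.0, 1.0)

    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv, _, _ in rows],
            "start": [iv.start for iv, _, _ in rows],
            "end": [iv.end for iv, _, _ in rows],
            "summit": [s for _, s, _ in rows],
            "x": x.astype(int),
            "y": y.astype(int),
            "A": a_val,
            "M_raw": m_raw,
            "M_norm": m_norm,
            "pvalue": pvals,
            "class": cls,
        }
    ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)
    df.attrs["fit"] = (a0, b0)
    return df


# ---------------------------------------------------------------------------
# browser-track scaling
# ---------------------------------------------------------------------------

def track_scale_factor(
    track_wt: TagTrack,
    track_mut: TagTrack,
    common_regions: list[GenomicInterval],
) -> float:
    """Scale factor s for the mutant track so that tag totals over the
    common peak regions match the wild type exactly."""
    if not common_regions:
        raise ValueError("common regions must be non-empty")
    wt = sum(track_wt.count(iv) for iv in common_regions)
    mut = sum(track_mut.count(iv) for iv in common_regions)
    if mut == 0:
        raise ValueError("mutant track has zero tags in common regions")
    return wt / mut


def input_lambda_match(
    track_input: TagTrack,
    track_ref: TagTrack,
    peak_free_regions: list[GenomicInterval],
    window: int = 1000,
) -> float:
    """Scale for an input track by Poisson rate matching in peak-free
    regions: lambda per window is the Poisson MLE (mean tags/window) for
    each track; returns lambda_ref / lambda_input."""
    windows: list[GenomicInterval] = []
    for region in peak_free_regions:
        for s in range(region.start, region.end - window + 1, window):
            windows.append(GenomicInterval(region.chrom, s, s + window))
    if len(windows) < 100:
        raise ValueError("peak-free regions must cover >= 100 windows")
    lam_in = np.mean([track_input.count(w) for w in windows])
    lam_ref = np.mean([track_ref.count(w) for w in windows])
    if lam_in == 0:
        raise ValueError("input track has zero rate in peak-free regions")
    return float(lam_ref / lam_in)
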