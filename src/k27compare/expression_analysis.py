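"""RNA-seq side of the pipeline: RPKM, differential expression,
expression-pattern clustering, tissue clustering and GSEA.

Differential expression uses a negative-binomial exact conditional test
(size factors by median-of-ratios; method-of-moments dispersion pooled
across conditions and moderated toward the common across-gene value) —
a transparent stand-in for heavier DE frameworks whose precise
shrinkage is out of scope here. The DE call combines |log2FC| > 1 with
P < 0.05. GSEA is the classic weighted Kolmogorov-Smirnov running
statistic with a gene-label permutation null and NES normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .differential import kmeans_cluster

LOG2FC_CUT = 1.0
DE_P_CUT = 0.05


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads Per Kilobase per Million mapped reads.

    RPKM[g, s] = count / (length_kb[g] * total_millions[s]); totals
    default to the per-sample column sums.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"missing gene length for {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = geometric mean gene)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf.fillna(1.0)


@dataclass
class DEResult:
    table: pd.DataFrame  # gene x (baseMeanA, baseMeanB, log2fc, pvalue, de)
    dispersion: pd.Series


def _mom_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion, method of moments pooled across conditions."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    df = 0
    for cols in groups:
        sub = norm[:, cols]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (v - m)
        den += m ** 2
        df += sub.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(disp, 0.0, None), df


def de_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    fc_cut: float = LOG2FC_CUT,
    p_cut: float = DE_P_CUT,
    prior_df: float = 20.0,
    literal_criteria: bool = False,
) -> DEResult:
    """Differential expression of condition A vs condition B.

    Size factors are estimated jointly; per-gene dispersions (method of
    moments, pooled across conditions) are moderated toward the common
    across-gene dispersion with ``prior_df`` prior degrees of freedom.
    Each gene is tested with an exact NB conditional test on the
    normalized condition totals. log2FC uses a 0.5 pseudocount on the
    normalized means; the DE flag is |log2FC| > fc_cut and P < p_cut
    (``literal_criteria`` inverts the fold-change inequality).
    """
    if counts_a.shape[1] < 1 or counts_b.shape[1] < 1:
        raise ValueError("need >= 1 replicate per condition")
    joint = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(joint)
    norm = joint.div(sf, axis=1).to_numpy(dtype=float)
    n_a = counts_a.shape[1]
    cols_a = np.arange(n_a)
    cols_b = np.arange(n_a, joint.shape[1])

    disp_gene, df = _mom_dispersion(norm, [cols_a, cols_b])
    common = float(disp_gene[norm.mean(axis=1) > 0].mean()) if df > 0 else 0.0
    disp = (disp_gene * df + common * prior_df) / max(df + prior_df, 1)
    disp = np.clip(disp, 1e-8, None)

    mean_a = norm[:, cols_a].mean(axis=1)
    mean_b = norm[:, cols_b].mean(axis=1)
    log2fc = np.log2(mean_a + 0.5) - np.log2(mean_b + 0.5)

    # exact conditional test on per-condition totals: under H0 the
    # totals T_A ~ NB(n_a * mu, disp / n_a), T_B ~ NB(n_b * mu, disp / n_b)
    t_a = np.rint(norm[:, cols_a].sum(axis=1)).astype(np.int64)
    t_b = np.rint(norm[:, cols_b].sum(axis=1)).astype(np.int64)
    n_b = len(cols_b)
    pvals = np.ones(len(t_a))
    for i in range(len(t_a)):
        s = t_a[i] + t_b[i]
        if s == 0:
            log2fc[i] = 0.0
            continue
        pvals[i] = _exact_nb_pvalue(t_a[i], t_b[i], n_a, n_b, disp[i])

    if literal_criteria:
        de = (np.abs(log2fc) < fc_cut) & (pvals < p_cut)
    else:
        de = (np.abs(log2fc) > fc_cut) & (pvals < p_cut)

    table = pd.DataFrame(
        {
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "de": de,
        },
        index=joint.index,
    )
    return DEResult(table, pd.Series(disp, index=joint.index))


def _exact_nb_pvalue(
    ta: int, tb: int, n_a: int, n_b: int, disp: float
) -> float:
    """Two-sided exact test: condition totals conditioned on ta + tb.

    Under H0 both conditions share mean mu; with the sum s = ta + tb
    fixed, P(T_A = t | s) is proportional to pmf_A(t) * pmf_B(s - t)
    where pmf_C is NB with size n_C/disp and mean n_C * mu_hat. The
    two-sided P sums all outcomes no more probable than the observed.
    """
    s = ta + tb
    mu = s / (n_a + n_b)
    r_a = n_a / disp
    r_b = n_b / disp
    t = np.arange(s + 1)
    logp = stats.nbinom.logpmf(
        t, r_a, r_a / (r_a + n_a * mu)
    ) + stats.nbinom.logpmf(s - t, r_b, r_b / (r_b + n_b * mu))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(min(1.0, p[p <= p[ta] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_expression_groups(
    log2fc: pd.DataFrame, k: int = 3, seed: int = 0
) -> tuple[pd.Series, np.ndarray]:
    """k-means on the genes x mutants log2 fold-change matrix.

    Returns (labels indexed by gene, centroids ordered by mean
    fold-change ascending).
    """
    labels, centroids = kmeans_cluster(log2fc.to_numpy(), k=k, seed=seed)
    return pd.Series(labels, index=log2fc.index, name="group"), centroids


def sample_correlation_clustering(
    log2fc: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hierarchical clustering of samples by Pearson correlation of
    per-gene log2 fold-changes (distance 1 - r, average linkage).

    Returns (scipy linkage matrix, correlation matrix). Columns are
    processed in name-sorted order so tie-breaks are deterministic.
    """
    if log2fc.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    df = log2fc[sorted(log2fc.columns)]
    if (df.std(axis=0) == 0).any():
        bad = df.columns[(df.std(axis=0) == 0)][0]
        raise ValueError(f"zero-variance sample {bad!r}")
    corr = df.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return link, corr


def cluster_tissues(
    expression: pd.DataFrame, k: int = 8, seed: int = 0
) -> pd.Series:
    """k-means grouping of tissues (columns) on per-gene standardized
    expression profiles."""
    if k > expression.shape[1]:
        raise ValueError("k exceeds the number of tissues")
    x = expression.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    labels, _ = kmeans_cluster(z.T, k=k, seed=seed)
    return pd.Series(labels, index=expression.columns, name="tissue_group")


def tissue_specificity_rank(
    expression: pd.DataFrame,
    tissue_group: list[str],
    min_mean: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Rank genes by specificity to a tissue group.

    Score = mean log2 expression within the group minus mean elsewhere,
    z-standardized across genes; descending order. Genes with mean
    expression below ``min_mean`` across all tissues are removed first.
    """
    group = [t for t in tissue_group if t in expression.columns]
    if not group:
        raise ValueError("tissue group is empty")
    others = [c for c in expression.columns if c not in group]
    if not others:
        raise ValueError("tissue group covers all tissues")
    expr = expression[expression.mean(axis=1) >= min_mean]
    logx = np.log2(expr + pseudocount)
    score = logx[group].mean(axis=1) - logx[others].mean(axis=1)
    sd = score.std(ddof=0)
    if sd > 0:
        score = (score - score.mean()) / sd
    return score.sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    es: float
    nes: float
    pvalue: float
    leading_edge: list[str]
    running_score: np.ndarray


def _enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int, np.ndarray]:
    """Weighted KS running statistic; returns (ES, extremum index, trace)."""
    n = len(scores)
    n_hits = int(hit_mask.sum())
    weights = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        hit_w = hit_mask.astype(float)
        total_hit = hit_w.sum()
    miss = np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(hit_w / total_hit - miss)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), i_ext, running


def gsea(
    ranked: pd.Series,
    gene_set: set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Gene set enrichment analysis on a pre-ranked gene list.

    ``ranked`` maps genes (index) to ranking scores, ordered descending.
    ES is the extremum of the weighted KS running score (hits increment
    proportionally to |score|^weight, misses decrement uniformly); the
    null distribution permutes gene-set labels (random sets of the same
    size); NES = ES / mean |ES_null| with sign preserved;
    P = (1 + #{|ES_null| >= |ES|}) / (n_perm + 1); the leading edge is
    the hits up to (through) the extremum.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    hit_mask = np.isin(genes, list(gene_set))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene set covers the whole ranked list")

    es, i_ext, running = _enrichment_score(scores, hit_mask, weight)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_mask = np.zeros(len(genes), dtype=bool)
        perm_mask[rng.choice(len(genes), size=n_hits, replace=False)] = True
        null[i], _, _ = _enrichment_score(scores, perm_mask, weight)
    mean_abs = np.abs(null).mean()
    nes = es / mean_abs if mean_abs > 0 else 0.0
    p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (n_perm + 1)

    if es >= 0:
        leading = genes[: i_ext + 1][hit_mask[: i_ext + 1]]
    else:
        leading = genes[i_ext:][hit_mask[i_ext:]]
    return GseaResult(es, float(nes), float(p), list(leading), running)
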