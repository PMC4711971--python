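"""Replicate-concordance metrics and the ChIP-qPCR percent-input formula.

The Robust Index compares the log2 fold-changes a feature shows in two
replicate datasets; regions or genes with a lower Robust Index are more
reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def robust_index(fc1, fc2, literal: bool = False) -> float | np.ndarray:
    """Robust Index = |log2 FC1 - log2 FC2| / (|log2 FC1| + |log2 FC2|).

    Defined as 0 when both log fold-changes are 0. The default
    denominator takes absolute values so the index is non-negative;
    ``literal=True`` uses the signed sum (log2 FC1 + log2 FC2), which
    can be zero or negative for discordant replicates.
    """
    fc1 = np.asarray(fc1, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    if np.any(fc1 <= 0) or np.any(fc2 <= 0):
        raise ValueError("fold changes must be strictly positive")
    l1 = np.log2(fc1)
    l2 = np.log2(fc2)
    num = np.abs(l1 - l2)
    den = (l1 + l2) if literal else (np.abs(l1) + np.abs(l2))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((num == 0) & (den == 0), 0.0, num / den)
    return out if out.ndim else float(out)


def foldchange_concordance(values1, values2) -> float:
    """Pearson correlation of paired log2 fold-changes between replicates."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) != len(v2) or len(v1) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero-variance replicate vector")
    r, _ = stats.pearsonr(v1, v2)
    return float(r)


def percent_input(ct_input, ct_ip, ct_neg):
    """ChIP-qPCR percent input from cycle thresholds.

    %input = 2^(Ct_input - Ct_IP) - 2^(Ct_input - Ct_neg), as a
    fraction (multiply by 100 for percent). Negative values (Ct_IP >
    Ct_neg) and values above 1 (Ct_IP < Ct_input) are numerically valid
    and should be flagged by the caller as suspicious.
    """
    ct_input = np.asarray(ct_input, dtype=float)
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_neg = np.asarray(ct_neg, dtype=float)
    if not (
        np.all(np.isfinite(ct_input))
        and np.all(np.isfinite(ct_ip))
        and np.all(np.isfinite(ct_neg))
    ):
        raise ValueError("Ct values must be finite")
    out = np.exp2(ct_input - ct_ip) - np.exp2(ct_input - ct_neg)
    return out if out.ndim else float(out)
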