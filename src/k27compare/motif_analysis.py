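"""PWM scanning and motif enrichment of peak sets.

The raw motif matching score of a peak is the maximum log-odds
log2 P(S|M) / P(S|B) over all windows S of motif width within a 1 kb
window centred on the peak centre, on both strands. Occurrence calls
use a per-motif threshold calibrated as a high quantile of scores on
background-sampled sequences, and enrichment compares occurrence
fractions in the peak set against random genomic regions with Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode(sequence: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> -1."""
    return _BASE_INDEX[np.frombuffer(sequence.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """A motif probability matrix with genomic background frequencies.

    ``matrix`` is 4 x w (rows A, C, G, T; columns sum to 1);
    ``background`` is the 4-vector of genome nucleotide frequencies.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        b = np.asarray(self.background, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("matrix must be 4 x w")
        if np.any(m <= 0):
            raise ValueError("probabilities must be strictly positive")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("matrix columns must sum to 1")
        if not np.isclose(b.sum(), 1.0, atol=1e-9) or np.any(b <= 0):
            raise ValueError("background must be positive and sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", b)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(motif_id, probs, np.asarray(background, dtype=float))

    @property
    def log_odds(self) -> np.ndarray:
        """4 x w log2(p / background); row for N (-1) handled separately."""
        return np.log2(self.matrix / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=0))


@dataclass(frozen=True)
class ScanResult:
    peak_index: int
    score: float
    position: int  # window start, coordinates of the scanned sequence
    strand: str
    occurrence: bool


def _window_scores(idx: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Score of every width-w window of an encoded sequence.

    N bases (index -1) contribute 0 (background-equivalent).
    """
    w = lodds.shape[1]
    n_win = len(idx) - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    padded = np.vstack([lodds, np.zeros(w)])  # row 4 (= index -1) scores 0
    for j in range(w):
        scores += padded[idx[j : j + n_win], j]
    return scores


def _best_score_encoded(idx: np.ndarray, pwm: PWM) -> tuple[float, int, str]:
    lodds = pwm.log_odds
    fwd = _window_scores(idx, lodds)
    # reverse strand: score the reverse-complement motif on the forward
    # sequence; position i marks the window whose RC matches the motif.
    # Row reversal maps each base to its complement (rows are A,C,G,T);
    # index -1 (N) still lands on the appended zero row.
    rev = _window_scores(idx, lodds[::-1, ::-1])
    best_f = int(np.argmax(fwd))
    best_r = int(np.argmax(rev))
    if fwd[best_f] >= rev[best_r]:
        return float(fwd[best_f]), best_f, "+"
    return float(rev[best_r]), best_r, "-"


def log_odds_score(sequence: str, pwm: PWM) -> tuple[float, int, str]:
    """Best log2-odds score over all windows and both strands.

    Returns (score, window start on the forward sequence, strand).
    Ties prefer the leftmost position and the forward strand.
    """
    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than motif width")
    return _best_score_encoded(encode(sequence), pwm)


def calibrate_threshold(
    pwm: PWM,
    seq_length: int = 1000,
    n: int = 1000,
    quantile: float = 0.999,
    seed: int = 0,
) -> float:
    """Occurrence threshold: the given quantile of best scores on
    background-sampled sequences of the scan-window length."""
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(n, seq_length), p=pwm.background)
    scores = np.empty(n)
    for i in range(n):
        scores[i], _, _ = _best_score_encoded(
            draws[i].astype(np.int8), pwm
        )
    return float(np.quantile(scores, quantile))


def scan_peaks(
    peaks: list[GenomicInterval],
    sequences: dict[str, str],
    pwm: PWM,
    window: int = 1000,
    threshold: float | None = None,
    threshold_seed: int = 0,
) -> list[ScanResult]:
    """Scan a ``window`` bp region centred on each peak centre.

    Windows are clipped at chromosome edges. ``threshold=None``
    calibrates the per-motif background quantile threshold.
    """
    if threshold is None:
        threshold = calibrate_threshold(
            pwm, seq_length=window, seed=threshold_seed
        )
    out: list[ScanResult] = []
    for i, iv in enumerate(peaks):
        if iv.chrom not in sequences:
            raise KeyError(f"chromosome {iv.chrom!r} absent from FASTA")
        seq = sequences[iv.chrom]
        centre = iv.center
        lo = max(0, centre - window // 2)
        hi = min(len(seq), centre + window // 2)
        sub = seq[lo:hi]
        if len(sub) < pwm.width:
            out.append(ScanResult(i, -np.inf, lo, ".", False))
            continue
        score, pos, strand = log_odds_score(sub, pwm)
        out.append(
            ScanResult(i, score, lo + pos, strand, score >= threshold)
        )
    return out


def sample_random_regions(
    chrom_sizes: dict[str, int],
    n: int,
    lengths: list[int],
    seed: int = 0,
) -> list[GenomicInterval]:
    """n random regions, chromosomes chosen proportional to length,
    lengths drawn from the query set's empirical lengths."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out: list[GenomicInterval] = []
    for _ in range(n):
        size = int(lengths[rng.integers(0, len(lengths))])
        feasible = [i for i, c in enumerate(chroms) if chrom_sizes[c] >= size]
        if not feasible:
            raise ValueError(f"length {size} exceeds every chromosome")
        p = probs[feasible] / probs[feasible].sum()
        ci = feasible[rng.choice(len(feasible), p=p)]
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - size + 1))
        out.append(GenomicInterval(chroms[ci], start, start + size))
    return out


def motif_enrichment(
    peaks: list[GenomicInterval],
    pwms: list[PWM],
    sequences: dict[str, str],
    chrom_sizes: dict[str, int],
    n_random: int = 1000,
    window: int = 1000,
    seed: int = 0,
    p_enriched: float = 0.01,
    calibration_n: int = 1000,
) -> list[dict]:
    """Per-motif occurrence enrichment of a peak set vs random regions.

    ratio = occurrence fraction in peaks / occurrence fraction in
    random regions; P from Fisher's exact test on the 2x2 occurrence
    table; enriched flag at P < 0.01 with ratio > 1. A motif absent
    from both sets has an undefined (NaN) ratio.
    """
    if not peaks:
        raise ValueError("peak set must be non-empty")
    lengths = [len(iv) for iv in peaks]
    random_regions = sample_random_regions(
        chrom_sizes, n_random, lengths, seed=seed
    )
    results = []
    for pwm in pwms:
        thr = calibrate_threshold(
            pwm, seq_length=window, n=calibration_n, seed=seed
        )
        peak_scan = scan_peaks(peaks, sequences, pwm, window, threshold=thr)
        rand_scan = scan_peaks(
            random_regions, sequences, pwm, window, threshold=thr
        )
        k_peak = sum(r.occurrence for r in peak_scan)
        k_rand = sum(r.occurrence for r in rand_scan)
        f_peak = k_peak / len(peaks)
        f_rand = k_rand / n_random
        table = [
            [k_peak, len(peaks) - k_peak],
            [k_rand, n_random - k_rand],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        ratio = f_peak / f_rand if f_rand > 0 else (
            np.inf if f_peak > 0 else np.nan
        )
        results.append(
            {
                "motif": pwm.motif_id,
                "peak_fraction": f_peak,
                "random_fraction": f_rand,
                "ratio": ratio,
                "pvalue": float(p),
                "enriched": bool(p < p_enriched and f_peak > f_rand),
                "threshold": thr,
            }
        )
    return results


def motif_position_profile(
    scans: list[ScanResult],
    summits: list[int],
    bin_size: int = 50,
    halfwidth: int = 500,
) -> np.ndarray:
    """Histogram of motif-occurrence distances to the peak summit.

    Fractions per distance bin over [-halfwidth, +halfwidth); sums to 1
    over occurrences falling inside the range.
    """
    dists = [
        s.position - summits[s.peak_index] for s in scans if s.occurrence
    ]
    if not dists:
        raise ValueError("no motif occurrences to profile")
    edges = np.arange(-halfwidth, halfwidth + bin_size, bin_size)
    hist, _ = np.histogram(dists, bins=edges)
    total = hist.sum()
    if total == 0:
        raise ValueError("no occurrences within the profiled range")
    return hist / total
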