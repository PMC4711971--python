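# Methods

This note documents the models and procedures implemented in
`k27compare`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open. Conversion happens
exactly once, at the I/O boundary: BED and bedGraph are half-open on
disk and pass through unchanged; GFF3 (1-based closed) is converted on
read (`start-1`, `end`). Genes are reduced to a single stranded span
per gene id; the TSS is the strand-aware 5′ end. Position frequency
matrices (JASPAR layout, parsed with Biopython) are converted to
probabilities with a +1 pseudocount per cell so no log-odds term is
−∞.

## Tag tracks and peak calling

A `TagTrack` is a per-chromosome sorted array of single-base tag
positions (5′ ends, with an optional constant fragment shift applied at
construction — the shift is exposed as configuration because no single
value is canonical). Interval counts are two binary searches.

The caller is a deliberately small Poisson sliding-window scanner in
the MACS mould, not a reimplementation of it: windows (default 300 bp,
step 100 bp — broad-mark-friendly values, configurable) are tested
against an upper-tail Poisson P with
λ_local = max(genome-wide rate, control rate over 1/5/10 kb surrounds
rescaled to treatment depth) × window; windows with P below the cutoff
(default 1e-5) merge when closer than 200 bp. The summit is the centre
of maximum 100 bp-smoothed coverage, leftmost on ties. A chromosome
missing from a track counts as zero coverage with a warning rather
than an error, since a mutant library may legitimately lack a
scaffold. Known behaviour relevant downstream: called intervals extend
of order one window-step past the true enriched region into
background, which dilutes whole-region fold-changes slightly (see
"Differential criteria" below).

## MA normalization

For a mutant-vs-wild-type pair, peaks are partitioned into *common*
(≥ 1 bp overlap with a peak of the other sample; greedy 1:1 matching
by descending overlap length) and *unique*. Each common pair is
collapsed to the union interval of the two peaks — the exact region
bookkeeping of the published normalization tool is not documented, so
this package fixes one deterministic rule. Counts over the region in
each track give

    M = log2((x+0.5)/(y+0.5)),  A = ½·log2((x+0.5)(y+0.5)),

with the 0.5 pseudocount avoiding log 0. The key assumption, inherited
from the MA-normalization idea, is that peaks common to both samples
are predominantly unchanged, so a robust linear trend M = a + b·A
fitted over common peaks (Huber loss, tuning constant 1.345, via
statsmodels RLM) captures the technical between-sample bias; the
normalized value is M′ = M − (a + b·A). The assumption fails — and the
fit visibly absorbs biology — when a large share of common peaks is
differential *and* their intensity correlates with the effect; the
synthetic defaults keep differential peaks a minority per comparison
for this reason. After fitting, the median M′ over common peaks is
required to sit within ±0.1 of zero; the comparison table carries the
fit coefficients in `attrs["fit"]`.

Significance uses the Audic–Claverie conditional count model,

    p(y | x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)),

which for fixed x is a negative binomial with r = x+1 and success
probability N1/(N1+N2); tails are therefore evaluated in log space via
`scipy.stats.nbinom` (an explicit factorial summation is kept as the
independent oracle in the tests). The two-sided P doubles the smaller
of the two lower tails P(Y ≤ y | x) and P(X ≤ x | y); this form equals
the textbook "double the smaller tail" value on the cases of interest
and is *exactly* symmetric under swapping the samples, which the
doubled upper/lower-tail form is not. The test is applied to (x, y′)
where y′ = (y+0.5)·2^−(a+b·A) − 0.5, rounded and floored at 0 — i.e.
the wild-type count rescaled onto the mutant scale by the fitted
trend — with equal effective library sizes.

Browser-track scaling follows two rules: mutant tracks are multiplied
by s = (wild-type tags in common peak regions)/(mutant tags there), so
common-region totals match exactly; input tracks are scaled by the
ratio of Poisson rates (mean tags per 1 kb window, the Poisson MLE)
estimated in peak-free regions.

## Differential criteria, M matrix, peak sets

A region is *down* iff M′ < −1 and P < 1e-3, *up* iff M′ > +1 and
P < 1e-3; inequalities are strict, matching the printed ">" of the
criteria. Regions differential in ≥ 1 comparison are union-merged
(overlapping regions from different comparisons become one row) and
projected onto every comparison by ≥ 1 bp overlap, taking the
overlapping peak's M′; where a comparison has no overlapping peak the
cell is filled with raw M recomputed from tag counts over the region —
zero-filling would drag absent-but-covered regions toward "no change".
k-means (scikit-learn, 50 k-means++ restarts under a fixed seed) on
the matrix yields the peak sets; clusters are reported ordered by
ascending centroid mean M so labels are stable. M-value bins rank
peaks by M′ descending and cut them into n consecutive near-equal
groups (remainder to the leading groups; default 8 bins — enough to
show a trend without empty bins at desk scale).

Because a 2-fold change sits *exactly at* the |M′| > 1 boundary, the
expected detection rate for 2-fold effects is ~0.5 by construction,
and in practice lower still because called-peak extension dilutes
whole-region M; the sensitivity claims this package makes are for
effects clearly past the boundary (≥ 4-fold), where recovery is
essentially complete (measured by `scripts/acceptance.py`).

## Targeting, overlap statistics, spreading

The target of a peak is chosen among genes whose window
[TSS − 1 kb, TES] (strand-aware) overlaps the peak by ≥ 1 bp, taking
the gene with TSS nearest the summit, ties by lexicographic gene id;
peaks without candidates are explicitly unassigned. A variant rule
(gene body within 1 kb of the peak on either side) is available as
`rule="peak_window"`.

The permutation overlap test re-places each reference region uniformly
at random (chromosome chosen proportional to length, length preserved,
overlaps among shuffled regions permitted — only length preservation
is part of the procedure being modelled) and counts query regions
overlapped; the empirical P uses the +1 correction,
P = (1 + #{null ≥ observed})/(n+1), so P = 1/(n+1) is the floor and at
the default n = 1000 an extreme observation is reported as P < 1e-3.
Fisher tests (region co-occupancy over a universe; DE-gene enrichment
of target groups, with the observed/expected score
obs/( |group|·|de|/|universe| ) and stars at 5e-2/1e-2/1e-3) use
`scipy.stats.fisher_exact`, with the Haldane +0.5 correction for odds
ratios when a cell is zero.

The spreading classifier splits a down-regulated region at the summit:
M is computed (pseudocount 0.5, mutant counts multiplied by the
common-region scale factor) over the summit window [summit ± 250 bp)
and over the remaining flanks. The region is *flank-biased* when
M_flank ≤ −1 and M_summit − M_flank ≥ 1 — loss concentrated away from
the summit. The half-width and both thresholds are configurable
because the underlying phenomenon ("less reduction at summits") does
not come with a canonical statistic; the defaults are chosen so that a
3-fold flank-only reduction with ≥ 50 tags per flank is reliably
flagged while uniform reductions of any depth are not (both rates are
measured, not asserted, in the acceptance suite).

## Motif analysis

The score of a motif on a peak is max over all windows S (motif width)
of Σ log2 p_i(S_i)/B(S_i), over a 1 kb window centred on the peak
centre and over both strands (reverse-strand scores come from the
reverse-complemented matrix scanned on the forward sequence; complement
is row reversal because rows are ordered A,C,G,T). Log base 2 is used
throughout; the base cancels out of occurrence calls because
thresholds are calibrated per motif: the default occurrence threshold
is the 99.9th percentile of best scores on background-sampled
sequences of the scan-window length (1,000 draws). N bases contribute
0 (background-equivalent). For short, high-information motifs this
quantile can saturate at the maximum attainable score; occurrence uses
≥, so exact-consensus matches still count. Enrichment of a peak set is
the ratio of occurrence fractions in peaks vs random genomic regions
(lengths resampled from the query set, chromosomes ∝ length), with a
two-sided Fisher P on the 2×2 occurrence table and an enriched flag at
P < 0.01 with ratio > 1.

## Expression

RPKM = count / (gene length in kb × mapped reads in millions).
Differential expression: size factors by median-of-ratios; per-gene NB
dispersion by method of moments pooled across conditions, moderated
toward the common (across-gene mean) dispersion with 20 prior degrees
of freedom — with two replicates a raw per-gene estimate is mostly
noise, and the moderation is what keeps the test calibrated (type-I
error at P < 0.05 measured within [0.03, 0.07] on simulated nulls);
the per-gene test is exact and conditional, comparing the normalized
condition totals T_A, T_B given their sum under a shared NB mean, with
a two-sided P summing outcomes no more probable than observed. The DE
flag combines |log2FC| > 1 (0.5 pseudocount on normalized means) with
P < 0.05. A printed variant of this criterion with the fold-change
inequality inverted exists in the literature this package follows; the
inverted form selects the *unchanged* genes, so the package treats it
as a typographic slip and implements ">", keeping the literal form
behind `literal_criteria=True`. Externally computed DE tables in the
same schema can be used in place of the built-in test.

Expression-pattern groups are k-means (k = 3 by default) on the genes ×
mutants log2FC matrix; sample relationships use hierarchical average
linkage on 1 − Pearson r of per-gene log2FC (columns processed in
name-sorted order for deterministic ties); tissues are clustered by
k-means (k = 8 by default) on per-gene z-scored expression profiles.
Tissue specificity ranks genes by mean log2 expression in the group
minus mean elsewhere, z-standardized, after removing genes with mean
expression below 2.

GSEA is the classic weighted Kolmogorov–Smirnov running score: hits
increment by |score|^w / Σ_hits |score|^w (w = 1 by default; w = 0 is
the unweighted form with closed-form checks), misses decrement by
1/(N − N_hits); ES is the extremum. The null permutes gene-set labels
(random same-size sets), NES = ES / mean|ES_null| with sign preserved,
P = (1 + #{|ES_null| ≥ |ES|})/(n_perm + 1), and the leading edge is
the hits up to and including the extremum.

## Replicate QC

Robust Index = |log2 FC1 − log2 FC2| / (|log2 FC1| + |log2 FC2|),
defined as 0 when both logs are 0; lower is more reproducible. The
denominator uses absolute values — the signed sum can be zero or
negative for discordant replicates, which would break the "lower is
better" reading; the literal signed form is available via
`literal=True`. Percent input = 2^(Ct_input − Ct_IP) −
2^(Ct_input − Ct_neg); negative values and values above 1 are returned
as-is for the caller to flag.

## Synthetic data: what it emulates, and what it does not

The generator produces: random sequences at configurable base
frequencies; uniformly placed non-overlapping stranded genes (2 kb by
default); peaks centred on a random subset of genes (fixing the true
target) with a triangular enrichment profile rising from background at
the edges to the per-peak fold at the true summit — a flat profile
would leave summits undefined — discretized at 25 bp, with per-peak
folds drawn uniformly in mean ± 50% so A values span a realistic
range; mutant effects applied regionally (uniform division by a fold;
flank-only division preserving a ± halfwidth summit window; uniform
multiplication), so the flank/summit count-ratio truths hold by
construction; tags drawn per bin either as Poisson (default; totals
random) or as an exact multinomial allocation of a configured library
size; replicates as independent redraws; NB expression counts whose
means are multiplied (divided) by a configured fold for genes whose
peak loses (gains) the mark; and motif instances sampled column-wise
from a PWM, implanted on a uniform strand and position in a Bernoulli
fraction of peaks. Every stream derives from `(seed, product-name)`,
so outputs are byte-identical under a fixed config and independent of
call order.

Default study conditions: 1 Mb genome in two chromosomes, 250 genes,
120 peaks of 1.5 kb at 10× mean enrichment over 0.02 tags/bp (≈ 165
wild-type tags per peak per replicate), two replicates; effect classes
set_I (15%, flank reduction fold 6 with a 100 bp preserved summit
window, in the clf/lhp1-like samples), set_II (12%, uniform fold-4
reduction in the bmi1/ring1-like samples), set_III (8%, fold-2.5
increase), the rest stable; expression NB dispersion 0.05 and 4-fold
de-repression. Differential classes are deliberately a minority so the
common-peak normalization assumption holds; the set_I fold is chosen
so expected whole-region M (≈ −1.35 after accounting for called-peak
extension into background) clears the |M| > 1 cutoff while the summit
stays at wild-type level — i.e. the flank-biased regions appear
*inside* the differential set, which is the phenomenon of interest.

What the generator does not emulate — and hence what passing tests do
not show about real data: read-level sequencing (no FASTQ, no error or
duplicate model), mappability and GC structure, overlapping or
isoform-rich gene models, correlated replicate noise, batch effects,
composition bias between libraries beyond a global depth factor, and
biological coupling subtler than "reduction ⇒ fixed-fold
de-repression". Results on real libraries depend on upstream
alignment and filtering that are outside this package's scope.

## Numerical choices and degenerate inputs

Pseudocounts: 0.5 in all M/A and fold-change logs; +1 per PFM cell.
Ties: leftmost summit; leftmost, forward-strand motif window;
name-sorted samples in hierarchical clustering; stable sorts
throughout. Empty cases: empty peak lists partition to all-unique;
an empty treatment track calls no peaks (warning); all-zero genes get
P = 1 and log2FC = 0. Errors: < 10 common peaks cannot be normalized;
zero mutant tags in common regions, zero input rate, zero-variance
samples, empty query sets, infeasible shuffle lengths and
motif-wider-than-peak implants all raise with specific messages.
P-value floors: permutation and GSEA P use the +1 correction;
Audic–Claverie P is clamped away from 0 at the smallest positive
float. k-means uses 50 restarts under a fixed seed; determinism is a
test invariant, not an aspiration.

## Known limitations

The peak caller is desk-scale: single-CPU numpy scanning, no model-
based fragment-size estimation, no broad/narrow duality; its peak
boundaries are window-quantized. Greedy 1:1 common-peak matching can
mis-pair in dense peak neighbourhoods where a split/merge treatment
would differ. The NB DE test's moderation constant (20 prior df) is a
fixed choice, not estimated from data. GSEA uses gene-label
permutation, which ignores inter-gene correlation and is
anti-conservative on strongly co-expressed sets. The motif occurrence
threshold saturates for very short/strong motifs (see above). The
spreading statistic is a two-threshold rule on summit/flank M values,
chosen for transparency over power.
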