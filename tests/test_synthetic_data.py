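"""Determinism, distributional truths and conservation laws of the
synthetic-data generator."""

import numpy as np
import pytest

from k27compare.intervals import GenomicInterval
from k27compare.motif_analysis import PWM, log_odds_score
from k27compare.synthetic_data import (
    EffectSpec,
    PeakClassSpec,
    SimulationConfig,
    generate_genome,
    implant_motifs,
    simulate_expression,
    simulate_tracks,
    write_bundle,
)
from tests.conftest import small_config


class TestConfigValidation:
    def test_reduction_fold_must_exceed_one(self):
        with pytest.raises(ValueError, match="> 1"):
            EffectSpec("uniform_reduction", 1.0)

    def test_unknown_effect_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            small_config(
                samples=("a",),
                peak_classes=[
                    PeakClassSpec("x", 0.5, {"zz": EffectSpec("increase", 2.0)})
                ],
            )

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            small_config(background_rate=0.0)


class TestGenerateGenome:
    def test_zero_genes_still_emits_sequences(self):
        genome = generate_genome(small_config(n_genes=0, n_peaks=0))
        assert genome.genes == []
        assert len(genome.sequences["chr1"]) == 120_000

    def test_byte_identical_under_seed(self, tmp_path):
        config = small_config()
        for d in ("a", "b"):
            genome = generate_genome(config)
            tracks, truth = simulate_tracks(genome, config)
            counts = simulate_expression(genome, truth, config)
            write_bundle(tmp_path / d, genome, tracks, truth, counts)
        for name in ["genome.fa", "genes.gff3", "truth_peaks.tsv",
                     "tags_wt_rep1.bed", "expression_counts.tsv"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_base_frequencies_within_binomial_bound(self):
        config = small_config(chrom_lengths={"chr1": 100_000}, n_genes=0,
                              n_peaks=0)
        genome = generate_genome(config)
        seq = genome.sequences["chr1"]
        se = np.sqrt(0.25 * 0.75 / 100_000)
        for base in "ACGT":
            assert abs(seq.count(base) / 100_000 - 0.25) < 3 * se

    def test_genes_nonoverlapping_within_bounds(self):
        genome = generate_genome(small_config(n_genes=40))
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda v: v.start)
            assert ivs[-1].end <= genome.chrom_sizes[chrom]
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="fit"):
            generate_genome(
                small_config(chrom_lengths={"chr1": 10_000}, n_genes=50)
            )


class TestSimulateTracks:
    def test_no_effect_means_unit_count_ratio(self):
        config = small_config(samples=("mut",), peak_classes=[], n_peaks=15)
        genome = generate_genome(config)
        tracks, truth = simulate_tracks(genome, config)
        wt_counts = mut_counts = 0
        for r in truth.peaks.itertuples():
            iv = GenomicInterval(r.chrom, r.start, r.end)
            wt_counts += tracks["wt_rep1"].count(iv)
            mut_counts += tracks["mut_rep1"].count(iv)
        ratio = mut_counts / wt_counts
        se = np.sqrt(1 / wt_counts + 1 / mut_counts)
        assert abs(ratio - 1) < 3 * se

    def test_flank_reduction_ratio_truth(self):
        config = small_config(
            samples=("mut",),
            peak_classes=[
                PeakClassSpec(
                    "f", 1.0, {"mut": EffectSpec("flank_reduction", 2.0, 250)}
                )
            ],
            n_peaks=15,
        )
        genome = generate_genome(config)
        tracks, truth = simulate_tracks(genome, config)
        wt_s = mut_s = wt_f = mut_f = 0
        for r in truth.peaks.itertuples():
            summit_iv = GenomicInterval(r.chrom, r.summit - 250, r.summit + 250)
            region = GenomicInterval(r.chrom, r.start, r.end)
            for rep in (1, 2):
                wt_s += tracks[f"wt_rep{rep}"].count(summit_iv)
                mut_s += tracks[f"mut_rep{rep}"].count(summit_iv)
                wt_f += tracks[f"wt_rep{rep}"].count(region)
                mut_f += tracks[f"mut_rep{rep}"].count(region)
        wt_f -= wt_s
        mut_f -= mut_s
        r_summit = mut_s / wt_s
        r_flank = mut_f / wt_f
        assert abs(r_summit - 1.0) < 3 * np.sqrt(1 / wt_s + 1 / mut_s)
        assert abs(r_flank - 0.5) < 3 * 0.5 * np.sqrt(1 / wt_f + 1 / mut_f)

    def test_background_tag_totals_poisson(self):
        config = small_config(n_peaks=0, n_genes=0)
        genome = generate_genome(config)
        tracks, _ = simulate_tracks(genome, config)
        lam = config.background_rate * sum(config.chrom_lengths.values())
        for track in tracks.values():
            assert abs(track.total - lam) < 4 * np.sqrt(lam)

    def test_exact_library_size_conservation(self):
        config = small_config(library_sizes=5000)
        genome = generate_genome(config)
        tracks, _ = simulate_tracks(genome, config)
        assert all(t.total == 5000 for t in tracks.values())

    def test_replicates_are_independent_redraws(self):
        config = small_config()
        genome = generate_genome(config)
        tracks, _ = simulate_tracks(genome, config)
        assert not np.array_equal(
            tracks["wt_rep1"].positions["chr1"],
            tracks["wt_rep2"].positions["chr1"],
        )


class TestSimulateExpression:
    def test_poisson_limit_variance(self):
        config = small_config(
            expression_dispersion=1e-12, n_replicates=8, samples=("mut",),
            peak_classes=[],
        )
        genome = generate_genome(config)
        _, truth = simulate_tracks(genome, config)
        counts = simulate_expression(genome, truth, config)
        wt = counts[[c for c in counts if c.startswith("wt")]]
        ratio = wt.var(axis=1) / wt.mean(axis=1)
        assert abs(ratio.mean() - 1.0) < 0.25

    def test_library_factor_doubles_median(self):
        config = small_config(
            samples=("mut",), peak_classes=[],
            expression_library_factors={"wt_rep2": 2.0},
        )
        genome = generate_genome(config)
        _, truth = simulate_tracks(genome, config)
        counts = simulate_expression(genome, truth, config)
        ratio = (counts["wt_rep2"] / counts["wt_rep1"].clip(lower=1)).median()
        assert 1.6 < ratio < 2.5

    def test_invalid_dispersion(self):
        config = small_config()
        genome = generate_genome(config)
        _, truth = simulate_tracks(genome, config)
        object.__setattr__  # dataclass not frozen; mutate directly
        config.expression_dispersion = -1.0
        with pytest.raises(ValueError):
            simulate_expression(genome, truth, config)


class TestImplantMotifs:
    def _pwm(self):
        mat = np.full((4, 8), 0.01)
        for j, b in enumerate("ACGTTGCA"):
            mat["ACGT".index(b), j] = 0.97
        return PWM("m", mat, np.full(4, 0.25))

    def test_rate_zero_unchanged(self):
        seqs = {"chr1": "ACGT" * 1000}
        peaks = [GenomicInterval("chr1", 0, 2000)]
        out, flags = implant_motifs(seqs, peaks, self._pwm(), 0.0, seed=0)
        assert out == seqs and flags == [False]

    def test_rate_one_all_implanted_and_scannable(self):
        rng = np.random.default_rng(0)
        seqs = {"chr1": "".join(rng.choice(list("ACGT"), 50_000))}
        peaks = [
            GenomicInterval("chr1", i * 1000, i * 1000 + 800) for i in range(40)
        ]
        pwm = self._pwm()
        out, flags = implant_motifs(seqs, peaks, pwm, 1.0, seed=1)
        assert all(flags)
        found = 0
        for iv in peaks:
            score, _, _ = log_odds_score(out[iv.chrom][iv.start:iv.end], pwm)
            # permissive threshold: a single sampling mismatch still passes
            found += score >= 0.55 * 8 * np.log2(0.97 / 0.25)
        assert found / len(peaks) >= 0.95

    def test_binomial_count_bound(self):
        rng = np.random.default_rng(2)
        seqs = {"chr1": "".join(rng.choice(list("ACGT"), 100_000))}
        peaks = [
            GenomicInterval("chr1", i * 500, i * 500 + 400) for i in range(200)
        ]
        _, flags = implant_motifs(seqs, peaks, self._pwm(), 0.5, seed=3)
        se = np.sqrt(200 * 0.25)
        assert abs(sum(flags) - 100) < 3 * se

    def test_motif_wider_than_peaks_is_error(self):
        with pytest.raises(ValueError, match="wider"):
            implant_motifs(
                {"chr1": "ACGTACGT"}, [GenomicInterval("chr1", 0, 4)],
                self._pwm(), 1.0,
            )
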