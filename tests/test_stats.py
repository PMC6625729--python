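"""Statistics layer: enrichment, ROC, permutation null, distributions."""

import numpy as np
import pytest

from oracles import auc_pairwise, bh_step_up, chi2_closed_form, random_dna
from secrete import (
    PlantedMotifSpec,
    ScanConfig,
    SimulationSpec,
    Transcript,
    bh_fdr,
    chi2_enrichment,
    ecdf_compare,
    fraction_with_motif,
    gene_rng,
    generate_transcriptome,
    length_correlation,
    max_run_length,
    permutation_z,
    positional_distribution,
    region_distribution,
    roc_auc,
    scan_transcript,
    shuffle_codons,
    significant_fraction,
    threshold_sweep,
    utr_y_content_comparison,
)

CFG = ScanConfig(10, "Y", {"CDS"}, {0, 1, 2})


class TestFractions:
    def test_counts(self):
        ts = [Transcript(f"y{i}", "TAC" * 30) for i in range(3)]
        ts += [Transcript(f"n{i}", "AAG" * 30) for i in range(7)]
        frac, n_with, n_total = fraction_with_motif(ts, CFG)
        assert (frac, n_with, n_total) == (0.3, 3, 10)
        assert fraction_with_motif(ts[:3], CFG)[0] == 1.0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            fraction_with_motif([], CFG)

    def test_planted_fraction_recovered_exactly(self):
        spec = SimulationSpec(
            n_secretome=25,
            n_non_secretome=25,
            motif_secretome=PlantedMotifSpec(10, 14, 2, "CDS", 1.0),
            motif_non_secretome=PlantedMotifSpec(5, 9, 2, "CDS", 0.0),
            seed=3,
        )
        ts, _ = generate_transcriptome(spec)
        sec = [t for t in ts if t.is_secretome]
        non = [t for t in ts if not t.is_secretome]
        assert fraction_with_motif(sec, CFG)[0] == 1.0
        assert fraction_with_motif(non, CFG)[0] == 0.0


class TestChi2:
    def test_no_association(self):
        result = chi2_enrichment((50, 50), (50, 50))
        assert result.chi2 == 0.0 and result.p_value == 1.0

    def test_matches_closed_form_oracle(self):
        result = chi2_enrichment((90, 10), (50, 50))
        assert result.chi2 == pytest.approx(chi2_closed_form([[90, 10], [50, 50]]))
        assert result.chi2 == pytest.approx(38.0952380952, abs=1e-9)

    def test_row_swap_symmetry(self):
        a = chi2_enrichment((90, 10), (50, 50))
        b = chi2_enrichment((50, 50), (90, 10))
        assert a.chi2 == pytest.approx(b.chi2)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(50):
            t = rng.integers(1, 200, size=(2, 2))
            result = chi2_enrichment(tuple(t[0]), tuple(t[1]))
            assert result.chi2 == pytest.approx(chi2_closed_form(t), abs=1e-9)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi2_enrichment((0, 10), (0, 20))


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.02]) == pytest.approx([0.02])

    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_random_vectors_match_oracle_and_monotone(self, rng):
        for _ in range(30):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = bh_fdr(p)
            assert q == pytest.approx(bh_step_up(p), abs=1e-12)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [5, 4, 1, 0]).auc == 1.0

    def test_total_ties(self):
        assert roc_auc([1, 0, 1, 0], [2, 2, 2, 2]).auc == 0.5

    def test_hand_enumerated_example(self):
        assert roc_auc([1, 1, 0, 0], [3, 1, 2, 0]).auc == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])

    def test_curve_endpoints_and_monotone(self, rng):
        r = roc_auc(rng.integers(0, 2, 50).tolist() + [0, 1], rng.uniform(size=52))
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_matches_pairwise_oracle(self, rng):
        """AUC equals explicit Mann-Whitney pair enumeration, ties included."""
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0], labels[-1] = 0, 1
            scores = rng.integers(0, 6, size=n).astype(float)
            assert roc_auc(labels, scores).auc == pytest.approx(
                auc_pairwise(labels, scores), abs=1e-12
            )


class TestThresholdSweep:
    def test_planted_lengths_select_threshold_ten(self, small_transcriptome):
        _, transcripts, _ = small_transcriptome
        table, best = threshold_sweep(transcripts)
        assert best == 10
        assert table.loc[table.threshold == 10, "auc"].iloc[0] == 1.0

    def test_longer_plants_favor_larger_thresholds(self):
        spec = SimulationSpec(
            n_secretome=20, n_non_secretome=20,
            motif_secretome=PlantedMotifSpec(15, 15, 2, "CDS", 1.0),
            motif_non_secretome=PlantedMotifSpec(5, 9, 2, "CDS", 1.0),
            seed=5,
        )
        ts, _ = generate_transcriptome(spec)
        table, _ = threshold_sweep(ts)
        auc = dict(zip(table.threshold, table.auc))
        assert auc[15] >= auc[5]

    def test_needs_two_thresholds(self, small_transcriptome):
        _, transcripts, _ = small_transcriptome
        with pytest.raises(ValueError):
            threshold_sweep(transcripts, thresholds=(10,))


class TestLengthCorrelation:
    def test_proportional_counts(self):
        # i copies of a 12-run block: count = i, length = 39*i -> r = 1
        cfg = ScanConfig(9, "Y", {"CDS"}, {2})
        block = "AAC" * 12 + "AAA"
        ts = [Transcript(f"h{i}", block * i) for i in range(1, 6)]
        assert length_correlation(ts, cfg) == pytest.approx(1.0)

    def test_anti_proportional_counts(self):
        # count decreases linearly while length increases -> r = -1
        cfg = ScanConfig(9, "Y", {"CDS"}, {2})
        block = "AAC" * 12 + "AAA"
        ts = [
            Transcript(f"h{i}", block * (6 - i) + "AAA" * (20 * i))
            for i in range(1, 6)
        ]
        assert length_correlation(ts, cfg) == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        ts = [Transcript(f"g{i}", "AAA" * 30) for i in range(4)]
        with pytest.raises(ValueError):
            length_correlation(ts, CFG)


class TestShuffle:
    def test_single_codon_identity(self, rng):
        assert shuffle_codons("GCT", rng) == "GCT"

    def test_codon_multiset_conserved(self, rng):
        for _ in range(30):
            cds = random_dna(rng, 3 * int(rng.integers(2, 80)))
            shuffled = shuffle_codons(cds, rng)
            original = sorted(cds[i : i + 3] for i in range(0, len(cds), 3))
            after = sorted(shuffled[i : i + 3] for i in range(0, len(shuffled), 3))
            assert original == after

    def test_uniform_over_orderings(self, rng):
        """Each of the 6 orderings of 3 distinct codons is equally likely."""
        cds = "AAACCCGGG"
        counts = {}
        n = 6000
        for _ in range(n):
            counts[shuffle_codons(cds, rng)] = counts.get(shuffle_codons(cds, rng), 0) + 1
        assert len(counts) == 6
        expected = n / 6
        sigma = np.sqrt(n * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - expected) < 4 * sigma


class TestPermutation:
    def test_identical_codons_degenerate(self):
        t = Transcript("g", "GCT" * 40)
        (r,) = permutation_z(t, ScanConfig(10, "Y", {"CDS"}, {2}), n=50, seed=1)
        assert r.degenerate and r.z == 0.0

    def test_flag_permutation_equals_explicit_shuffle(self):
        """The fast path scores exactly what scanning the shuffled CDS scores."""
        t = Transcript("g", "GCTAAATACGGGTTTCCCATTAGAGAT" * 6)
        cfg = ScanConfig(3, "Y", {"CDS"}, {2})
        (r,) = permutation_z(t, cfg, statistic="max_run_length", n=40, seed=9)
        rng = gene_rng(9, "g")
        draws = [max_run_length(shuffle_codons(t.cds, rng), 2) for _ in range(40)]
        assert r.mean == pytest.approx(np.mean(draws))
        assert r.std == pytest.approx(np.std(draws))

    def test_planted_run_is_significant(self):
        rng = np.random.default_rng(17)
        purine_codons = ["AAA", "GAA", "AGA", "GGA", "AAG", "GAG"]
        body = [purine_codons[i] for i in rng.integers(0, 6, 120)]
        body[40:55] = ["TAC"] * 15  # planted 15-triplet NNY run
        t = Transcript("g", "".join(body))
        (r,) = permutation_z(t, ScanConfig(10, "Y", {"CDS"}, {2}), n=1000, seed=2)
        assert r.z >= 1.96

    def test_null_calibration(self):
        """Type-I rate of Z >= 1.96 near 2.5-5% on shuffle-null sequences."""
        spec = SimulationSpec(
            n_secretome=0, n_non_secretome=200,
            motif_non_secretome=PlantedMotifSpec(5, 9, 2, "CDS", 0.0),
            seed=23,
        )
        ts, _ = generate_transcriptome(spec)
        results = []
        for t in ts:
            null_cds = shuffle_codons(t.cds, gene_rng(77, t.gene_id))
            results.extend(
                permutation_z(
                    Transcript(t.gene_id, null_cds),
                    ScanConfig(10, "Y", {"CDS"}, {2}),
                    n=200,
                    seed=31,
                )
            )
        frac = significant_fraction(results)
        assert 0.01 <= frac <= 0.09

    def test_significant_fraction_bookkeeping(self):
        from secrete.stats import PermutationResult

        def pr(z, degenerate=False):
            return PermutationResult("g", 2, "max_run_length", 0, 0, 1, z, 10, 0, degenerate)

        assert significant_fraction([pr(0.0)] * 5) == 0.0
        assert significant_fraction([pr(3.0)] * 5) == 1.0
        mixed = [pr(3.0), pr(1.0), pr(2.5), pr(0.0, degenerate=True)]
        assert significant_fraction(mixed) == pytest.approx(2 / 3)


class TestECDF:
    def test_identical_samples(self):
        r = ecdf_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.ks_statistic == 0.0

    def test_disjoint_supports(self):
        r = ecdf_compare([10.0, 11.0], [1.0, 2.0])
        assert r.ks_statistic == 1.0

    def test_shift_detected(self, rng):
        a = rng.normal(1.0, 1.0, 300)
        b = rng.normal(0.0, 1.0, 300)
        r = ecdf_compare(a, b)
        assert r.p_value < 1e-6

    def test_ecdf_is_step_from_zero_to_one(self, rng):
        r = ecdf_compare(rng.normal(size=40), rng.normal(size=25))
        for cdf in (r.cdf_with, r.cdf_without):
            assert np.all(np.diff(cdf) >= 0)
            assert cdf[-1] == 1.0 and cdf[0] >= 0.0


class TestDistributions:
    def test_region_counts_and_density(self):
        ts = [Transcript("g", "AAC" * 40, utr5="A" * 12, utr3="A" * 12)]
        cfg = ScanConfig(10, "Y", {"CDS", "5UTR", "3UTR"}, {0, 1, 2})
        hits = [h for t in ts for h in scan_transcript(t, cfg)]
        df = region_distribution(hits, ts).set_index("region")
        assert df.loc["CDS", "count"] == 1
        assert df.loc["5UTR", "count"] == 0 and df.loc["3UTR", "count"] == 0
        assert df.loc["CDS", "density"] == pytest.approx(1 / 120)

    def test_density_normalization_arithmetic(self):
        # equal counts; CDS mean length 10x the UTR's -> UTR density 10x CDS
        from secrete.motif_core import MotifHit

        ts = [Transcript("g", "A" * 300, utr5="A" * 30)]
        hits = [
            MotifHit("g", "CDS", 2, 0, 10, "X"),
            MotifHit("g", "5UTR", 0, 0, 10, "X"),
        ]
        df = region_distribution(hits, ts).set_index("region")
        assert df.loc["5UTR", "density"] == pytest.approx(10 * df.loc["CDS", "density"])

    def test_positional_histogram_conserves_hits(self, small_transcriptome):
        _, transcripts, _ = small_transcriptome
        cfg = ScanConfig(5, "Y", {"CDS", "5UTR", "3UTR"}, {0, 1, 2})
        hits = [h for t in transcripts for h in scan_transcript(t, cfg)]
        counts = positional_distribution(hits, transcripts, n_bins=10)
        assert counts.sum() == len(hits)

    def test_positional_all_at_start(self):
        from secrete.motif_core import MotifHit

        ts = [Transcript("g", "A" * 300)]
        hits = [MotifHit("g", "CDS", 2, 0, 10, "X")] * 4
        counts = positional_distribution(hits, ts, n_bins=5)
        assert counts[0] == 4 and counts[1:].sum() == 0


class TestUTRYContent:
    def _transcriptome(self):
        ts = []
        for i in range(12):
            ts.append(Transcript(f"s{i}", "ATGTAA", utr5="CTCTCTCTGG", utr3="CT" * 10,
                                 is_secretome=True))
        for i in range(12):
            ts.append(Transcript(f"n{i}", "ATGTAA", utr5="AGAGAGAGGG", utr3="AG" * 10,
                                 is_secretome=False))
        return ts

    def test_planted_high_y_secretome_significant(self):
        df = utr_y_content_comparison(self._transcriptome()).set_index("region")
        assert df.loc["5UTR", "mean_secretome"] > df.loc["5UTR", "mean_non_secretome"]
        assert df.loc["3UTR", "p_value"] < 1e-6

    def test_identical_groups_not_significant(self):
        # both groups receive the same mix of Y contents -> t = 0, p = 1
        variants = ["CCGG", "CCCG"]
        ts = [
            Transcript(f"g{i}", "ATGTAA", utr5=variants[(i // 2) % 2],
                       utr3=variants[(i // 2) % 2], is_secretome=(i % 2 == 0))
            for i in range(20)
        ]
        df = utr_y_content_comparison(ts)
        assert (df["p_value"] > 0.99).all()

    def test_exclusion_drops_exactly_motif_bearing_genes(self):
        ts = self._transcriptome()
        # give two secretome genes a long 3'UTR motif
        for t in ts[:2]:
            t.utr3 = "C" * 36
        cfg = ScanConfig(10, "Y", {"3UTR"}, {0, 1, 2})
        df = utr_y_content_comparison(ts, cfg, exclude_secrete_utrs=True)
        row = df.set_index("region").loc["3UTR"]
        assert row["n_excluded"] == 2 and row["n_secretome"] == 10
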