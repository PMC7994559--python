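import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spikequant import (
    GenomeIndex,
    Interval,
    aggregate_signal_matrix,
    batch_adjust,
    bin_genome,
    bivalent_peak_set,
    call_broad_domains,
    classify_repeat_elements,
    compute_spikein_nf,
    enrichment_distribution,
    ks_compare,
    merge_and_intersect,
    pca_embed,
    promoter_windows,
    region_counts,
    scale_bin_counts,
)
from spikequant.chip import (
    BinMatrix,
    DegenerateInputError,
    EnrichmentDistribution,
    ScaleFactor,
    SpeciesSplitCounts,
    merge_intervals,
)
from .conftest import make_bin_matrix


def ip(target, spike, sample="ip"):
    return SpeciesSplitCounts(sample, "IP", "c", 1, target, spike)


def inp(target, spike, sample="in"):
    return SpeciesSplitCounts(sample, "input", "c", 1, target, spike)


class TestSpikeinNF:
    def test_ratio_of_ratios_formula(self):
        nf = compute_spikein_nf(ip(900_000, 100_000), inp(800_000, 200_000))
        assert nf.nf == pytest.approx(9 / 4)

    def test_equal_ratios_give_unity(self):
        nf = compute_spikein_nf(ip(500, 100), inp(1000, 200))
        assert nf.nf == pytest.approx(1.0)

    def test_zero_spike_reads_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_spikein_nf(ip(900, 0), inp(800, 200))

    @given(
        st.integers(1, 10**7), st.integers(1, 10**7),
        st.integers(1, 10**7), st.integers(1, 10**7),
        st.integers(2, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_depth_invariance(self, t1, s1, t2, s2, c):
        """Uniformly rescaling either sample's reads leaves the NF unchanged."""
        base = compute_spikein_nf(ip(t1, s1), inp(t2, s2)).nf
        scaled = compute_spikein_nf(ip(t1 * c, s1 * c), inp(t2, s2)).nf
        assert scaled == pytest.approx(base, rel=1e-12)


class TestBinGenome:
    def test_truncated_last_bin(self):
        bins = bin_genome(GenomeIndex({"chrT": 25_000}), width=10_000)
        assert [(b.start, b.end) for b in bins] == [(0, 10_000), (10_000, 20_000),
                                                    (20_000, 25_000)]

    def test_exact_multiple_single_bin(self):
        bins = bin_genome(GenomeIndex({"chrT": 10_000}), width=10_000)
        assert [(b.start, b.end) for b in bins] == [(0, 10_000)]

    @given(
        st.dictionaries(
            st.sampled_from(["c1", "c2", "c3"]), st.integers(1, 100_000),
            min_size=1, max_size=3,
        ),
        st.integers(1, 7_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_bins_tile_genome_exactly(self, sizes, width):
        genome = GenomeIndex(sizes)
        bins = bin_genome(genome, width)
        assert sum(len(b) for b in bins) == genome.total_length
        by_chrom = {}
        for b in bins:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in by_chrom.items():
            assert bs[0].start == 0 and bs[-1].end == sizes[chrom]
            for a, b in zip(bs, bs[1:]):
                assert a.end == b.start


class TestScaleBinCounts:
    def test_multiplies_by_nf(self):
        bm = make_bin_matrix(np.array([[10.0]]), columns=["s1"])
        out = scale_bin_counts(bm, [ScaleFactor("s1", 2.25)])
        assert out.counts.iloc[0, 0] == pytest.approx(22.5)
        assert out.scale_applied["s1"] == pytest.approx(2.25)

    def test_unit_factors_identity(self):
        rng = np.random.default_rng(0)
        bm = make_bin_matrix(rng.poisson(10, (20, 2)).astype(float))
        out = scale_bin_counts(bm, [ScaleFactor("s0", 1.0), ScaleFactor("s1", 1.0)])
        pd.testing.assert_frame_equal(out.counts, bm.counts)

    def test_missing_factor_is_lookup_error(self):
        bm = make_bin_matrix(np.ones((3, 2)))
        with pytest.raises(KeyError):
            scale_bin_counts(bm, [ScaleFactor("s0", 1.0)])

    def test_scaling_commutes_with_summation(self):
        """Linearity: scaling then summing equals summing then scaling."""
        rng = np.random.default_rng(1)
        values = rng.poisson(20, (50, 3)).astype(float)
        bm = make_bin_matrix(values)
        factors = [ScaleFactor(f"s{i}", f) for i, f in enumerate([0.5, 2.0, 3.3])]
        scaled = scale_bin_counts(bm, factors)
        np.testing.assert_allclose(
            scaled.counts.sum(axis=0).to_numpy(),
            values.sum(axis=0) * np.array([0.5, 2.0, 3.3]),
        )


class TestEnrichmentDistribution:
    def test_equal_signal_gives_log2_of_one_and_a_half(self):
        ip_bm = make_bin_matrix(np.full((5, 1), 7.0))
        in_bm = make_bin_matrix(np.full((5, 1), 7.0))
        dist = enrichment_distribution(ip_bm, in_bm)
        np.testing.assert_allclose(dist.values, np.log2(1.5))

    def test_zero_ip_gives_minus_one(self):
        ip_bm = make_bin_matrix(np.zeros((3, 1)))
        in_bm = make_bin_matrix(np.full((3, 1), 4.0))
        dist = enrichment_distribution(ip_bm, in_bm)
        np.testing.assert_allclose(dist.values, -1.0)

    def test_zero_input_bins_dropped_and_tallied(self):
        ip_bm = make_bin_matrix(np.array([[1.0], [2.0], [3.0]]))
        in_bm = make_bin_matrix(np.array([[1.0], [0.0], [1.0]]))
        dist = enrichment_distribution(ip_bm, in_bm)
        assert len(dist.values) == 2 and dist.n_dropped == 1

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            enrichment_distribution(
                make_bin_matrix(np.ones((3, 1))), make_bin_matrix(np.ones((4, 1)))
            )

    def test_global_loss_left_shifts_ecdf(self, small_chip_sim):
        """The r_global = 0.5 condition's enrichment ECDF is left of the control's."""
        params, splits, bins, _ = small_chip_sim
        by_cond = {}
        for cond in ("control", "treated"):
            ip_cols = [s.sample for s in splits if s.condition == cond and s.role == "IP"]
            in_cols = [s.sample for s in splits if s.condition == cond and s.role == "input"]
            factors = [
                ScaleFactor(
                    c,
                    compute_spikein_nf(
                        next(s for s in splits if s.sample == c),
                        next(s for s in splits if s.sample == c.replace("_IP", "_input")),
                    ).nf,
                )
                for c in ip_cols
            ]
            ip_bm = BinMatrix(bins=list(bins.bins), counts=bins.counts[ip_cols])
            scaled = scale_bin_counts(ip_bm, factors)
            in_bm = BinMatrix(bins=list(bins.bins), counts=bins.counts[in_cols])
            by_cond[cond] = enrichment_distribution(scaled, in_bm, label=cond)
        grid = np.linspace(-1, 3, 50)
        ecdf_t = by_cond["treated"].ecdf(grid)
        ecdf_c = by_cond["control"].ecdf(grid)
        assert np.median(by_cond["treated"].values) < np.median(by_cond["control"].values)
        assert (ecdf_t >= ecdf_c - 1e-12).mean() > 0.9  # left shift = higher ECDF


class TestKsCompare:
    def test_identical_distributions(self):
        a = EnrichmentDistribution(np.arange(10.0), "a", 0.5)
        D, p = ks_compare(a, a)
        assert D == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_disjoint_supports_give_unit_statistic(self):
        a = EnrichmentDistribution(np.array([1.0, 2, 3]), "a", 0.5)
        b = EnrichmentDistribution(np.array([10.0, 11, 12]), "b", 0.5)
        D, _ = ks_compare(a, b)
        assert D == pytest.approx(1.0)

    def test_statistic_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 37)
        y = rng.normal(0.4, 1.3, 29)
        D, _ = ks_compare(
            EnrichmentDistribution(x, "x", 0.5), EnrichmentDistribution(y, "y", 0.5)
        )
        thresholds = np.concatenate([x, y])
        gaps = [
            abs((x <= t).mean() - (y <= t).mean()) for t in thresholds
        ]
        assert D == pytest.approx(max(gaps), abs=1e-12)

    def test_empty_distribution_degenerate(self):
        a = EnrichmentDistribution(np.array([]), "a", 0.5)
        b = EnrichmentDistribution(np.array([1.0]), "b", 0.5)
        with pytest.raises(DegenerateInputError):
            ks_compare(a, b)


class TestBatchAdjust:
    def test_constant_offset_removed_exactly_without_shrinkage(self):
        rng = np.random.default_rng(5)
        base = rng.normal(5, 1, size=(60, 6))
        offset = rng.normal(2, 0.5, size=(60, 1))
        X = base.copy()
        X[:, 3:] += offset
        bm = make_bin_matrix(X)
        adj = batch_adjust(bm, ["b1"] * 3 + ["b2"] * 3, shrink=False)
        m1 = adj.counts.iloc[:, :3].mean(axis=1)
        m2 = adj.counts.iloc[:, 3:].mean(axis=1)
        assert np.abs(m1 - m2).max() < 1e-6

    def test_single_batch_identity(self):
        bm = make_bin_matrix(np.random.default_rng(6).normal(size=(10, 4)))
        adj = batch_adjust(bm, ["b"] * 4)
        pd.testing.assert_frame_equal(adj.counts, bm.counts)

    def test_singleton_batch_rejected(self):
        bm = make_bin_matrix(np.ones((5, 3)))
        with pytest.raises(DegenerateInputError):
            batch_adjust(bm, ["b1", "b1", "b2"])

    def test_condition_survives_batch_removal(self):
        """With condition effect 3x batch effect, PC1 separates condition after adjustment."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(7)
        n_feat = 300
        base = rng.normal(8, 1, size=(n_feat, 1))
        cond_effect = np.zeros((n_feat, 1))
        cond_effect[: n_feat // 3] = 1.5
        batch_effect = np.zeros((n_feat, 1))
        batch_effect[n_feat // 2 :] = 0.5
        samples, cond_labels, batch_labels = [], [], []
        for b in ("b1", "b2"):
            for cond in ("ctl", "trt"):
                for rep in range(2):
                    col = base[:, 0] + (cond == "trt") * cond_effect[:, 0] + \
                        (b == "b2") * batch_effect[:, 0] + rng.normal(0, 0.3, n_feat)
                    samples.append(col)
                    cond_labels.append(cond)
                    batch_labels.append(b)
        bm = make_bin_matrix(np.column_stack(samples))
        adj = batch_adjust(bm, batch_labels)
        coords, _ = pca_embed(adj, n_components=2)
        pc1 = coords[["PC1"]].to_numpy()
        sil_cond = silhouette_score(pc1, cond_labels)
        sil_batch = silhouette_score(pc1, batch_labels)
        assert sil_cond > sil_batch


class TestPcaEmbed:
    def test_identical_samples_at_origin(self):
        bm = make_bin_matrix(np.tile([[1.0], [2.0], [3.0]], (1, 2)))
        coords, _ = pca_embed(bm, n_components=1)
        np.testing.assert_allclose(coords["PC1"], 0.0, atol=1e-12)

    def test_variance_explained_matches_eigendecomposition(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5))  # 20 bins x 5 samples
        bm = make_bin_matrix(X)
        _, var = pca_embed(bm, n_components=4)
        centered = X.T - X.T.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centered @ centered.T))[::-1]
        np.testing.assert_allclose(var, eigvals[:4] / eigvals.sum(), rtol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        bm = make_bin_matrix(rng.normal(size=(30, 4)))
        a, _ = pca_embed(bm)
        b, _ = pca_embed(bm)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_components_rejected(self):
        bm = make_bin_matrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            pca_embed(bm, n_components=3)


class TestBroadDomains:
    def test_gap_chaining_joins_nearby_runs(self):
        rng = np.random.default_rng(10)
        n = 200
        base = rng.poisson(200, size=n).astype(float)
        ipc = rng.poisson(200, size=n).astype(float)
        ipc[50:60] = rng.poisson(900, size=10)
        ipc[62:70] = rng.poisson(900, size=8)  # gap of 2 non-significant bins
        domains = call_broad_domains(
            make_bin_matrix(ipc[:, None]), make_bin_matrix(base[:, None]), gap_bins=3
        )
        assert len(domains) == 1
        assert domains[0].start == 50 * 10_000 and domains[0].end == 70 * 10_000

    def test_all_zero_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            call_broad_domains(
                make_bin_matrix(np.ones((10, 1))), make_bin_matrix(np.zeros((10, 1)))
            )

    def test_null_background_rarely_yields_domains(self):
        """On matched homogeneous IP/input, BH keeps the family-wise rate near q."""
        from spikequant.simulate import ChipSimParams, simulate_chip_experiment

        zero_runs = 0
        n_runs = 20
        for k in range(n_runs):
            params = ChipSimParams(
                n_bins=2_000, depth=400_000, n_replicates=1, r_global=1.0,
                seed=500 + k,
            )
            _, bins, _ = simulate_chip_experiment(params)
            domains = call_broad_domains(
                BinMatrix(bins=list(bins.bins), counts=bins.counts[["control_rep1_IP"]]),
                BinMatrix(bins=list(bins.bins), counts=bins.counts[["control_rep1_input"]]),
            )
            zero_runs += len(domains) == 0
        assert zero_runs >= n_runs - 2

    def test_recovers_implanted_domain(self):
        from spikequant.simulate import ChipSimParams, simulate_chip_experiment

        params = ChipSimParams(
            n_bins=2_000, depth=1_000_000, n_replicates=1, r_global=1.0,
            domain_spec=[(400, 30, 3.0)], seed=42,
        )
        _, bins, _ = simulate_chip_experiment(params)
        domains = call_broad_domains(
            BinMatrix(bins=list(bins.bins), counts=bins.counts[["control_rep1_IP"]]),
            BinMatrix(bins=list(bins.bins), counts=bins.counts[["control_rep1_input"]]),
        )
        truth_start, truth_end = 400 * 10_000, 430 * 10_000
        inter = sum(
            max(0, min(d.end, truth_end) - max(d.start, truth_start)) for d in domains
        )
        union = (truth_end - truth_start) + sum(len(d) for d in domains) - inter
        assert inter / union >= 0.8


class TestMergeAndIntersect:
    def test_gap_of_exactly_3000_merges(self):
        merged = merge_intervals(
            [Interval("c", 100, 200), Interval("c", 3200, 3300)], 3000
        )
        assert [(m.start, m.end) for m in merged] == [(100, 3300)]

    def test_gap_of_3001_does_not_merge(self):
        merged = merge_intervals(
            [Interval("c", 100, 200), Interval("c", 3201, 3300)], 3000
        )
        assert len(merged) == 2

    def test_identical_replicates_yield_merged_set(self):
        peaks = [Interval("c", 0, 500), Interval("c", 2000, 2500),
                 Interval("c", 9000, 9500)]
        out = merge_and_intersect(peaks, peaks, merge_distance=3000)
        assert [(m.start, m.end) for m in out] == [(0, 2500), (9000, 9500)]

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(11)
        starts = rng.integers(0, 100_000, 30)
        peaks = [Interval("c", int(s), int(s) + 100) for s in starts]
        rev = list(reversed(peaks))
        once = merge_and_intersect(peaks, rev)
        twice = merge_and_intersect(once, once)
        assert [(m.start, m.end) for m in once] == [(m.start, m.end) for m in twice]
        for a, b in zip(once, once[1:]):
            assert a.end < b.start  # sorted and disjoint


class TestRegionCounts:
    def test_exact_bin_region(self):
        bm = make_bin_matrix(np.array([[4.0], [8.0]]))
        table = region_counts(bm, [Interval("chrT", 10_000, 20_000)])
        assert table.iloc[0, 0] == pytest.approx(8.0)

    def test_half_bin_overlap_weighting(self):
        bm = make_bin_matrix(np.array([[4.0]]))
        table = region_counts(bm, [Interval("chrT", 0, 5_000)])
        assert table.iloc[0, 0] == pytest.approx(2.0)

    def test_tiling_conserves_total_signal(self):
        rng = np.random.default_rng(12)
        values = rng.gamma(3, 2, size=(40, 2))
        bm = make_bin_matrix(values)
        tiling = [Interval("chrT", s, s + 16_000) for s in range(0, 400_000, 16_000)]
        table = region_counts(bm, tiling)
        np.testing.assert_allclose(
            table.sum(axis=0).to_numpy(), values.sum(axis=0), rtol=1e-9
        )

    def test_unknown_chromosome_is_lookup_error(self):
        bm = make_bin_matrix(np.ones((3, 1)))
        with pytest.raises(KeyError):
            region_counts(bm, [Interval("chrZ", 0, 100)])


class TestPromoterWindows:
    def test_plus_strand_extension(self):
        (w,) = promoter_windows(
            [Interval("c", 50_000, 50_001, strand="+")], 10_000, 1_000
        )
        assert (w.start, w.end) == (40_000, 51_001)

    def test_minus_strand_mirror(self):
        (w,) = promoter_windows(
            [Interval("c", 50_000, 50_001, strand="-")], 10_000, 1_000
        )
        # mirror of the plus-strand window: same 11001 bp length
        assert (w.start, w.end) == (49_000, 60_001)
        assert len(w) == 11_001

    def test_clamped_at_chromosome_start(self):
        (w,) = promoter_windows(
            [Interval("c", 5_000, 5_001, strand="+")], 10_000, 1_000,
            genome=GenomeIndex({"c": 100_000}),
        )
        assert w.start == 0


class TestBivalentPeakSet:
    def test_peak_overlapping_two_windows_reported_once(self):
        tss = [Interval("c", 10_000, 10_001, strand="+"),
               Interval("c", 10_500, 10_501, strand="+")]
        peaks = [Interval("c", 9_000, 11_000)]
        assert len(bivalent_peak_set(tss, peaks)) == 1

    def test_no_overlap_empty(self):
        tss = [Interval("c", 100_000, 100_001, strand="+")]
        peaks = [Interval("c", 0, 1_000)]
        assert bivalent_peak_set(tss, peaks) == []

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(13)
        tss = [
            Interval("c", int(p), int(p) + 1, strand=rng.choice(["+", "-"]))
            for p in rng.integers(2_000, 500_000, 40)
        ]
        peaks = [
            Interval("c", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 500_000, 60), rng.integers(200, 5_000, 60))
        ]
        windows = promoter_windows(tss, 1_000, 100)
        expected = sorted(
            {
                (p.chrom, p.start, p.end)
                for p in peaks
                for w in windows
                if p.overlaps(w)
            }
        )
        got = [(p.chrom, p.start, p.end) for p in bivalent_peak_set(tss, peaks)]
        assert got == expected


class TestRepeatClassification:
    @pytest.mark.parametrize(
        "high,ctrl,expected",
        [
            (6.0, 2.0, "hyper"),   # log2 = 1.585 > 0.7 and high > 5
            (2.0, 6.0, "hypo"),    # log2 = -1.585 and high < 3
            (6.0, 5.0, "neither"),  # |log2| = 0.263
            (4.0, 1.0, "neither"),  # strong ratio but high <= 5
        ],
    )
    def test_threshold_rules(self, high, ctrl, expected):
        calls, _ = classify_repeat_elements(
            pd.Series([high], index=["e1"]), pd.Series([ctrl], index=["e1"])
        )
        assert calls[0].call == expected

    def test_zero_control_excluded_with_tally(self):
        calls, n_excluded = classify_repeat_elements(
            pd.Series([6.0, 3.0], index=["e1", "e2"]),
            pd.Series([0.0, 3.0], index=["e1", "e2"]),
        )
        assert n_excluded == 1 and len(calls) == 1

    def test_classes_partition_all_elements(self):
        rng = np.random.default_rng(14)
        high = pd.Series(rng.gamma(2, 3, 200))
        ctrl = pd.Series(rng.gamma(2, 3, 200) + 0.01)
        calls, n_excluded = classify_repeat_elements(high, ctrl)
        assert len(calls) + n_excluded == 200
        assert all(c.call in ("hyper", "hypo", "neither") for c in calls)


class TestAggregateSignalMatrix:
    def test_uniform_signal_flat_profile(self):
        bm = make_bin_matrix(np.full((50, 1), 3.0))
        regions = [Interval("chrT", 200_000, 250_000)]
        _, profile = aggregate_signal_matrix(bm, regions, flank=50_000)
        np.testing.assert_allclose(profile, 3.0)

    def test_single_region_profile_equals_row(self):
        rng = np.random.default_rng(15)
        bm = make_bin_matrix(rng.gamma(2, 2, size=(50, 1)))
        regions = [Interval("chrT", 200_000, 210_000)]
        matrix, profile = aggregate_signal_matrix(bm, regions, flank=30_000)
        np.testing.assert_allclose(matrix.iloc[0].to_numpy(), profile)

    def test_minus_strand_reverses_positions(self):
        values = np.arange(50, dtype=float)[:, None]
        bm = make_bin_matrix(values)
        plus = [Interval("chrT", 200_000, 210_000, strand="+")]
        minus = [Interval("chrT", 200_000, 210_000, strand="-")]
        m_plus, _ = aggregate_signal_matrix(bm, plus, flank=30_000)
        m_minus, _ = aggregate_signal_matrix(bm, minus, flank=30_000)
        # the minus-strand anchor is the region end; mirroring the signal around
        # the anchor and reversing must reproduce the plus-strand view
        mirrored = make_bin_matrix(values[::-1])
        anchor_flipped = [
            Interval("chrT", 500_000 - 210_000, 500_000 - 200_000, strand="+")
        ]
        m_expected, _ = aggregate_signal_matrix(mirrored, anchor_flipped, flank=30_000)
        np.testing.assert_allclose(
            m_minus.to_numpy()[0], m_expected.to_numpy()[0]
        )

    def test_flank_beyond_chromosome_marks_missing(self):
        bm = make_bin_matrix(np.full((5, 1), 2.0))
        matrix, _ = aggregate_signal_matrix(
            bm, [Interval("chrT", 0, 10_000)], flank=30_000
        )
        assert matrix.iloc[0].isna().any()
        matrix_zero, _ = aggregate_signal_matrix(
            bm, [Interval("chrT", 0, 10_000)], flank=30_000, missing_as_zero=True
        )
        assert not matrix_zero.iloc[0].isna().any()
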