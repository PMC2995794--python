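"""Two-class SNR statistic, regularization, and the permutation FDR
threshold."""

import numpy as np
import pytest

from kcscan import (AberrationSpec, ClassLabels, GenomeLayout, KernelSpec,
                    build_sample_points, call_differential_regions,
                    compare_classes, generate_dataset, per_sample_kc,
                    pooled_sd, regularization_factor, snr_fdr_threshold,
                    snr_statistic)
from oracles import (enumerate_label_permutation_threshold, naive_pooled_sd,
                     naive_snr)


LAB4 = ClassLabels((1, 1, 2, 2))


class TestClassLabels:
    def test_group_sizes(self):
        l = ClassLabels((1, 2, 1, 2, 2))
        assert l.n1 == 2 and l.n2 == 3

    @pytest.mark.parametrize("labels", [(1, 1, 1, 2), (1, 1), (1, 1, 3, 2, 2)])
    def test_invalid_labelings_rejected(self, labels):
        with pytest.raises(ValueError):
            ClassLabels(labels)

    def test_from_file_mismatch_lists_ids(self, tmp_path):
        p = tmp_path / "lab.tsv"
        p.write_text("S1\t1\nS2\t1\nS3\t2\nS9\t2\n")
        with pytest.raises(ValueError, match="S9"):
            ClassLabels.from_file(p, ("S1", "S2", "S3", "S4"))


class TestPooledSd:
    def test_hand_computed_two_by_two(self):
        profiles = np.array([[0.0], [2.0], [1.0], [3.0]])
        assert pooled_sd(profiles, LAB4)[0] == pytest.approx(np.sqrt(2.0))

    def test_internally_constant_groups_give_zero(self):
        profiles = np.array([[5.0, 1.0]] * 2 + [[2.0, 0.0]] * 2)
        np.testing.assert_array_equal(pooled_sd(profiles, LAB4), [0.0, 0.0])

    def test_label_swap_invariance(self, rng):
        profiles = rng.normal(size=(6, 20))
        a = pooled_sd(profiles, ClassLabels((1, 1, 1, 2, 2, 2)))
        b = pooled_sd(profiles, ClassLabels((2, 2, 2, 1, 1, 1)))
        np.testing.assert_allclose(a, b)

    def test_matches_naive_loop(self, rng):
        profiles = rng.normal(size=(7, 15))
        labels = ClassLabels((1, 1, 2, 1, 2, 2, 2))
        np.testing.assert_allclose(pooled_sd(profiles, labels),
                                   naive_pooled_sd(profiles, labels.labels),
                                   rtol=1e-12)


class TestRegularizationFactor:
    def test_constant_groups_give_zero_f(self):
        profiles = np.array([[1.0, 2.0]] * 2 + [[0.0, 5.0]] * 2)
        assert regularization_factor(profiles, LAB4) == 0.0

    def test_type7_quantile_on_explicit_vector(self, rng):
        # pooled_sd vector 1..100 -> 95th percentile 95.05 under linear
        # interpolation; build profiles whose pooled SD is exactly 1..100.
        base = rng.normal(size=(4, 100))
        sd = pooled_sd(base, LAB4)
        profiles = base / sd * np.arange(1.0, 101.0)
        np.testing.assert_allclose(pooled_sd(profiles, LAB4),
                                   np.arange(1.0, 101.0), rtol=1e-10)
        assert regularization_factor(profiles, LAB4) == pytest.approx(95.05)

    def test_invariant_to_point_reordering(self, rng):
        profiles = rng.normal(size=(4, 50))
        perm = rng.permutation(50)
        assert regularization_factor(profiles, LAB4) == pytest.approx(
            regularization_factor(profiles[:, perm], LAB4))


class TestSnrStatistic:
    def test_equal_group_means_give_zero(self, rng):
        block = rng.normal(size=(2, 30))
        profiles = np.vstack([block, block])
        np.testing.assert_allclose(
            snr_statistic(profiles, LAB4, 1.0), 0.0, atol=1e-14)

    def test_label_swap_negates(self, rng):
        profiles = rng.normal(size=(6, 25))
        a = snr_statistic(profiles, ClassLabels((1, 1, 1, 2, 2, 2)), 0.3)
        b = snr_statistic(profiles, ClassLabels((2, 2, 2, 1, 1, 1)), 0.3)
        np.testing.assert_allclose(a, -b, rtol=1e-12)

    def test_direct_formula_with_zero_pooled_sd(self):
        profiles = np.vstack([np.ones((2, 10)), np.zeros((2, 10))])
        np.testing.assert_allclose(
            snr_statistic(profiles, LAB4, 0.5), 2.0)

    def test_zero_denominator_instructs_nonzero_f(self):
        profiles = np.vstack([np.ones((2, 5)), np.zeros((2, 5))])
        with pytest.raises(ValueError, match="regularization"):
            snr_statistic(profiles, LAB4, 0.0)


class TestSnrFdrThreshold:
    def test_identity_between_stored_fields(self, rng):
        profiles = rng.normal(size=(8, 60))
        labels = ClassLabels((1,) * 4 + (2,) * 4)
        thr, res = snr_fdr_threshold(profiles, labels, 0.2, n_perms=30, seed=6)
        np.testing.assert_allclose(
            res.snr, (res.mu1 - res.mu2) / (res.pooled_sd + res.f), rtol=1e-14)
        snr_ref, f_ref = naive_snr(profiles, labels.labels)
        assert res.f == pytest.approx(f_ref)
        np.testing.assert_allclose(res.snr, snr_ref, rtol=1e-12)

    def test_matches_independent_seeded_enumeration(self, rng):
        profiles = rng.normal(size=(6, 50))
        profiles[:3, 10:14] += 2.5  # a genuine class difference
        labels = ClassLabels((1, 1, 1, 2, 2, 2))
        thr, _ = snr_fdr_threshold(profiles, labels, 0.25, n_perms=20, seed=13)
        expect = enumerate_label_permutation_threshold(
            profiles, labels.labels, 0.25, n_perms=20, seed=13)
        assert thr == pytest.approx(expect, rel=1e-12)

    def test_loose_target_calls_every_point(self, rng):
        profiles = rng.normal(size=(8, 40))
        profiles[:4] += 5.0  # huge shift everywhere
        labels = ClassLabels((1,) * 4 + (2,) * 4)
        thr, res = snr_fdr_threshold(profiles, labels, 0.99, n_perms=20, seed=2)
        assert thr == pytest.approx(np.abs(res.snr).min())
        assert np.all(np.abs(res.snr) >= thr)

    def test_degenerate_data_yields_infinite_threshold(self):
        profiles = np.tile(np.linspace(0, 1, 30), (8, 1))
        labels = ClassLabels((1,) * 4 + (2,) * 4)
        thr, res = snr_fdr_threshold(profiles, labels, 0.05, n_perms=20, seed=0)
        assert np.isinf(thr)
        assert np.all(res.null_exceedance == 0)

    def test_label_swap_leaves_threshold_unchanged_and_swaps_channels(self):
        layout = GenomeLayout(("c",), (10_000_000,))
        grid = build_sample_points(layout, 100_000)
        ds = generate_dataset(
            layout, 5, 5, n_probes_per_chrom=200, noise_sd=0.2,
            specs=[AberrationSpec("c", 3_000_000, 4_000_000, -1.0,
                                  1.0, "class1")], seed=21)
        profiles = per_sample_kc(ds.probes, grid, KernelSpec(300_000))
        labels = ds.labels
        swapped = ClassLabels(tuple(3 - l for l in labels.labels))
        thr_a, res_a = snr_fdr_threshold(profiles, labels, 0.05,
                                         n_perms=50, seed=8, grid=grid)
        thr_b, res_b = snr_fdr_threshold(profiles, swapped, 0.05,
                                         n_perms=50, seed=8, grid=grid)
        assert thr_a == pytest.approx(thr_b, rel=1e-12)
        np.testing.assert_allclose(res_a.snr, -res_b.snr, rtol=1e-12)
        down_a = res_a.regions.by_channel("diff_down")
        up_b = res_b.regions.by_channel("diff_up")
        assert [(r.start_bp, r.end_bp) for r in down_a] == \
               [(r.start_bp, r.end_bp) for r in up_b]

    def test_shift_and_scale_invariance(self, rng):
        profiles = rng.normal(size=(8, 40))
        profiles[:4, 5:9] += 1.5
        labels = ClassLabels((1,) * 4 + (2,) * 4)
        thr0, res0 = snr_fdr_threshold(profiles, labels, 0.2, n_perms=25, seed=3)
        thr1, res1 = snr_fdr_threshold(profiles + 7.0, labels, 0.2,
                                       n_perms=25, seed=3)
        thr2, res2 = snr_fdr_threshold(profiles * 3.0, labels, 0.2,
                                       n_perms=25, seed=3)
        np.testing.assert_allclose(res0.snr, res1.snr, rtol=1e-10)
        np.testing.assert_allclose(res0.snr, res2.snr, rtol=1e-10)
        assert thr0 == pytest.approx(thr1, rel=1e-10)
        assert thr0 == pytest.approx(thr2, rel=1e-10)


class TestCallDifferentialRegions:
    def test_hand_traced_runs(self):
        layout = GenomeLayout(("c",), (500_000,))
        grid = build_sample_points(layout, 100_000)
        labels = ClassLabels((1, 1, 2, 2))
        res_stub = type("R", (), {})()
        res_stub.snr = np.array([0.0, 3.0, 3.0, -3.0, 0.0])
        res_stub.thr = 2.0
        rs = call_differential_regions(res_stub, grid)
        up = rs.by_channel("diff_up")
        down = rs.by_channel("diff_down")
        assert len(up) == 1 and up[0].n_points == 2 and up[0].score == 3.0
        assert len(down) == 1 and down[0].n_points == 1 and down[0].score == -3.0

    def test_infinite_threshold_calls_nothing(self, grid):
        res_stub = type("R", (), {})()
        res_stub.snr = np.ones(grid.n_points)
        res_stub.thr = np.inf
        assert len(call_differential_regions(res_stub, grid)) == 0

    def test_channels_never_overlap(self, grid, rng):
        res_stub = type("R", (), {})()
        res_stub.snr = rng.normal(size=grid.n_points)
        res_stub.thr = 0.5
        rs = call_differential_regions(res_stub, grid)
        for u in rs.by_channel("diff_up"):
            for d in rs.by_channel("diff_down"):
                if u.chrom == d.chrom:
                    assert u.end_bp <= d.start_bp or d.end_bp <= u.start_bp


class TestCompareClasses:
    def test_class_specific_deletion_called_diff_down(self):
        layout = GenomeLayout(("c1", "c2"), (20_000_000, 20_000_000))
        grid = build_sample_points(layout, 50_000)
        ds = generate_dataset(
            layout, 10, 10, n_probes_per_chrom=800, noise_sd=0.3,
            specs=[AberrationSpec("c1", 8_000_000, 9_000_000, -1.0,
                                  1.0, "class1")], seed=3)
        res = compare_classes(ds.probes, ds.labels, grid, KernelSpec(200_000),
                              fdr_target=0.05, n_perms=100, seed=4)
        down = res.regions.by_channel("diff_down")
        assert any(r.chrom == "c1" and r.start_bp < 9_000_000
                   and r.end_bp > 8_000_000 for r in down)
        up = res.regions.by_channel("diff_up")
        assert not any(r.chrom == "c1" and r.start_bp < 9_000_000
                       and r.end_bp > 8_000_000 for r in up)
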