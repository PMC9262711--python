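"""Window estimators against brute-force oracles, masking semantics,
window tiling, PCA and RI assignment."""

import numpy as np
import pandas as pd
import pytest

from hetri.popgen import (
    CallabilityMask,
    GroupAssignment,
    VariantMatrix,
    WindowSpec,
    assign_ri_from_pc1,
    fst_dxy_window,
    fst_permutation_null,
    mask_sites,
    pca_snps,
    pi_window,
    tajimas_d_window,
    theta_w_window,
    window_scan,
)
from hetri.synthetic import TwoGroupParams, generate_two_group_snps

from conftest import random_matrix
from oracles import (
    bf_dxy_total,
    bf_harmonic,
    bf_hudson_fst,
    bf_pi_total,
    bf_tajimas_d,
    bf_theta_w_total,
)


def matrix_from_rows(rows, length=100, samples=None):
    gt = np.asarray(rows, dtype=np.int8)
    pos = np.arange(1, gt.shape[0] + 1) * 10
    samples = samples or [f"s{i}" for i in range(gt.shape[1])]
    return VariantMatrix(
        samples=samples,
        chrom_lengths={"chr1": length},
        positions={"chr1": pos},
        genotypes={"chr1": gt},
    )


class TestWorkedExamples:
    def test_pi_single_difference(self):
        vm = matrix_from_rows([[0, 1]], length=10_000)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        assert pi_window(vm, mask, "chr1", 1, 10_000) == pytest.approx(1e-4)

    def test_pi_four_haplotypes(self):
        # sites (derived counts 2, 1, 1): mean pairwise difference 10/6
        rows = [[0, 1, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        vm = matrix_from_rows(rows, length=100)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        assert pi_window(vm, mask, "chr1", 1, 100) == pytest.approx(
            (10 / 6) / 100
        )

    def test_theta_w_examples(self):
        rows = [[0, 1, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        vm = matrix_from_rows(rows, length=1000)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        expected = 3 / (bf_harmonic(4) * 1000)  # 1.6364e-3
        assert theta_w_window(vm, mask, "chr1", 1, 1000) == pytest.approx(
            expected, rel=1e-9
        )
        # n=2: a_n = 1 so thetaW = S / L_eff
        vm2 = matrix_from_rows([[0, 1], [1, 0]], length=1000)
        assert theta_w_window(
            vm2, CallabilityMask.all_usable(vm2.chrom_lengths), "chr1", 1, 1000
        ) == pytest.approx(2 / 1000)

    def test_tajimas_d_worked_example(self):
        """Four haplotypes over three sites give D close to +0.17 (value
        frozen from the independent constant transcription in oracles)."""
        rows = [[0, 1, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        gt = np.asarray(rows, dtype=np.int8)
        oracle = bf_tajimas_d(gt)
        assert oracle == pytest.approx(0.1676, abs=5e-3)
        vm = matrix_from_rows(rows, length=100)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        assert tajimas_d_window(vm, mask, "chr1", 1, 100) == pytest.approx(
            oracle, rel=1e-10
        )

    def test_tajimas_d_sign_conventions(self):
        # singleton-only data: excess rare variants, D < 0
        singles = np.zeros((10, 8), dtype=np.int8)
        for i in range(10):
            singles[i, i % 8] = 1
        vm = matrix_from_rows(singles, length=200)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        assert tajimas_d_window(vm, mask, "chr1", 1, 200) < 0
        # balanced intermediate-frequency sites: D > 0
        balanced = np.tile([0, 0, 0, 0, 1, 1, 1, 1], (5, 1)).astype(np.int8)
        vm2 = matrix_from_rows(balanced, length=200)
        assert tajimas_d_window(
            vm2, CallabilityMask.all_usable(vm2.chrom_lengths), "chr1", 1, 200
        ) > 0

    def test_dxy_half_frequencies(self):
        rows = [[0, 1, 0, 1]]  # p1 = p2 = 0.5
        vm = matrix_from_rows(rows, length=1000)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        groups = GroupAssignment(
            {"s0": "rV-group", "s1": "rV-group", "s2": "RV1-group", "s3": "RV1-group"}
        )
        _, dxy = fst_dxy_window(vm, mask, "chr1", 1, 1000, groups)
        assert dxy == pytest.approx(0.5e-3)

    def test_fst_fixed_differences(self):
        rows = [[0, 0, 1, 1]] * 5
        vm = matrix_from_rows(rows, length=1000)
        mask = CallabilityMask.all_usable(vm.chrom_lengths)
        groups = GroupAssignment(
            {"s0": "rV-group", "s1": "rV-group", "s2": "RV1-group", "s3": "RV1-group"}
        )
        fst, dxy = fst_dxy_window(vm, mask, "chr1", 1, 1000, groups)
        assert fst == pytest.approx(1.0)
        assert dxy == pytest.approx(5 / 1000)


class TestEstimatorOracles:
    def test_brute_force_agreement_random_matrices(self, rng):
        """pi, thetaW, D, Hudson Fst and Dxy match the brute-force
        definitions to 1e-10 relative tolerance on random small matrices."""
        for rep in range(100):
            n = int(rng.integers(4, 7))
            sites = int(rng.integers(5, 200))
            missing = 0.0 if rep % 2 == 0 else 0.1
            vm = random_matrix(rng, n, sites, length=5000, missing_rate=missing)
            mask = CallabilityMask.all_usable(vm.chrom_lengths)
            gt = vm.genotypes["chr1"]
            assert pi_window(vm, mask, "chr1", 1, 5000) == pytest.approx(
                bf_pi_total(gt) / 5000, rel=1e-10, abs=1e-15
            )
            assert theta_w_window(vm, mask, "chr1", 1, 5000) == pytest.approx(
                bf_theta_w_total(gt) / 5000, rel=1e-10, abs=1e-15
            )
            if missing == 0.0:
                d = tajimas_d_window(vm, mask, "chr1", 1, 5000)
                bf = bf_tajimas_d(gt)
                if np.isnan(bf):
                    assert np.isnan(d)
                else:
                    assert d == pytest.approx(bf, rel=1e-10)
            half = n // 2
            groups = GroupAssignment(
                {
                    f"s{i}": ("rV-group" if i < half else "RV1-group")
                    for i in range(n)
                }
            )
            fst, dxy = fst_dxy_window(vm, mask, "chr1", 1, 5000, groups)
            g1, g2 = list(range(half)), list(range(half, n))
            assert dxy == pytest.approx(
                bf_dxy_total(gt, g1, g2) / 5000, rel=1e-10, abs=1e-15
            )
            bf = bf_hudson_fst(gt, g1, g2)
            if np.isnan(bf):
                assert np.isnan(fst)
            else:
                assert fst == pytest.approx(bf, rel=1e-10, abs=1e-12)


class TestMaskingSemantics:
    def test_fully_masked_sites_change_nothing(self, rng):
        """Adding sites inside masked intervals never changes pi/thetaW."""
        vm = random_matrix(rng, 5, 40, length=10_000)
        mask = CallabilityMask.from_intervals(
            {"chr1": 10_000}, {"chr1": [(6000, 7000)]}
        )
        base_pi = pi_window(vm, mask, "chr1", 1, 10_000)
        base_tw = theta_w_window(vm, mask, "chr1", 1, 10_000)
        # inject extra sites at masked positions
        extra_pos = np.arange(6001, 6021)
        extra_gt = rng.integers(0, 2, size=(20, 5)).astype(np.int8)
        pos = np.concatenate([vm.positions["chr1"], extra_pos])
        gt = np.concatenate([vm.genotypes["chr1"], extra_gt])
        order = np.argsort(pos)
        vm2 = VariantMatrix(
            samples=vm.samples,
            chrom_lengths=vm.chrom_lengths,
            positions={"chr1": pos[order]},
            genotypes={"chr1": gt[order]},
        )
        assert pi_window(vm2, mask, "chr1", 1, 10_000) == base_pi
        assert theta_w_window(vm2, mask, "chr1", 1, 10_000) == base_tw

    def test_low_effective_length_reported_missing(self, rng):
        """Windows with effective length below 5 kb are NaN in the scan."""
        vm = random_matrix(rng, 4, 30, length=10_000)
        mask = CallabilityMask.from_intervals(
            {"chr1": 10_000}, {"chr1": [(0, 6000)]}
        )
        df = window_scan(vm, mask, WindowSpec(10_000, 10_000, 5_000))
        assert df.loc[0, "l_eff"] == 4000
        assert np.isnan(df.loc[0, "pi"])
        assert np.isnan(df.loc[0, "theta_w"])

    def test_all_sites_masked_window_missing(self, rng):
        vm = random_matrix(rng, 4, 10, length=2000)
        mask = CallabilityMask.from_intervals({"chr1": 2000}, {"chr1": [(0, 2000)]})
        assert np.isnan(pi_window(vm, mask, "chr1", 1, 2000))

    def test_constant_coverage_masks_nothing(self):
        cov = {"a": {"chr1": np.full(1000, 30)}, "b": {"chr1": np.full(1000, 30)}}
        mask = mask_sites(cov, {"chr1": [(0, 1000)]}, {"chr1": 1000})
        assert mask.usable["chr1"].all()

    def test_repeat_with_normal_coverage_in_one_sample_not_masked(self, rng):
        length = 10_000
        base = rng.poisson(40, size=length)
        spike = base.copy()
        spike[5000:5100] = 500
        cov = {
            "bad1": {"chr1": spike},
            "bad2": {"chr1": spike.copy()},
            # constant coverage: strict quantile rule flags nothing
            "fine": {"chr1": np.full(length, 40)},
        }
        mask = mask_sites(cov, {"chr1": [(5000, 5100)]}, {"chr1": length})
        assert mask.usable["chr1"][5000:5100].all()  # intersection fails

    def test_quantile_bounds_validated(self):
        with pytest.raises(ValueError):
            mask_sites({"a": {"chr1": np.ones(10)}}, {}, {"chr1": 10}, low_q=0.0)
        with pytest.raises(ValueError):
            mask_sites({}, {}, {"chr1": 10})


class TestWindowTiling:
    def test_interior_positions_covered_ten_times(self):
        spec = WindowSpec(10_000, 1_000, 5_000)
        length = 50_000
        coverage = np.zeros(length + 1)
        for start in spec.starts(length):
            end = min(start + spec.length - 1, length)
            coverage[start : end + 1] += 1
        interior = coverage[10_000:40_001]
        assert (interior == 10).all()

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(1000, 2000)


class TestPermutationNull:
    def test_planted_island_extreme_p(self):
        params = TwoGroupParams(
            n_per_group=(10, 10),
            chrom_lengths={"chr5": 60_000},
            island_chrom="chr5",
            island_span=(20_001, 30_000),
            island_n_sites=60,
            island2_chrom=None,
            seed=2,
        )
        vm, labels = generate_two_group_snps(params)
        groups = GroupAssignment(labels)
        df = window_scan(
            vm, None, WindowSpec(10_000, 10_000, 5_000), groups=groups,
            n_perm=1000, seed=3,
        )
        island = df[(df.start == 20_001)]
        assert island["fst"].iloc[0] == pytest.approx(1.0)
        assert island["p_perm"].iloc[0] == pytest.approx(1 / 1001)

    def test_null_p_values_roughly_uniform(self, rng):
        """Random labels give permutation p-values with no excess of small
        values (calibration of the one-sided empirical p)."""
        vm = random_matrix(rng, 10, 300, length=50_000)
        groups = GroupAssignment(
            {f"s{i}": ("rV-group" if i < 5 else "RV1-group") for i in range(10)}
        )
        df = window_scan(
            vm, None, WindowSpec(10_000, 10_000, 5_000), groups=groups,
            n_perm=200, seed=4,
        )
        p = df["p_perm"].dropna()
        assert (p < 0.05).mean() < 0.3

    def test_zero_permutations_rejected(self, rng):
        vm = random_matrix(rng, 4, 10, length=10_000)
        groups = GroupAssignment(
            {f"s{i}": ("rV-group" if i < 2 else "RV1-group") for i in range(4)}
        )
        with pytest.raises(ValueError):
            fst_permutation_null(vm, None, WindowSpec(), groups, n_perm=0)


class TestPca:
    def test_planted_groups_separate_on_pc1(self):
        params = TwoGroupParams(seed=9)
        vm, labels = generate_two_group_snps(params)
        scores, varfrac = pca_snps(vm, scope="chr5")
        side = scores["PC1"] > 0
        truth = pd.Series({s: labels[s] == "rV-group" for s in scores.index})
        agree = (side == truth).mean()
        assert agree in (0.0, 1.0)  # perfect separation up to sign
        assert varfrac[0] > 0.3

    def test_background_chromosome_uninformative(self):
        params = TwoGroupParams(seed=9, island2_chrom=None)
        vm, labels = generate_two_group_snps(params)
        scores, _ = pca_snps(vm, scope="chr2")
        truth = np.array([1.0 if labels[s] == "rV-group" else 0.0 for s in scores.index])
        r = np.corrcoef(scores["PC1"], truth)[0, 1]
        assert abs(r) < 0.5

    def test_duplicate_samples_identical_scores(self, rng):
        vm = random_matrix(rng, 6, 50, length=5000)
        vm.genotypes["chr1"][:, 1] = vm.genotypes["chr1"][:, 0]
        scores, _ = pca_snps(vm, maf_min=0.0)
        assert np.allclose(scores.iloc[0], scores.iloc[1])

    def test_no_passing_sites_error(self, rng):
        vm = random_matrix(rng, 4, 5, length=1000)
        vm.genotypes["chr1"][:] = 0
        with pytest.raises(ValueError):
            pca_snps(vm)


class TestRiAssignment:
    def test_anchored_assignment_and_sign_invariance(self):
        pc1 = {f"a{i}": -2.0 - i for i in range(5)}
        pc1.update({f"b{i}": 2.0 + i for i in range(5)})
        anchors = {"a0": "rV-group", "b0": "RV1-group"}
        assign = assign_ri_from_pc1(pc1, anchors)
        assert all(assign.labels[f"a{i}"] == "rV-group" for i in range(5))
        assert all(assign.labels[f"b{i}"] == "RV1-group" for i in range(5))
        flipped = assign_ri_from_pc1({k: -v for k, v in pc1.items()}, anchors)
        assert flipped.labels == assign.labels

    def test_zero_score_unassigned(self):
        pc1 = {"a": -1.0, "b": 1.0, "c": 0.0}
        assign = assign_ri_from_pc1(pc1, {"a": "rV-group", "b": "RV1-group"})
        assert assign.labels["c"] == "unassigned"

    def test_single_label_anchors_rejected(self):
        with pytest.raises(ValueError):
            assign_ri_from_pc1({"a": 1.0}, {"a": "rV-group"})
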