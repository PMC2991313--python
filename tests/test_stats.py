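"""Voxel-wise statistics: t-maps, FDR/FWE corrections, clusters."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from autorad3d.core import Volume
from autorad3d.phantom import PhantomSpec, make_group_study
from autorad3d.stats import (
    GroupData,
    bonferroni,
    cluster_filter,
    fdr_bh,
    fwe_permutation_maxt,
    smooth_group,
    voxelwise_ttest,
)

VOX = (10.0, 10.0, 20.0)


def group_from_arrays(a_stack, b_stack, mask=None):
    vols = [Volume(v, VOX) for v in a_stack] + [Volume(v, VOX) for v in b_stack]
    labels = ["A"] * len(a_stack) + ["B"] * len(b_stack)
    return GroupData(vols, labels, analysis_mask=mask)


class TestVoxelwiseTTest:
    def test_hand_computed_pooled_t(self):
        # A = {10,12,11}, B = {14,15,16}: means 11 and 15, pooled s^2 = 1,
        # t = 4 / sqrt(2/3) = 4.898979..., df = 4 (long-hand oracle)
        a = np.array([10.0, 12.0, 11.0]).reshape(3, 1, 1, 1)
        b = np.array([14.0, 15.0, 16.0]).reshape(3, 1, 1, 1)
        maps = group_from_arrays(a, b)
        out = voxelwise_ttest(maps)
        assert out.t_map.ravel()[0] == pytest.approx(4.898979485566356, abs=1e-12)
        assert out.df == 4

    def test_matches_scipy_ttest_ind(self, rng):
        a = rng.normal(10, 2, (4, 6, 5, 3))
        b = rng.normal(11, 2, (5, 6, 5, 3))
        out = voxelwise_ttest(group_from_arrays(a, b))
        t_ref, p_ref = sps.ttest_ind(b, a, axis=0, equal_var=True)
        assert np.allclose(out.t_map, t_ref, atol=1e-12)
        assert np.allclose(out.p_two_sided, p_ref, atol=1e-12)

    def test_identical_groups_give_null_maps(self, rng):
        a = rng.normal(10, 2, (3, 4, 4, 2))
        out = voxelwise_ttest(group_from_arrays(a, a.copy()))
        assert np.allclose(out.t_map, 0.0)
        assert np.allclose(out.p_pos, 0.5)
        assert np.allclose(out.p_neg, 0.5)

    def test_constant_voxel_lands_in_degenerate_set(self, rng):
        a = rng.normal(10, 2, (3, 4, 4, 2))
        b = rng.normal(10, 2, (3, 4, 4, 2))
        a[:, 0, 0, 0] = b[:, 0, 0, 0] = 7.0
        out = voxelwise_ttest(group_from_arrays(a, b))
        assert out.degenerate_mask[0, 0, 0]
        assert not out.analysis_mask[0, 0, 0]

    def test_label_exchange_negates_t_and_swaps_p(self, rng):
        a = rng.normal(10, 2, (4, 5, 5, 3))
        b = rng.normal(12, 2, (4, 5, 5, 3))
        fwd = voxelwise_ttest(group_from_arrays(a, b))
        rev = voxelwise_ttest(group_from_arrays(b, a))
        assert np.allclose(fwd.t_map, -rev.t_map, atol=1e-12)
        assert np.allclose(fwd.p_pos, rev.p_neg, atol=1e-12)
        assert np.allclose(fwd.p_neg, rev.p_pos, atol=1e-12)

    def test_one_sided_p_consistency(self, rng):
        a = rng.normal(10, 2, (4, 5, 5, 3))
        b = rng.normal(12, 2, (4, 5, 5, 3))
        out = voxelwise_ttest(group_from_arrays(a, b))
        m = out.analysis_mask
        lhs = np.minimum(out.p_pos, out.p_neg)[m]
        assert np.allclose(lhs, out.p_two_sided[m] / 2, atol=1e-12)


class TestFdrBH:
    def test_definitional_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.9])
        thr, q = fdr_bh(p, np.ones(5, bool), 0.05)
        assert thr == pytest.approx(0.04)
        assert np.sum(p <= thr) == 4

    def test_matches_statsmodels(self, rng):
        import statsmodels.stats.multitest as smm

        p = rng.uniform(0, 1, 200)
        p[:20] = rng.uniform(0, 0.001, 20)
        _, q = fdr_bh(p, np.ones(200, bool), 0.05)
        _, q_ref, _, _ = smm.multipletests(p, 0.05, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)

    def test_all_ones_no_discoveries(self):
        thr, q = fdr_bh(np.ones(10), np.ones(10, bool), 0.05)
        assert thr is None
        assert np.all(q == 1.0)

    def test_single_test_reduces_to_plain_threshold(self):
        thr, q = fdr_bh(np.array([0.03]), np.ones(1, bool), 0.05)
        assert thr == pytest.approx(0.03)
        thr2, _ = fdr_bh(np.array([0.07]), np.ones(1, bool), 0.05)
        assert thr2 is None


class TestFWE:
    def test_bonferroni_multiplication(self):
        p = np.full(1000, 1e-5)
        thr, p_fwe = bonferroni(p, np.ones(1000, bool), 0.05)
        assert np.allclose(p_fwe, 0.01)
        assert thr == pytest.approx(0.05 / 1000)

    def test_bonferroni_dominates_bh(self, rng):
        p = rng.uniform(0, 1, 500)
        mask = np.ones(500, bool)
        _, q = fdr_bh(p, mask, 0.05)
        _, p_fwe = bonferroni(p, mask, 0.05)
        assert np.all(p_fwe >= q - 1e-12)

    def test_exhaustive_3v3_permutation_matches_enumeration(self, rng):
        a = rng.normal(0, 1, (3, 4, 4, 2))
        b = rng.normal(1, 1, (3, 4, 4, 2))
        data = group_from_arrays(a, b)
        maps = voxelwise_ttest(data)
        p_fwe, maxima = fwe_permutation_maxt(data, maps, n_permutations=1000)

        # oracle: direct enumeration of all C(6,3)=20 relabelings
        pooled = np.concatenate([a, b], axis=0)
        from autorad3d.stats import _pooled_t

        ref_maxima = []
        for combo in itertools.combinations(range(6), 3):
            sel = np.zeros(6, bool)
            sel[list(combo)] = True
            t, _, degen = _pooled_t(pooled[sel], pooled[~sel])
            ref_maxima.append(np.abs(np.where(degen, 0.0, t)).max())
        assert len(maxima) == 20
        assert np.allclose(np.sort(maxima), np.sort(ref_maxima), atol=1e-12)

        obs = np.abs(maps.t_map)
        m = maps.analysis_mask
        ref_p = np.ones_like(obs)
        ref_p[m] = (1 + (np.asarray(ref_maxima)[None, :]
                         >= obs[m][:, None] - 1e-12).sum(1)) / 21.0
        assert np.allclose(p_fwe, ref_p, atol=1e-12)


class TestClusterFilter:
    def test_empty_map_gives_empty_table(self):
        labels, table = cluster_filter(np.zeros((5, 5, 5), bool))
        assert labels.max() == 0
        assert table.empty

    def test_size_filter_keeps_only_large_blob(self):
        sig = np.zeros((20, 20, 10), bool)
        sig[2:7, 2:7, 2:6] = True  # 100 voxels
        sig[15:16, 15:16, 2:7] = True  # 5 voxels
        labels, table = cluster_filter(sig, min_cluster_size=10)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 100

    def test_matches_flood_fill_oracle(self, rng):
        def flood_fill_count(binary):
            # brute-force 26-connected flood fill
            visited = np.zeros_like(binary, bool)
            sizes = []
            idx = np.argwhere(binary)
            for seed in map(tuple, idx):
                if visited[seed]:
                    continue
                stack, size = [seed], 0
                visited[seed] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in itertools.product((-1, 0, 1), repeat=3):
                        if d == (0, 0, 0):
                            continue
                        q = tuple(np.add(p, d))
                        if (all(0 <= q[i] < binary.shape[i] for i in range(3))
                                and binary[q] and not visited[q]):
                            visited[q] = True
                            stack.append(q)
                sizes.append(size)
            return sorted(sizes, reverse=True)

        for _ in range(10):
            binary = rng.random((12, 12, 8)) < 0.25
            labels, table = cluster_filter(binary, min_cluster_size=1)
            assert table["size"].tolist() == flood_fill_count(binary)

    def test_peak_statistic_reported(self):
        sig = np.zeros((10, 10, 5), bool)
        sig[2:5, 2:5, 1:3] = True
        t = np.zeros((10, 10, 5))
        t[3, 3, 2] = 7.5
        labels, table = cluster_filter(sig, peak_stat=t)
        assert table.iloc[0]["peak_t"] == pytest.approx(7.5)
        assert (table.iloc[0][["peak_i", "peak_j", "peak_k"]].tolist()
                == [3, 3, 2])


class TestSmoothGroup:
    def test_factor_zero_is_identity(self, rng):
        a = rng.normal(10, 2, (2, 8, 8, 4))
        b = rng.normal(10, 2, (2, 8, 8, 4))
        data = group_from_arrays(a, b)
        out = smooth_group(data, 0.0)
        assert out is data

    def test_white_noise_variance_reduction_matches_theory(self, rng):
        # smoothing an iid field divides the variance by prod(2 sqrt(pi) s_a)
        # for per-axis sigma s_a in voxels (continuum approximation)
        sigma_vox = np.array([30.0, 30.0, 60.0]) / 2.354820045 / np.array(VOX)
        noise = rng.standard_normal((64, 64, 40))
        from scipy import ndimage

        sm = ndimage.gaussian_filter(noise, sigma_vox)
        expected = 1.0 / np.prod(2 * np.sqrt(np.pi) * sigma_vox)
        observed = sm[8:-8, 8:-8, 4:-4].var()
        assert observed == pytest.approx(expected, rel=0.10)


class TestNullCalibration:
    def test_uncorrected_p_fraction_matches_alpha(self):
        # subject-level resampling: mean suprathreshold fraction over seeds
        fracs = []
        for seed in range(6):
            spec = PhantomSpec(noise_sd=5.0)
            study = make_group_study(spec, 4, effect_size=0.0, seed=300 + seed,
                                     max_shift=0, max_angle=0)
            data = GroupData([s.volume for s in study.subjects],
                             [s.group for s in study.subjects])
            maps = voxelwise_ttest(smooth_group(data, 3.0))
            m = maps.analysis_mask
            fracs.append(float(np.mean(maps.p_two_sided[m] < 0.05)))
        mean = np.mean(fracs)
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(mean - 0.05) < max(3 * se, 0.04)
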