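import numpy as np
import pytest

from fivec_locus import normalization as norm
from fivec_locus import synthetic_data as sd
from fivec_locus.io_formats import ContactMatrix

from conftest import power_law_matrix


def brute_force_local_stats(d, v, x, k):
    """Independent oracle: tricube-weighted mean/SD of the k nearest points."""
    d, v = np.asarray(d, float), np.asarray(v, float)
    order = np.argsort(np.abs(d - x), kind="stable")[:k]
    h = np.abs(d[order] - x).max()
    w = np.ones(k) if h == 0 else (1 - (np.abs(d[order] - x) / (h * 1.0001)) ** 3) ** 3
    m = np.average(v[order], weights=w)
    var = np.average((v[order] - m) ** 2, weights=w)
    return m, np.sqrt(var)


class TestDecayCurve:
    def test_power_law_recovered_within_2pct(self, decay_matrix):
        curve = norm.global_distance_decay(decay_matrix, span=0.05)
        d = decay_matrix.distance_grid()
        lo, hi = np.percentile(d, [10, 90])
        sel = (curve.support > lo) & (curve.support < hi)
        expected = 1e6 / curve.support[sel]
        np.testing.assert_allclose(curve.mean[sel], expected, rtol=0.02)

    def test_constant_matrix_flat_with_floored_sd(self, small_probe_map):
        m = ContactMatrix(small_probe_map, np.full((20, 20), 7.0))
        curve = norm.global_distance_decay(m)
        np.testing.assert_allclose(curve.mean, 7.0)
        np.testing.assert_allclose(curve.sd, 7e-3)  # rel floor applied
        z = norm.z_score_grid(m, curve)
        np.testing.assert_allclose(np.asarray(z), 0.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1_000, 100_000, 300)
        v = 50 + rng.normal(0, 5, 300)
        span = 0.1
        curve = norm.loess_fit(d, v, span)
        k = max(5, int(np.ceil(span * 300)))
        for x in np.percentile(d, [20, 50, 80]):
            xq = curve.support[np.argmin(np.abs(curve.support - x))]
            m, s = brute_force_local_stats(d, v, xq, k)
            assert curve.expected_mean(xq) == pytest.approx(m, rel=1e-6)
            assert curve.expected_sd(xq) == pytest.approx(s, rel=1e-6, abs=1e-6)

    def test_masked_cells_excluded(self, small_probe_map):
        m = power_law_matrix(small_probe_map)
        i, j = 5, 5
        m.values[i, j] *= 10  # bump one cell well above the curve
        d_bump = m.distance_grid()[i, j]
        c_all = norm.global_distance_decay(m)
        m2 = m.copy()
        m2.cell_mask[i, j] = True
        c_masked = norm.global_distance_decay(m2)
        assert c_masked.expected_mean(d_bump) < c_all.expected_mean(d_bump)

    def test_single_distance_degenerate(self):
        with pytest.raises(norm.DegenerateFitError):
            norm.loess_fit(np.full(100, 5.0), np.arange(100.0), 0.1)


class TestPurge:
    def test_identical_profiles_no_removals(self, small_probe_map):
        rng = np.random.default_rng(1)
        d = small_probe_map.distance_grid()
        m = ContactMatrix(
            small_probe_map, rng.poisson(1e7 / np.maximum(d, 1)).astype(float)
        )
        decay = norm.global_distance_decay(m)
        _, qc = norm.purge_cis_probes(m, decay, 0.85)
        assert qc.removed == []

    def test_shuffled_probe_detected(self, study_probe_map):
        cfg = sd.SimulationConfig(seed=5, bad_probe_count=4, probe_bias_sd=0.3)
        mats, truth = sd.simulate_contact_matrices(
            study_probe_map, sd.default_layout(), [], cfg, 1
        )
        decay = norm.global_distance_decay(mats[0])
        _, qc = norm.purge_cis_probes(mats[0], decay)
        recovered = set(qc.removed) & set(map(str, truth.bad_probes[0]))
        assert len(recovered) >= 3  # at least 3 of 4 planted bad probes

    def test_insufficient_data_flagged_not_purged(self, small_probe_map):
        m = power_law_matrix(small_probe_map)
        m.cell_mask[0, :] = True
        m.cell_mask[0, :3] = False  # probe F... has only 3 cells
        decay = norm.global_distance_decay(m)
        _, qc = norm.purge_cis_probes(m, decay)
        pid = small_probe_map.forward[0].probe_id
        assert pid in qc.insufficient
        assert pid not in qc.removed

    def test_idempotent_given_same_decay(self, small_probe_map):
        rng = np.random.default_rng(2)
        d = small_probe_map.distance_grid()
        m = ContactMatrix(
            small_probe_map, rng.poisson(1e7 / np.maximum(d, 1)).astype(float)
        )
        decay = norm.global_distance_decay(m)
        m1, qc1 = norm.purge_cis_probes(m, decay)
        m2, qc2 = norm.purge_cis_probes(m1, decay)
        assert qc2.removed == []
        np.testing.assert_array_equal(m1.mask, m2.mask)


class TestSingletons:
    def test_no_cell_above_threshold_unchanged(self, decay_matrix):
        decay = norm.global_distance_decay(decay_matrix)
        out, removed = norm.remove_singletons(decay_matrix, decay)
        assert removed == []
        np.testing.assert_array_equal(out.mask, decay_matrix.mask)

    def test_threshold_inclusive_at_exactly_25(self, small_probe_map):
        m = power_law_matrix(small_probe_map)
        decay = norm.global_distance_decay(m)
        d = m.distance_grid()
        i, j = 5, 7
        # engineer a cell sitting exactly at Z = 25
        m.values[i, j] = (
            decay.expected_mean(d[i, j]) + 25.0 * decay.expected_sd(d[i, j])
        )
        decay2 = norm.global_distance_decay(m)
        z = norm.z_score_grid(m, decay2)[i, j]
        out, removed = norm.remove_singletons(m, decay2, z_threshold=float(z))
        assert (small_probe_map.forward[i].probe_id,
                small_probe_map.reverse[j].probe_id) in removed
        assert out.cell_mask[i, j]

    def test_planted_spikes_recovered(self, study_probe_map):
        cfg = sd.SimulationConfig(seed=6, singleton_rate=0.001, bad_probe_count=0)
        mats, truth = sd.simulate_contact_matrices(
            study_probe_map, sd.default_layout(), [], cfg, 1
        )
        res = norm.normalize_library(mats[0])
        planted = set(truth.singletons[0])
        recovered = planted & set(res.singletons)
        assert len(recovered) / len(planted) >= 0.85


class TestNormalizeProfiles:
    def test_constant_matrix_identity(self, small_probe_map):
        m = ContactMatrix(small_probe_map, np.full((20, 20), 9.0))
        decay = norm.global_distance_decay(m)
        out, factors = norm.normalize_profiles(m, decay)
        assert all(f == pytest.approx(1.0) for f in factors.values())
        np.testing.assert_allclose(out.values, m.values)

    def test_planted_biases_corrected(self, study_probe_map):
        """Correlation to the bias-free expectation strictly improves
        after profile normalization of a bias-only simulation."""
        cfg = sd.SimulationConfig(seed=7, probe_bias_sd=0.3, singleton_rate=0.0,
                                  bad_probe_count=0)
        mats, truth = sd.simulate_contact_matrices(
            study_probe_map, sd.default_layout(), [], cfg, 1
        )
        res = norm.normalize_library(mats[0])
        sel = ~res.matrix.mask
        exp = truth.expected_biasfree
        c_raw = np.corrcoef(mats[0].values[sel], exp[sel])[0, 1]
        c_norm = np.corrcoef(res.matrix.values[sel], exp[sel])[0, 1]
        assert c_norm > c_raw

    def test_doubling_probe_profile_halves_its_factor(self, small_probe_map):
        rng = np.random.default_rng(3)
        d = small_probe_map.distance_grid()
        base = rng.poisson(1e7 / np.maximum(d, 1)).astype(float)
        m1 = ContactMatrix(small_probe_map, base)
        m2 = ContactMatrix(small_probe_map, base.copy())
        m2.values[4, :] *= 2
        decay = norm.global_distance_decay(m1)
        _, f1 = norm.normalize_profiles(m1, decay)
        out2, f2 = norm.normalize_profiles(m2, decay)
        pid = small_probe_map.forward[4].probe_id
        assert f2[pid] == pytest.approx(f1[pid] / 2, rel=0.02)
        # normalized profile of the doubled probe is (nearly) invariant
        out1, _ = norm.normalize_profiles(m1, decay)
        np.testing.assert_allclose(
            out2.values[4, :], out1.values[4, :], rtol=0.05
        )

    def test_global_scale_equivariance(self, small_probe_map):
        rng = np.random.default_rng(4)
        d = small_probe_map.distance_grid()
        base = rng.poisson(1e7 / np.maximum(d, 1)).astype(float)
        m = ContactMatrix(small_probe_map, base)
        out1, _ = norm.normalize_profiles(m, norm.global_distance_decay(m))
        m3 = ContactMatrix(small_probe_map, 3.0 * base)
        out3, _ = norm.normalize_profiles(m3, norm.global_distance_decay(m3))
        np.testing.assert_allclose(out3.values, 3.0 * out1.values, rtol=1e-6)

    def test_all_zero_profile_masked(self, small_probe_map):
        m = power_law_matrix(small_probe_map)
        m.values[6, :] = 0.0
        decay = norm.global_distance_decay(m)
        out, factors = norm.normalize_profiles(m, decay)
        assert out.fwd_probe_mask[6]
        assert small_probe_map.forward[6].probe_id not in factors


class TestBinning:
    def test_bin_size_smaller_than_step_rejected(self, decay_matrix):
        with pytest.raises(ValueError, match="bin_size"):
            norm.bin_matrix(decay_matrix, bin_size=10_000, step=20_000)

    def test_single_region_bin_equals_global_mean(self, small_probe_map,
                                                  small_region):
        m = power_law_matrix(small_probe_map)
        binned = norm.bin_matrix(
            m, bin_size=small_region.end - small_region.start,
            step=small_region.end - small_region.start,
            region=small_region.interval(),
        )
        assert binned.values.shape == (1, 1)
        assert binned.values[0, 0] == pytest.approx(m.values.mean())

    def test_symmetric(self, small_probe_map, small_region):
        m = power_law_matrix(small_probe_map)
        binned = norm.bin_matrix(m, 100_000, 20_000, small_region.interval())
        np.testing.assert_allclose(binned.values, binned.values.T)
        np.testing.assert_array_equal(binned.coverage, binned.coverage.T)

    def test_single_pair_lands_in_overlapping_windows(self, probe_map_6):
        m = ContactMatrix(probe_map_6, np.zeros((3, 3)))
        m.values[0, 0] = 10.0  # F01 mid 500, R01 mid 1500
        m.cell_mask[:] = True
        m.cell_mask[0, 0] = False
        binned = norm.bin_matrix(
            m, bin_size=2_000, step=1_000,
            region=type(probe_map_6.span)("chr3", 0, 6_000),
        )
        nz = np.nonzero(binned.values)
        # fwd mid 500 lies in window [0,2000); rev mid 1500 in [0,2000) and [1000,3000)
        assert set(zip(*nz)) == {(0, 0), (0, 1), (1, 0)}

    def test_masks_only_grow_and_values_untouched_through_qc(
        self, study_probe_map
    ):
        cfg = sd.SimulationConfig(seed=8)
        mats, _ = sd.simulate_contact_matrices(
            study_probe_map, sd.default_layout(), [], cfg, 1
        )
        m = mats[0]
        decay = norm.global_distance_decay(m)
        purged, _ = norm.purge_cis_probes(m, decay)
        assert (purged.mask | m.mask).sum() == purged.mask.sum()
        cleaned, _ = norm.remove_singletons(
            purged, norm.global_distance_decay(purged)
        )
        assert (cleaned.mask | purged.mask).sum() == cleaned.mask.sum()
        sel = ~cleaned.mask
        np.testing.assert_array_equal(cleaned.values[sel], m.values[sel])
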