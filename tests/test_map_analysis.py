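"""Delta matrices, stage clustering, P(s), compartments, insulation."""

import numpy as np
import pytest

from chromoswitch import hic_io, map_analysis, synthetic_data as sd
from chromoswitch.hic_io import GenomicBinning, normalize_to_probability
from chromoswitch.map_analysis import (boundary_overlap, cluster_stages,
                                       compartment_profile, delta_matrix,
                                       ice_normalize, insulation, oe_enhance,
                                       ps_curve, tad_size_series)


def uniform_map(n, off_value=0.3, binning=None):
    v = np.full((n, n), off_value)
    idx = np.arange(n)
    v[idx, idx] = 1.0
    v[idx[:-1], idx[:-1] + 1] = v[idx[:-1] + 1, idx[:-1]] = 1.0
    return hic_io.ContactMap(binning or GenomicBinning("chrU", 0, n - 1, 1), v)


def power_law_map(n, a, seed=0):
    spec = sd.SyntheticStateSpec(n, a, (), tuple(["A"] * n), 0.0, 0.0, seed)
    return sd.make_target_map(spec)


class TestDeltaMatrix:
    def test_identical_maps_give_zero(self):
        m = power_law_map(30, -1.2)
        dm = delta_matrix([m, m, m])
        np.testing.assert_array_equal(dm.values, 0.0)

    def test_hand_computed_asymmetry(self):
        # 2x2 toy: off-diagonals 0.5 vs 0.25 (diag fixed at 1)
        b = GenomicBinning("c", 0, 1, 1)
        mi = hic_io.ContactMap(b, np.array([[1.0, 0.5], [0.5, 1.0]]))
        mj = hic_io.ContactMap(b, np.array([[1.0, 0.25], [0.25, 1.0]]))
        dm = delta_matrix([mi, mj], "total")
        assert dm.values[0, 1] == pytest.approx(0.5)   # /sum(P^I)
        assert dm.values[1, 0] == pytest.approx(1.0)   # /sum(P^J)
        np.testing.assert_allclose(dm.symmetrized[0, 1], 0.75)

    def test_nonnegative_and_zero_diagonal(self):
        maps = [power_law_map(25, a, seed=i)
                for i, a in enumerate((-1.5, -1.2, -1.0))]
        dm = delta_matrix(maps)
        assert dm.values.min() >= 0
        assert np.all(np.diag(dm.values) == 0)

    def test_symmetrized_triangle_inequality(self):
        rng = np.random.default_rng(4)
        maps = []
        for _ in range(5):
            v = rng.uniform(0.05, 0.95, (12, 12))
            maps.append(normalize_to_probability((v + v.T) / 2))
        dm = delta_matrix(maps)
        s = dm.symmetrized
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert s[i, j] <= s[i, k] + s[k, j] + 1e-12

    def test_empty_filter_rejected(self):
        # 1-bp bins: no pair exceeds 2 Mb
        maps = [uniform_map(10), uniform_map(10, 0.4)]
        with pytest.raises(ValueError, match="no pairs"):
            delta_matrix(maps, "nonlocal")


class TestClusterStages:
    def _maps_from_series(self, levels, binning=None):
        return [uniform_map(12, lv, binning) for lv in levels]

    def test_two_maps_two_stages(self):
        maps = self._maps_from_series([0.2, 0.6])
        st = cluster_stages(delta_matrix(maps), delta_matrix(maps), 2)
        assert list(st.labels) == [0, 1]

    def test_three_plateaus_found(self):
        levels = [0.2] * 4 + [0.5] * 4 + [0.8] * 4
        maps = self._maps_from_series(levels)
        st = cluster_stages(delta_matrix(maps), delta_matrix(maps), 3)
        assert list(st.labels) == [0] * 4 + [1] * 4 + [2] * 4

    def test_single_stage(self):
        maps = self._maps_from_series([0.2, 0.3, 0.4])
        st = cluster_stages(delta_matrix(maps), delta_matrix(maps), 1)
        assert set(st.labels) == {0}

    def test_infeasible_count_reports_nearest(self):
        # A-B-A alternation: any 2-cluster cut breaks temporal contiguity
        maps = self._maps_from_series([0.2, 0.8, 0.2])
        with pytest.raises(ValueError, match="nearest feasible"):
            cluster_stages(delta_matrix(maps), delta_matrix(maps), 2)


class TestPsCurve:
    def test_exact_power_law_recovered(self):
        curve = ps_curve(power_law_map(300, -1.5), (5, 50))
        assert curve.exponent == pytest.approx(-1.5, abs=0.02)

    def test_constant_map_zero_slope(self):
        curve = ps_curve(uniform_map(80), (3, 30))
        assert curve.exponent == pytest.approx(0.0, abs=1e-12)

    def test_plaid_map_slope_near_backbone(self):
        n = 300
        labels = sd.make_ab_labels(n, 20, 2)
        spec = sd.SyntheticStateSpec(n, -1.2, (), labels, plaid_strength=0.3)
        curve = ps_curve(sd.make_target_map(spec), (5, 50))
        assert curve.exponent == pytest.approx(-1.2, abs=0.1)

    def test_sub_decade_range_rejected(self):
        with pytest.raises(ValueError, match="decade"):
            ps_curve(power_law_map(100, -1.0), (5, 40))

    def test_range_beyond_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            ps_curve(power_law_map(30, -1.0), (3, 40))


class TestCompartments:
    def test_power_law_map_has_no_compartment_signal(self):
        prof = compartment_profile(power_law_map(200, -1.2))
        oe = oe_enhance(power_law_map(200, -1.2))
        off = np.abs(np.subtract.outer(*[np.arange(200)] * 2)) > 1
        np.testing.assert_allclose(oe[off], 1.0, atol=1e-9)
        assert np.abs(prof.pc1.values).max() < 1e-6 or \
            np.nanstd(prof.pc1.values) < 1e-6

    def test_plaid_recovery_and_sign_fix(self):
        n = 300
        labels = np.array(sd.make_ab_labels(n, 20, 7))
        spec = sd.SyntheticStateSpec(n, -1.0, (), tuple(labels),
                                     plaid_strength=0.3)
        cmap = sd.make_target_map(spec)
        prof = compartment_profile(cmap, reference=labels)
        ref = np.where(labels == "A", 1.0, -1.0)
        corr = np.corrcoef(prof.pc1.values, ref)[0, 1]
        assert corr >= 0.8  # sign already fixed toward the reference
        assert np.all((prof.labels == "A") == (prof.pc1.values > 0))

    def test_profile_invariant_to_map_scaling(self):
        n = 200
        labels = sd.make_ab_labels(n, 20, 3)
        spec = sd.SyntheticStateSpec(n, -1.0, (), labels, plaid_strength=0.3)
        cmap = sd.make_target_map(spec)
        p1 = compartment_profile(cmap, reference=np.array(labels))
        # scaling the raw matrix is removed by probability normalization
        scaled = normalize_to_probability(cmap.values * 5.0, cmap.binning)
        p2 = compartment_profile(scaled, reference=np.array(labels))
        np.testing.assert_allclose(p1.pc1.values, p2.pc1.values, atol=1e-8)

    def test_ice_balances_row_sums(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.1, 1.0, (30, 30))
        out = ice_normalize((v + v.T) / 2, tol=1e-6)
        sums = out.sum(axis=1)
        assert np.max(np.abs(sums / sums.mean() - 1)) < 1e-5

    def test_ice_keeps_balanced_matrix(self):
        n = 20
        v = np.full((n, n), 0.5)
        out = ice_normalize(v, tol=1e-8)
        np.testing.assert_allclose(out, v, rtol=1e-6)

    def test_ice_zero_rows_reinserted_as_missing(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 1.0, (10, 10))
        v = (v + v.T) / 2
        v[3, :] = v[:, 3] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            out = ice_normalize(v)
        assert np.isnan(out[3]).all()
        assert not np.isnan(np.delete(np.delete(out, 3, 0), 3, 1)).any()

    def test_ice_non_convergence_raises(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0.1, 1.0, (20, 20))
        with pytest.raises(RuntimeError, match="ICE"):
            ice_normalize((v + v.T) / 2, tol=1e-12, max_iters=1)


class TestInsulation:
    def test_uniform_map_calls_no_boundaries(self):
        res = insulation(uniform_map(60), window_bins=5)
        valid = res.score.values[~np.isnan(res.score.values)]
        np.testing.assert_allclose(valid, 0.0, atol=1e-12)
        assert res.boundaries.size == 0

    def test_two_block_map_one_boundary_at_junction(self):
        n = 40
        v = np.full((n, n), 0.05)
        v[:20, :20] = 0.8
        v[20:, 20:] = 0.8
        idx = np.arange(n)
        v[idx, idx] = 1.0
        v[idx[:-1], idx[:-1] + 1] = v[idx[:-1] + 1, idx[:-1]] = 1.0
        cmap = hic_io.ContactMap(GenomicBinning("c", 0, n - 1, 1), v)
        res = insulation(cmap, window_bins=5)
        assert res.boundaries.size == 1
        assert abs(res.boundaries[0] - 20) <= 1

    def test_calls_invariant_to_scaling(self):
        n = 200
        bnd = sd.make_tad_boundaries(n, 9, 3)
        spec = sd.SyntheticStateSpec(n, -1.5, bnd, tuple(["A"] * n),
                                     tad_strength=2.0)
        cmap = sd.make_target_map(spec)
        res1 = insulation(cmap, 5)
        res2 = insulation(hic_io.ContactMap(cmap.binning, cmap.values * 0.25),
                          5)
        np.testing.assert_array_equal(res1.boundaries, res2.boundaries)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="window"):
            insulation(uniform_map(8), window_bins=5)

    def test_overlap_identical_sets(self):
        n_ol, f_ref, f_query = boundary_overlap([3, 9, 15], [3, 9, 15])
        assert (n_ol, f_ref, f_query) == (3, 1.0, 1.0)

    def test_overlap_within_tolerance(self):
        n_ol, f_ref, f_query = boundary_overlap([10, 20], [11, 30], tol_bins=1)
        assert n_ol == 1
        assert f_ref == 0.5


class TestTadSizeSeries:
    def test_mean_size_arithmetic(self):
        b = GenomicBinning("c", 0, 10_000_000, 100_000)
        ts = tad_size_series([[10, 20, 30]] * 3, b, [0.0, 1.0, 2.0])
        assert ts.mean_size_mb[0] == pytest.approx(1.0)

    def test_constant_series_degenerate(self):
        b = GenomicBinning("c", 0, 10_000_000, 100_000)
        ts = tad_size_series([[10, 20]] * 4, b, [0, 1, 2, 3])
        assert ts.degenerate
        assert ts.y0 == ts.y_inf

    def test_exact_exponential_recovered(self):
        b = GenomicBinning("c", 0, 10_000_000, 100_000)
        times = np.linspace(0, 15, 25)
        tau_r = 3.0
        sizes = 1.0 + 0.8 * np.exp(-times / tau_r)
        frames = []
        for s in sizes:
            step = s * 10  # bins per TAD at 0.1 Mb/bin
            frames.append(np.arange(0, 100.0001, step))
        ts = tad_size_series(frames, b, times)
        assert ts.tau_r == pytest.approx(tau_r, rel=0.05)

    def test_sparse_frames_flagged_missing(self):
        b = GenomicBinning("c", 0, 10_000_000, 100_000)
        ts = tad_size_series([[10, 20], [5], [10, 30], [10, 25]], b,
                             [0, 1, 2, 3])
        assert np.isnan(ts.mean_size_mb[1])
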