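"""SMLM point-pattern statistics against brute-force oracles and CSR limits."""

import numpy as np
import pytest

from focirad import smlm_stats as ss
from focirad import synthetic_data as syn
from focirad.datatypes import LocalizationSet


def _csr(n, W, H, seed):
    rng = np.random.default_rng(seed)
    return LocalizationSet(
        rng.uniform(0, W, n), rng.uniform(0, H, n),
        np.zeros(n, dtype=int), np.full(n, 15.0), (W, H),
    )


def _brute_force_k(locs, radii, correction):
    pts = locs.points
    n = len(pts)
    W, H = locs.window_nm
    area = W * H
    k = np.zeros(len(radii))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dxy = pts[i] - pts[j]
            d = np.hypot(*dxy)
            w = area / ((W - abs(dxy[0])) * (H - abs(dxy[1]))) if correction == "translation" else 1.0
            k += w * (d <= radii)
    return area / n**2 * k


class TestRipley:
    @pytest.mark.parametrize("correction", ["none", "translation"])
    def test_equals_brute_force_double_loop(self, correction):
        locs = _csr(200, 3000.0, 2500.0, seed=1)
        radii = np.linspace(50, 600, 12)
        got = ss.ripley_k(locs, radii, correction).k
        np.testing.assert_allclose(got, _brute_force_k(locs, radii, correction), rtol=1e-10)

    def test_k_is_nondecreasing_and_zero_at_origin(self):
        locs = _csr(300, 4000.0, 4000.0, seed=2)
        res = ss.ripley_k(locs, np.linspace(0, 800, 30))
        assert res.k[0] == 0.0
        assert np.all(np.diff(res.k) >= 0)

    def test_fewer_than_two_points_rejected(self):
        locs = LocalizationSet(
            np.array([1.0]), np.array([1.0]), np.array([0]), np.array([10.0]),
            (100.0, 100.0),
        )
        with pytest.raises(ValueError):
            ss.ripley_k(locs, [10.0])

    def test_large_radius_sets_warning_flag(self):
        locs = _csr(50, 1000.0, 1000.0, seed=3)
        assert ss.ripley_k(locs, [400.0]).radius_warning
        assert not ss.ripley_k(locs, [200.0]).radius_warning

    def test_clustered_pattern_exceeds_csr_envelope(self):
        locs, _ = syn.simulate_smlm(2.0, rng=np.random.default_rng(8))
        radii = np.linspace(20, 300, 15)
        res = ss.ripley_with_envelope(locs, radii, n_sim=39,
                                      rng=np.random.default_rng(9))
        # L(r) - r must break out above the envelope near the cluster scale
        env_l = np.sqrt(res.envelope_high / np.pi) - radii
        near = (radii > 20) & (radii < 150)
        assert np.any(res.l_minus_r[near] > env_l[near])


class TestEnvelope:
    def test_envelope_orders_and_modes(self):
        radii = np.linspace(20, 200, 8)
        lo, hi = ss.csr_envelope(100, (2000.0, 2000.0), radii, n_sim=19,
                                 rng=np.random.default_rng(0))
        assert np.all(lo <= hi)
        lo_p, hi_p = ss.csr_envelope(100, (2000.0, 2000.0), radii, n_sim=39,
                                     rng=np.random.default_rng(0), mode="percentile")
        assert np.all(lo_p <= hi_p)

    def test_envelope_widens_as_n_decreases(self):
        radii = np.linspace(50, 300, 6)
        rng = np.random.default_rng(1)
        lo_small, hi_small = ss.csr_envelope(50, (4000.0, 4000.0), radii, 39, rng)
        lo_big, hi_big = ss.csr_envelope(500, (4000.0, 4000.0), radii, 39, rng)
        assert np.mean(hi_small - lo_small) > np.mean(hi_big - lo_big)

    def test_too_few_simulations_rejected(self):
        with pytest.raises(ValueError):
            ss.csr_envelope(10, (100.0, 100.0), [10.0], n_sim=5)


class TestDensityImage:
    def test_single_point_has_zero_neighbors(self):
        locs = LocalizationSet(
            np.array([50.0]), np.array([50.0]), np.array([0]), np.array([10.0]),
            (100.0, 100.0),
        )
        img = ss.neighbor_density_image(locs)
        assert img.counts.tolist() == [0]
        assert img.radius_nm == 1000.0  # conventional neighborhood radius

    def test_counts_equal_brute_force(self):
        locs = _csr(500, 5000.0, 5000.0, seed=5)
        got = ss.neighbor_density_image(locs, radius_nm=800.0).counts
        pts = locs.points
        expect = np.array(
            [np.sum(np.hypot(*(pts - p).T) <= 800.0) - 1 for p in pts]
        )
        np.testing.assert_array_equal(got, expect)

    def test_rendered_image_max_matches_counts(self):
        locs = _csr(200, 2000.0, 2000.0, seed=6)
        img = ss.neighbor_density_image(locs, radius_nm=500.0, render_px_nm=100.0)
        assert img.image.max() == img.counts.max()


class TestDistanceFrequencies:
    def test_two_points_twenty_nm_apart(self):
        locs = LocalizationSet(
            np.array([40.0, 60.0]), np.array([50.0, 50.0]),
            np.array([0, 1]), np.array([10.0, 10.0]), (100.0, 100.0),
        )
        d = ss.distance_frequencies(locs, bin_nm=5.0)
        np.testing.assert_allclose(d.distances_nm, [20.0, 20.0])
        peak_bin = np.argmax(d.frequencies)
        assert d.bin_edges_nm[peak_bin] <= 20.0 <= d.bin_edges_nm[peak_bin + 1]

    def test_csr_mean_nn_distance_matches_closed_form(self):
        # Poisson process of intensity rho: E[NN distance] = 1 / (2 sqrt(rho))
        n, W = 5000, 10000.0
        locs = _csr(n, W, W, seed=7)
        rho = n / (W * W)
        expect = 1.0 / (2.0 * np.sqrt(rho))
        got = ss.distance_frequencies(locs).mean_nm
        assert abs(got - expect) / expect < 0.03

    def test_pairwise_mode_requires_cutoff(self):
        locs = _csr(50, 1000.0, 1000.0, seed=8)
        with pytest.raises(ValueError):
            ss.distance_frequencies(locs, mode="pairwise")
        d = ss.distance_frequencies(locs, mode="pairwise", max_nm=300.0)
        assert d.frequencies.sum() == len(d.distances_nm)

    def test_gamma_fit_family_available(self):
        locs = _csr(500, 3000.0, 3000.0, seed=9)
        d = ss.distance_frequencies(locs, fit="gamma")
        assert d.fit_family == "gamma"
        assert d.peak_maximum_nm > 0


class TestMergeBlinks:
    def test_well_separated_single_blinks_unmerged(self):
        rng = np.random.default_rng(0)
        n = 50
        x = np.arange(n) * 500.0 + 100.0
        locs = LocalizationSet(
            x, np.full(n, 100.0), rng.integers(0, 1000, n), np.full(n, 15.0),
            (n * 500.0 + 200.0, 200.0),
        )
        count, merged = ss.merge_blinks(locs)
        assert count == n

    def test_zero_radius_disables_merging(self):
        locs, _ = syn.simulate_smlm(1.0, rng=np.random.default_rng(1))
        count, merged = ss.merge_blinks(locs, merge_radius_nm=0.0)
        assert count == len(locs)

    def test_merging_is_idempotent(self):
        locs, _ = syn.simulate_smlm(1.0, rng=np.random.default_rng(2))
        n1, merged = ss.merge_blinks(locs)
        n2, merged2 = ss.merge_blinks(merged)
        assert n1 == n2
        np.testing.assert_allclose(merged.x_nm, merged2.x_nm)

    def test_recovers_true_tag_count_within_ten_percent(self):
        ratios = []
        for seed in range(3):
            locs, truth = syn.simulate_smlm(2.0, rng=np.random.default_rng(seed))
            count, _ = ss.merge_blinks(locs)
            smlm = syn.SmlmConfig()
            n_bg = smlm.background_density_per_um2 * locs.area_nm2 / 1e6
            ratios.append(count / (len(truth.tags) + n_bg))
        assert abs(np.mean(ratios) - 1.0) < 0.10


class TestDoseEfficiency:
    def test_recovers_linear_slope_and_selects_linear(self):
        rng = np.random.default_rng(0)
        a, b, sd = 300.0, 150.0, 40.0
        doses = np.repeat([0.0, 0.5, 1.0, 2.0, 4.0], 30)
        counts = a + b * doses + rng.normal(0, sd, len(doses))
        resp = ss.fit_dose_efficiency(doses, counts)
        assert resp.selected == "linear"
        slope = resp.models["linear"]["params"][1]
        assert abs(slope - b) < 2 * sd / np.sqrt(30)  # generous CI-scale bound
        assert abs(resp.linear_low["slope"] - b) < 3 * resp.linear_low["slope_se"]

    def test_supra_linear_data_prefers_curved_model(self):
        rng = np.random.default_rng(1)
        doses = np.repeat([0.0, 0.5, 1.0, 2.0, 3.0, 4.0], 30)
        counts = 300.0 + 150.0 * doses + 120.0 * np.maximum(doses - 2.0, 0) ** 2
        counts = counts + rng.normal(0, 40.0, len(doses))
        resp = ss.fit_dose_efficiency(doses, counts)
        assert resp.selected in ("quadratic", "exponential")

    def test_low_dose_window_defaults_to_two_gray(self):
        rng = np.random.default_rng(2)
        doses = np.repeat([0.0, 1.0, 2.0, 4.0], 10)
        counts = 100 + 50 * doses + rng.normal(0, 5, len(doses))
        resp = ss.fit_dose_efficiency(doses, counts)
        assert resp.linear_low["max_dose_gy"] == 2.0

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError):
            ss.fit_dose_efficiency([0, 0, 1, 1], [1, 2, 3, 4])
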