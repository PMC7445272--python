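"""Directional curves, the distributive shuffle test, Watson U^2,
correlations and half-session stability."""

import numpy as np
import pytest

import gridhead as gh
from gridhead.directional import (DirectionalCurve, ShuffleEnsemble,
                                  _two_tailed_p, classic_hd_curve,
                                  distributive_curve, significant_bins,
                                  shuffle_spike_locations,
                                  stability_percentile, watson_u2,
                                  watson_u2_permutation_p)
from gridhead.session_io import attach_kinematics
from gridhead.tuning import RateMap, compute_rate_map

from conftest import make_trajectory


def brute_force_watson_u2(a_deg, b_deg):
    """O((n+m)^2) direct implementation from the definition.

    For every rotation-invariant pair ordering the statistic integrates
    the squared centred difference of empirical CDFs over the pooled
    sample points.
    """
    a = np.sort(np.mod(np.asarray(a_deg, float), 360.0))
    b = np.sort(np.mod(np.asarray(b_deg, float), 360.0))
    n, m = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))
    d = np.empty(len(pooled))
    for k, t in enumerate(pooled):
        d[k] = np.sum(a <= t) / n - np.sum(b <= t) / m
    return n * m / (n + m) ** 2 * np.sum((d - d.mean()) ** 2)


class TestCurves:
    def test_uniform_spikes_give_flat_curve_at_known_rate(self):
        # 100 spikes over 100 s of uniform sampling -> 1 Hz everywhere
        rng = np.random.default_rng(0)
        traj_hd = np.arange(3000) * 360.0 / 3000.0  # uniform, 100 s @ 30 Hz
        spike_hd = np.arange(100) * 3.6
        for fn in (classic_hd_curve, distributive_curve):
            curve = fn(spike_hd, traj_hd, 30.0)
            np.testing.assert_allclose(
                curve.rate_hz[np.isfinite(curve.rate_hz)], 1.0, rtol=0.2)
            assert np.nanstd(curve.rate_hz) < 0.2

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        traj_hd = rng.uniform(0, 360, 5000)
        spike_hd = rng.vonmises(1.0, 3.0, 400) * 180 / np.pi % 360
        c0 = classic_hd_curve(spike_hd, traj_hd, 30.0)
        c90 = classic_hd_curve((spike_hd + 90) % 360,
                               (traj_hd + 90) % 360, 30.0)
        np.testing.assert_allclose(np.roll(c0.rate_hz, 90), c90.rate_hz,
                                   rtol=1e-9)

    def test_distributive_curve_conserves_mean_rate(self):
        rng = np.random.default_rng(2)
        traj_hd = rng.uniform(0, 360, 30000)
        spike_hd = rng.choice(traj_hd, 700)
        curve = distributive_curve(spike_hd, traj_hd, 30.0)
        occ_share = curve.occupancy_s / curve.occupancy_s.sum()
        mean_rate = 700 / (30000 / 30.0)
        assert np.nansum(curve.rate_hz * occ_share) \
            == pytest.approx(mean_rate, abs=1e-9)

    def test_conjunctive_truth_peak_recovered(self, long_trajectory):
        # 60-deg tuning keeps the curve's top curved enough for the
        # argmax to be a sharp estimator of the preferred direction
        errs = []
        for s in range(8):
            cell = gh.make_conjunctive_cell(hd_pref=213.0, hd_fwhm=60.0)
            st = gh.generate_spikes(long_trajectory, cell, seed=400 + s)
            curve = classic_hd_curve(st.spike_hd, long_trajectory.hd, 30.0)
            peak = curve.bin_centres[np.nanargmax(curve.rate_hz)]
            errs.append(abs((peak - 213.0 + 180) % 360 - 180))
        assert np.median(errs) <= 5.0


def one_bin_ratemap(row, col, rate=5.0, n=42, arena=100.0):
    m = np.zeros((n, n))
    m[row, col] = rate
    return RateMap(np.zeros((n, n)), np.ones((n, n)), m, arena / n, 0.0,
                   arena)


class TestShuffle:
    def test_single_hot_bin_forces_one_direction(self):
        # trajectory visits the hot bin only while facing ~90 deg
        n = 200
        x = np.r_[np.full(n, 1.0), np.full(n, 60.0)]
        y = np.r_[np.full(n, 1.0), np.full(n, 60.0)]
        hd = np.r_[np.full(n, 90.0), np.full(n, 270.0)]
        traj = make_trajectory(np.arange(2 * n) / 30.0, x, y, hd)
        rm = one_bin_ratemap(0, 0)
        ens = shuffle_spike_locations(rm, traj, 50, n_shuffles=64, seed=0)
        hot = int(90 // 18)
        for b in range(20):
            col = ens.curves[:, b]
            if b == hot:
                assert np.all(col[np.isfinite(col)] > 0)
            elif np.isfinite(col).any():
                assert np.all(col[np.isfinite(col)] == 0)

    def test_ensemble_mean_matches_closed_form(self, short_trajectory):
        cell = gh.generate_spikes(short_trajectory, gh.make_grid_cell(),
                                  seed=31)
        rm = compute_rate_map(short_trajectory, cell)
        n_spikes = 400
        ens = shuffle_spike_locations(rm, short_trajectory, n_spikes,
                                      n_shuffles=3000, seed=1)
        # closed form: each draw lands in hd-bin b with probability equal
        # to the rate-weighted share of trajectory samples facing b
        rows, cols = rm.bin_of(short_trajectory.x, short_trajectory.y)
        w = rm.rate_hz[rows, cols]
        w = np.where(np.isfinite(w), w, 0.0)
        w = w / w.sum()
        hd_bin = np.minimum((short_trajectory.hd / 18).astype(int), 19)
        p_bin = np.bincount(hd_bin, weights=w, minlength=20)
        occ = np.bincount(hd_bin, minlength=20)
        expected = np.where(occ > 0, n_spikes * p_bin / occ * 30.0, np.nan)
        got = np.nanmean(ens.curves, axis=0)
        m = np.isfinite(expected)
        np.testing.assert_allclose(got[m], expected[m], rtol=0.12,
                                   atol=0.05)

    def test_identical_seed_reproduces_ensemble(self, short_trajectory):
        cell = gh.generate_spikes(short_trajectory, gh.make_grid_cell(),
                                  seed=31)
        rm = compute_rate_map(short_trajectory, cell)
        e1 = shuffle_spike_locations(rm, short_trajectory, 100, 50, seed=9)
        e2 = shuffle_spike_locations(rm, short_trajectory, 100, 50, seed=9)
        np.testing.assert_array_equal(e1.curves, e2.curves)

    def test_all_zero_rate_map_rejected(self, short_trajectory):
        rm = one_bin_ratemap(0, 0, rate=0.0)
        with pytest.raises(ValueError, match="zero"):
            shuffle_spike_locations(rm, short_trajectory, 10, 10, seed=0)


class TestSignificantBins:
    def _uniform_ensemble(self, rng, n_shuffles=500, rate=2.0):
        occ = np.full(20, 1000)
        counts = rng.poisson(rate * 1000 / 30.0, (n_shuffles, 20))
        curves = counts / 1000 * 30.0
        return ShuffleEnsemble(curves.astype(float), occ, 100, 0)

    def test_observed_at_median_gives_no_significant_bins(self):
        rng = np.random.default_rng(3)
        ens = self._uniform_ensemble(rng)
        obs = DirectionalCurve("distributive", np.arange(20) * 18 + 9,
                               np.median(ens.curves, axis=0), 100,
                               np.full(20, 1000 / 30.0))
        sig = significant_bins(obs, ens)
        assert sig.n_significant == 0
        assert not sig.directional

    def test_extreme_observed_flags_bins_and_verdict(self):
        rng = np.random.default_rng(4)
        ens = self._uniform_ensemble(rng)
        rate = np.median(ens.curves, axis=0).copy()
        rate[3:7] = rate[3:7] * 5          # far outside the ensemble
        obs = DirectionalCurve("distributive", np.arange(20) * 18 + 9,
                               rate, 100, np.full(20, 1000 / 30.0))
        sig = significant_bins(obs, ens)
        assert sig.n_significant >= 4
        assert sig.directional
        assert sig.percentile > 97.5

    def test_bh_monotone_in_extra_null_bin(self):
        # making one bin strictly less extreme never raises the count
        rng = np.random.default_rng(5)
        ens = self._uniform_ensemble(rng)
        rate = np.median(ens.curves, axis=0).copy()
        rate[0:5] *= 4
        obs1 = DirectionalCurve("distributive", np.arange(20) * 18 + 9,
                                rate.copy(), 100, np.full(20, 33.3))
        rate2 = rate.copy()
        rate2[10] = np.median(ens.curves[:, 10])
        obs2 = DirectionalCurve("distributive", np.arange(20) * 18 + 9,
                                rate2, 100, np.full(20, 33.3))
        s1 = significant_bins(obs1, ens)
        s2 = significant_bins(obs2, ens)
        assert s2.n_significant <= s1.n_significant

    def test_bin_grid_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        ens = self._uniform_ensemble(rng)
        obs = DirectionalCurve("classic", np.arange(360) + 0.5,
                               np.ones(360), 10, np.ones(360))
        with pytest.raises(ValueError, match="grids differ"):
            significant_bins(obs, ens)


class TestWatsonU2:
    def test_identical_samples_give_zero(self):
        a = np.array([10.0, 100.0, 200.0, 300.0])
        u2, _ = watson_u2(a, a)
        assert u2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n, m = rng.integers(5, 40, 2)
            a = rng.uniform(0, 360, n)
            b = rng.vonmises(0.5, rng.uniform(0, 2), m) * 180 / np.pi % 360
            u2, _ = watson_u2(a, b)
            assert u2 == pytest.approx(brute_force_watson_u2(a, b),
                                       abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 360, 30)
        b = rng.uniform(90, 270, 25)
        u0, _ = watson_u2(a, b)
        for rot in (45.0, 123.4, 270.0):
            ur, _ = watson_u2((a + rot) % 360, (b + rot) % 360)
            assert ur == pytest.approx(u0, abs=1e-9)

    def test_opposite_semicircles_highly_significant(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 180, 50)
        b = rng.uniform(180, 360, 50)
        u2, band = watson_u2(a, b)
        assert band == "p < 0.001"
        p = watson_u2_permutation_p(a, b, n_permutations=2000, seed=0)
        assert p < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            watson_u2([], [1.0])


class TestCurveCorrelation:
    def _vm_curve(self, mu_deg, n_spikes=300, kappa=2.0, seed=0):
        rng = np.random.default_rng(seed)
        spikes = (rng.vonmises(np.deg2rad(mu_deg), kappa, n_spikes)
                  * 180 / np.pi) % 360
        traj = rng.uniform(0, 360, 20000)
        return classic_hd_curve(spikes, traj, 30.0)

    def test_self_correlation_is_one(self):
        c = self._vm_curve(90.0)
        assert gh.hd_curve_correlation(c, c) == pytest.approx(1.0)

    def test_opposite_unimodal_curves_anticorrelate(self):
        c1 = self._vm_curve(90.0, seed=1)
        c2 = self._vm_curve(270.0, seed=2)
        assert gh.hd_curve_correlation(c1, c2) < -0.3

    def test_independent_random_curves_centre_on_zero(self):
        rng = np.random.default_rng(10)
        rs = []
        for s in range(30):
            c1 = self._vm_curve(rng.uniform(0, 360), seed=100 + s)
            c2 = self._vm_curve(rng.uniform(0, 360), seed=200 + s)
            rs.append(gh.hd_curve_correlation(c1, c2))
        assert abs(np.median(rs)) < 0.35


class TestFieldCorrelations:
    def test_conjunctive_truth_fields_share_tuning(self, long_trajectory):
        """All fields of a conjunctive cell share one preference, so
        between-field correlations are strongly positive."""
        meds = []
        for s in range(3):
            cell_spec = gh.make_conjunctive_cell(hd_pref=45.0,
                                                 peak_rate=25.0)
            cell = gh.generate_spikes(long_trajectory, cell_spec,
                                      seed=600 + s)
            rm = compute_rate_map(long_trajectory, cell)
            flds = [gh.assign_events_to_field(long_trajectory, cell, f, rm)
                    for f in gh.detect_fields(rm)]
            out = gh.field_correlation_analysis(
                gh.Session(long_trajectory, [cell]), cell, flds,
                min_spikes=200)
            meds.append(out["median_between"])
        assert np.median(meds) > 0.5

    def test_multidirectional_truth_fields_decorrelate(self, long_trajectory):
        rs = []
        for s in range(5):
            spec = gh.make_multidirectional_cell(seed=s, peak_rate=30.0)
            cell = gh.generate_spikes(long_trajectory, spec, seed=700 + s)
            rm = compute_rate_map(long_trajectory, cell)
            flds = [gh.assign_events_to_field(long_trajectory, cell, f, rm)
                    for f in gh.detect_fields(rm)]
            out = gh.field_correlation_analysis(
                gh.Session(long_trajectory, [cell]), cell, flds,
                min_spikes=200)
            rs.extend(out["between_field_r"])
        assert len(rs) >= 5
        assert abs(np.median(rs)) < 0.35

    def test_low_spike_fields_excluded(self, long_trajectory):
        spec = gh.make_grid_cell(peak_rate=2.0)  # few spikes per field
        cell = gh.generate_spikes(long_trajectory, spec, seed=41)
        rm = compute_rate_map(long_trajectory, cell)
        flds = [gh.assign_events_to_field(long_trajectory, cell, f, rm)
                for f in gh.detect_fields(rm)]
        assert all(f.n_spikes <= 500 for f in flds)
        out = gh.field_correlation_analysis(
            gh.Session(long_trajectory, [cell]), cell, flds)
        assert len(out["between_field_r"]) == 0


class TestStabilityPercentile:
    def _noisy_ensembles(self, rng, base, noise, n=300):
        occ = np.full(20, 1000)
        a = base + rng.normal(0, noise, (n, 20))
        b = base + rng.normal(0, noise, (n, 20))
        return (ShuffleEnsemble(a, occ, 100, 0),
                ShuffleEnsemble(b, occ, 100, 1))

    def test_identical_halves_score_high(self):
        rng = np.random.default_rng(11)
        base = 2.0 + np.sin(np.linspace(0, 2 * np.pi, 20))
        ens_a, ens_b = self._noisy_ensembles(rng, 2.0 + 0 * base, 0.5)
        pct = stability_percentile(0.999, ens_a, ens_b, seed=3)
        assert pct > 95

    def test_observed_from_null_is_uniformly_placed(self):
        rng = np.random.default_rng(12)
        pcts = []
        for s in range(40):
            base = np.full(20, 2.0)
            ens_a, ens_b = self._noisy_ensembles(rng, base, 0.5, n=120)
            i, j = rng.integers(0, 120, 2)
            r = np.corrcoef(ens_a.curves[i], ens_b.curves[j])[0, 1]
            pcts.append(stability_percentile(r, ens_a, ens_b,
                                             n_pairs=20000, seed=s))
        pcts = np.asarray(pcts)
        # roughly uniform on (0, 100): mean near 50, spread wide
        assert 30 < pcts.mean() < 70
        assert pcts.std() > 15

    def test_subsample_equals_population_when_exhaustive(self):
        rng = np.random.default_rng(13)
        base = np.full(20, 2.0)
        ens_a, ens_b = self._noisy_ensembles(rng, base, 0.5, n=40)
        p_full = stability_percentile(0.3, ens_a, ens_b, n_pairs=None)
        p_cap = stability_percentile(0.3, ens_a, ens_b, n_pairs=40 * 40)
        assert p_full == pytest.approx(p_cap)


def test_two_tailed_p_never_zero_and_bounded():
    rng = np.random.default_rng(14)
    ens = rng.random((200, 20))
    obs = rng.random(20)
    p = _two_tailed_p(obs, ens)
    assert np.all(p > 0) and np.all(p <= 1)
    # an observation beyond every shuffle reaches the floor 2/(n+1)
    p_ext = _two_tailed_p(np.full(20, 2.0), ens)
    np.testing.assert_allclose(p_ext, 2.0 / 201.0)
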