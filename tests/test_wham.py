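"""WHAM solver: histogram bookkeeping, oracle equivalence, referencing,
symmetrization and bootstrap behaviour."""

import numpy as np
import pytest

import interfep as ifp
from interfep.profiles import ReferencingError
from interfep.wham import WhamError, bootstrap_profile, build_histograms, wham_solve

from _oracles import naive_wham


class TestHistograms:
    def test_hand_counted_bins(self):
        w = ifp.UmbrellaWindow(0.0, 2000.0, samples=[0.01, 0.02, 0.11])
        h = ifp.build_histograms([w], 0.1, (0.0, 0.2))
        assert h.counts.tolist() == [[2, 1]]
        assert h.n_samples.tolist() == [3]
        assert h.out_of_range_fraction() == 0.0

    def test_bookkeeping_over_many_windows(self, small_window_set):
        h = ifp.build_histograms(small_window_set, 0.01, (-3.6, 3.6))
        assert h.counts.shape[0] == 84
        for i, w in enumerate(small_window_set):
            assert h.n_samples[i] + h.out_of_range[i] == w.n_samples

    def test_out_of_range_reported(self):
        w = ifp.UmbrellaWindow(0.0, 2000.0, samples=[0.05, 0.15, 5.0])
        h = ifp.build_histograms([w], 0.1, (0.0, 0.2))
        assert h.out_of_range.tolist() == [1]
        assert h.out_of_range_fraction() == pytest.approx(1 / 3)

    def test_empty_window_is_error(self):
        w = ifp.UmbrellaWindow(0.3, 2000.0, samples=[])
        with pytest.raises(WhamError, match="no samples"):
            ifp.build_histograms([w], 0.1, (0.0, 1.0))

    def test_window_outside_grid_is_error(self):
        w = ifp.UmbrellaWindow(5.0, 2000.0, samples=[5.0, 5.1])
        with pytest.raises(WhamError, match="inside"):
            ifp.build_histograms([w], 0.1, (0.0, 1.0))


class TestSolver:
    def test_unbiased_window_collapses_to_log_histogram(self):
        """With k = 0 the WHAM profile is -RT ln(histogram) + constant."""
        rng = np.random.default_rng(0)
        w = ifp.UmbrellaWindow(0.0, 0.0, samples=rng.normal(0.0, 0.4, 5000))
        h = ifp.build_histograms([w], 0.1, (-1.0, 1.0))
        prof = wham_solve(h, [0.0], [0.0], temperature=300.0)
        rt = ifp.kT(300.0)
        counts = h.counts[0]
        occ = counts > 0
        expected = -rt * np.log(counts[occ] / counts.sum())
        diff = prof.g[occ] - expected
        assert np.max(np.abs(diff - diff.mean())) < 1e-10

    def test_duplicated_window_leaves_profile_unchanged(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0.2, 0.05, 4000)
        w = ifp.UmbrellaWindow(0.2, 2000.0, samples=s)
        h1 = ifp.build_histograms([w], 0.02, (0.0, 0.4))
        h2 = ifp.build_histograms([w, w], 0.02, (0.0, 0.4))
        p1 = wham_solve(h1, [0.2], [2000.0])
        p2 = wham_solve(h2, [0.2, 0.2], [2000.0, 2000.0])
        occ = np.isfinite(p1.g)
        assert np.allclose(p1.g[occ], p2.g[occ], atol=1e-9)

    @pytest.mark.parametrize("n_windows", [1, 2, 3])
    def test_matches_naive_double_loop_oracle(self, n_windows):
        """Small instances agree with an independent brute-force iteration."""
        rng = np.random.default_rng(2 + n_windows)
        centers = np.linspace(-0.2, 0.2, n_windows)
        ks = np.full(n_windows, 500.0)
        wins = [
            ifp.UmbrellaWindow(
                c, k, samples=rng.normal(c, np.sqrt(ifp.kT(300.0) / k), 3000)
            )
            for c, k in zip(centers, ks)
        ]
        h = ifp.build_histograms(wins, 0.05, (-0.5, 0.5))
        ours = wham_solve(h, centers, ks, tol=1e-13, max_iter=10_000_000)
        zb, g_oracle, _ = naive_wham(
            h.bin_edges, h.counts, centers, ks, 300.0, tol=1e-15
        )
        occ = np.isfinite(ours.g)
        assert np.allclose(ours.z, zb)
        assert np.max(np.abs(ours.g[occ] - g_oracle[occ])) < 1e-8

    def test_probability_normalised_over_occupied_bins(self, small_fit):
        raw = small_fit.raw_profile
        rt = ifp.kT(raw.temperature)
        p = np.exp(-raw.g[raw.occupied] / rt)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_deterministic(self, small_window_set):
        m = ifp.UmbrellaSampling(small_window_set)
        a = m.fit().profile
        b = m.fit().profile
        assert np.array_equal(a.g, b.g, equal_nan=True)

    def test_convergence_error_carries_residual(self):
        rng = np.random.default_rng(3)
        wins = [
            ifp.UmbrellaWindow(c, 2000.0, samples=rng.normal(c, 0.035, 500))
            for c in (0.0, 0.08)
        ]
        h = ifp.build_histograms(wins, 0.01, (-0.3, 0.4))
        from interfep.wham import ConvergenceError

        with pytest.raises(ConvergenceError) as err:
            wham_solve(
                h, [0.0, 0.08], [2000.0, 2000.0],
                tol=1e-13, max_iter=2, warm_start=False,
            )
        assert err.value.residual > 0

    def test_disconnected_windows_rejected(self):
        rng = np.random.default_rng(4)
        wins = [
            ifp.UmbrellaWindow(c, 2000.0, samples=rng.normal(c, 0.035, 1000))
            for c in (-1.0, 1.0)
        ]
        h = ifp.build_histograms(wins, 0.05, (-1.5, 1.5))
        with pytest.raises(WhamError, match="disconnected"):
            wham_solve(h, [-1.0, 1.0], [2000.0, 2000.0])


class TestReferencing:
    def test_shift_invariance(self, small_fit):
        raw = small_fit.raw_profile
        shifted = ifp.FreeEnergyProfile(
            z=raw.z, g=raw.g + 17.3, temperature=raw.temperature
        )
        a = ifp.set_reference(raw, (3.0, 3.5))
        b = ifp.set_reference(shifted, (3.0, 3.5))
        occ = a.occupied
        assert np.allclose(a.g[occ], b.g[occ], atol=1e-9)

    def test_reference_region_mean_is_zero(self, small_fit):
        p = small_fit.profile
        mask = p.region_mask((3.0, 3.5)) & p.occupied
        assert abs(np.mean(p.g[mask])) < 1e-9
        assert p.reference == "vacuum-plateau"

    def test_empty_region_raises(self, small_fit):
        raw = small_fit.raw_profile
        g = raw.g.copy()
        g[np.abs(raw.z) >= 3.0] = np.nan
        hollow = ifp.FreeEnergyProfile(z=raw.z, g=g)
        with pytest.raises(ReferencingError):
            ifp.set_reference(hollow, (3.0, 3.5))


class TestSymmetrize:
    def test_idempotent(self, small_fit):
        once = small_fit.profile
        twice = ifp.symmetrize(once)
        assert np.allclose(once.g, twice.g, atol=1e-12, equal_nan=True)

    def test_odd_function_becomes_zero(self):
        z = np.linspace(-1.0, 1.0, 21)
        prof = ifp.FreeEnergyProfile(z=z, g=z.copy())
        assert np.allclose(ifp.symmetrize(prof).g, 0.0, atol=1e-12)

    def test_asymmetric_grid_rejected(self):
        prof = ifp.FreeEnergyProfile(z=np.array([0.0, 1.0, 2.0]), g=np.zeros(3))
        with pytest.raises(ValueError, match="symmetric"):
            ifp.symmetrize(prof)


class TestBootstrap:
    def test_single_window_resamples_have_zero_se(self):
        rng = np.random.default_rng(5)
        w = ifp.UmbrellaWindow(0.0, 2000.0, samples=rng.normal(0, 0.035, 4000))
        prof = bootstrap_profile(
            [w], 0.01, (-0.2, 0.2), n_boot=20, seed=1,
            reference_region=(0.0, 0.2), do_symmetrize=False,
        )
        occ = np.isfinite(prof.se)
        assert np.allclose(prof.se[occ], 0.0)

    def test_below_minimum_resamples_rejected(self, small_window_set):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_profile(small_window_set, 0.01, (-3.6, 3.6), n_boot=5)

    def test_seeded_and_reproducible(self, small_window_set):
        kw = dict(n_boot=20, seed=12)
        a = bootstrap_profile(small_window_set, 0.02, (-3.6, 3.6), **kw)
        b = bootstrap_profile(small_window_set, 0.02, (-3.6, 3.6), **kw)
        assert np.array_equal(a.se, b.se, equal_nan=True)

    def test_more_samples_do_not_inflate_se(self, double_well_model, scheme84):
        """Mean bootstrap se shrinks (or holds) as window sampling grows."""
        means = []
        for n_steps in (30_000, 120_000):
            wins = [
                ifp.UmbrellaWindow(c, 2000.0) for c in scheme84.centers()
            ]
            cfg = ifp.SamplerConfig(seed=77, n_steps=n_steps)
            wins = ifp.sample_windows(double_well_model, wins, cfg)
            wins = [ifp.discard_equilibration(w) for w in wins]
            prof = bootstrap_profile(wins, 0.01, (-3.6, 3.6), n_boot=25, seed=8)
            means.append(np.nanmean(prof.se))
        assert means[1] <= means[0]


class TestCombineModes:
    def test_pooled_and_mean_agree_within_bootstrap_error(self, small_window_set):
        m = ifp.UmbrellaSampling(small_window_set)
        pooled = m.fit().bootstrap(n_boot=30, seed=2).profile
        mean = m.fit(combine="mean").profile
        both = pooled.occupied & np.isfinite(mean.g) & (pooled.se > 0)
        diff = np.abs(pooled.g[both] - mean.g[both])
        assert np.all(diff <= 3.0 * pooled.se[both] + 0.05)

    def test_unknown_combine_rejected(self, small_window_set):
        with pytest.raises(ValueError, match="combine"):
            ifp.UmbrellaSampling(small_window_set).fit(combine="median")
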