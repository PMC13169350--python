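"""WHAM solver: analytic limits, oracle recovery, invariances, diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from nptraj.errors import (ConfigError, ConvergenceError,
                           DisconnectedDatasetError, NoPlateauError)
from nptraj.wham import (KB_KJ_PER_MOL_K, KJ_PER_KCAL, BindingEnergyEstimate,
                         PmfProfile, UmbrellaWindow, WhamConfig, bias_energy,
                         block_convergence, bootstrap_pmf,
                         extract_binding_energy, overlap_histograms,
                         read_window_manifest, wham_solve,
                         write_window_manifest)

KT310 = KB_KJ_PER_MOL_K * 310.0


def boltzmann_window_samples(v_func, window, n, seed, domain=(-2.0, 4.0),
                             convention="full"):
    """Inverse-CDF samples from the exact biased Boltzmann density — the
    independent oracle route, with no dynamics involved."""
    rng = np.random.default_rng(seed)
    x = np.linspace(*domain, 20001)
    u = bias_energy(x, window, convention)
    logp = -(v_func(x) + u) / KT310
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, x)


class TestBiasEnergy:
    def test_zero_at_reference_both_conventions(self):
        w = UmbrellaWindow(1.0, 1000.0, np.array([1.0]))
        assert bias_energy(1.0, w, "full") == 0.0
        assert bias_energy(1.0, w, "half") == 0.0

    def test_printed_arithmetic(self):
        w = UmbrellaWindow(1.0, 1000.0, np.array([1.0]))
        assert bias_energy(1.1, w, "full") == pytest.approx(10.0)
        assert bias_energy(1.1, w, "half") == pytest.approx(5.0)


class TestSolverLimits:
    def test_single_unbiased_window_reproduces_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(1.0, 0.3, 4000)
        w = UmbrellaWindow(0.0, 1e-12, samples)
        cfg = WhamConfig(n_bins=30, output_unit="kJ/mol")
        pmf = wham_solve([w], cfg)
        counts, edges = np.histogram(samples,
                                     bins=np.linspace(samples.min() - 0.01,
                                                      samples.max() + 0.01,
                                                      31))
        # replicate the solver's edge padding exactly
        span = samples.max() - samples.min()
        edges = np.linspace(samples.min() - 0.01 * span,
                            samples.max() + 0.01 * span, 31)
        counts, _ = np.histogram(samples, bins=edges)
        g_ref = -KT310 * np.log(counts / counts.sum(),
                                where=counts > 0,
                                out=np.full(30, np.nan))
        g_ref -= np.nanmin(g_ref)
        np.testing.assert_allclose(pmf.free_energy[pmf.valid],
                                   g_ref[~np.isnan(g_ref)], atol=1e-6)

    def test_near_uniform_samples_give_flat_pmf(self):
        rng = np.random.default_rng(1)
        w = UmbrellaWindow(0.5, 1e-12, rng.random(20000))
        pmf = wham_solve([w], WhamConfig(n_bins=10, output_unit="kJ/mol"))
        g = pmf.free_energy[pmf.valid]
        # pooled-SE scale for a uniform histogram with 2000 counts/bin
        se = KT310 / math.sqrt(2000)
        assert np.nanmax(g) < 3 * se * 3

    def test_boltzmann_oracle_recovery(self):
        """Windows sampled exactly from Boltzmann of V(x)=A(x-c)^2 + bias
        must reproduce V up to a constant."""
        A, c = 20.0, 1.0
        v = lambda x: A * (x - c) ** 2
        refs = np.linspace(0.0, 2.0, 9)
        windows = [
            UmbrellaWindow(r, 300.0,
                           boltzmann_window_samples(v, UmbrellaWindow(
                               r, 300.0, np.array([r])), 5000, seed=10 + i))
            for i, r in enumerate(refs)]
        pmf = wham_solve(windows, WhamConfig(n_bins=60,
                                             output_unit="kJ/mol",
                                             tolerance_kj=1e-7))
        x = pmf.bin_centers_nm[pmf.valid]
        g = pmf.free_energy[pmf.valid]
        truth = v(x) - v(x).min()
        core = (x > 0.0) & (x < 2.0)      # exclude sparsely sampled fringes
        rmse = np.sqrt(np.mean((g[core] - truth[core]) ** 2)) / KJ_PER_KCAL
        assert rmse < 0.3

    def test_duplicated_window_leaves_pmf_unchanged(self):
        rng = np.random.default_rng(2)
        w = UmbrellaWindow(1.0, 500.0, rng.normal(1.0, 0.1, 2000))
        cfg = WhamConfig(n_bins=40)
        single = wham_solve([w], cfg)
        doubled = wham_solve([w, UmbrellaWindow(1.0, 500.0,
                                                w.samples.copy())], cfg)
        np.testing.assert_allclose(single.free_energy[single.valid],
                                   doubled.free_energy[doubled.valid],
                                   atol=1e-8)

    def test_convention_consistency(self):
        """Half-convention with 2k is the same bias as full-convention with
        k, so both runs must give bit-equal profiles on the same samples."""
        rng = np.random.default_rng(3)
        refs = [0.5, 1.0, 1.5]
        samples = [rng.normal(r, 0.15, 1500) for r in refs]
        full = [UmbrellaWindow(r, 400.0, s) for r, s in zip(refs, samples)]
        half = [UmbrellaWindow(r, 800.0, s) for r, s in zip(refs, samples)]
        pf = wham_solve(full, WhamConfig(bias_convention="full", n_bins=50))
        ph = wham_solve(half, WhamConfig(bias_convention="half", n_bins=50))
        np.testing.assert_array_equal(pf.free_energy, ph.free_energy)

    def test_gauge_shift_of_window_energies_cancels(self):
        """The WHAM probability is invariant to adding a constant to every
        window free energy (the gauge the f_1 = 0 convention fixes)."""
        rng = np.random.default_rng(4)
        refs = [0.5, 1.0]
        windows = [UmbrellaWindow(r, 400.0, rng.normal(r, 0.12, 800))
                   for r in refs]
        pmf = wham_solve(windows, WhamConfig(n_bins=30))
        from scipy.special import logsumexp
        centers = pmf.bin_centers_nm
        counts = np.stack([np.histogram(w.samples, bins=centers.size,
                                        range=(centers[0], centers[-1]))[0]
                           for w in windows])
        beta = 1.0 / KT310
        bias = np.stack([bias_energy(centers, w) for w in windows])
        logn = np.log(np.array([w.samples.size for w in windows], float))
        n_b = counts.sum(axis=0)

        def anchored_g(f):
            log_denom = logsumexp(-beta * bias + (logn + beta * f)[:, None],
                                  axis=0)
            with np.errstate(divide="ignore"):
                logp = np.log(n_b) - log_denom
            g = -KT310 * logp
            return g - np.nanmin(g[np.isfinite(g)])

        f = pmf.window_free_energies_kj
        np.testing.assert_allclose(anchored_g(f), anchored_g(f + 7.3),
                                   atol=1e-9)

    def test_residual_history_decreases_after_burn_in(self):
        rng = np.random.default_rng(5)
        refs = np.linspace(0.3, 1.7, 8)
        windows = [UmbrellaWindow(r, 400.0, rng.normal(r, 0.12, 1000))
                   for r in refs]
        pmf = wham_solve(windows, WhamConfig(n_bins=50))
        hist = pmf.residual_history
        burn = min(20, hist.size // 2)
        assert np.all(np.diff(hist[burn:]) <= 1e-12 + hist[burn:-1] * 0.5)


class TestSolverErrors:
    def test_disconnected_windows_raise(self):
        w1 = UmbrellaWindow(0.0, 500.0,
                            np.random.default_rng(0).normal(0.0, 0.05, 500))
        w2 = UmbrellaWindow(5.0, 500.0,
                            np.random.default_rng(1).normal(5.0, 0.05, 500))
        with pytest.raises(DisconnectedDatasetError):
            wham_solve([w1, w2], WhamConfig(n_bins=100))

    def test_iteration_budget_exhaustion_raises_with_residual(self):
        rng = np.random.default_rng(6)
        windows = [UmbrellaWindow(r, 400.0, rng.normal(r, 0.12, 500))
                   for r in (0.5, 1.0, 1.5)]
        with pytest.raises(ConvergenceError) as exc:
            wham_solve(windows, WhamConfig(max_iterations=2))
        assert exc.value.residual is not None


class TestOverlap:
    def test_identical_windows_full_overlap(self):
        s = np.random.default_rng(0).normal(1.0, 0.1, 2000)
        w1 = UmbrellaWindow(1.0, 400.0, s)
        w2 = UmbrellaWindow(1.01, 400.0, s.copy())
        _, df = overlap_histograms([w1, w2], np.linspace(0.5, 1.5, 40))
        assert df["overlap"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_supports_zero_overlap(self):
        w1 = UmbrellaWindow(0.0, 400.0, np.full(100, 0.1))
        w2 = UmbrellaWindow(1.0, 400.0, np.full(100, 0.9))
        _, df = overlap_histograms([w1, w2], np.linspace(0, 1, 21))
        assert df["overlap"].iloc[0] == 0.0
        assert bool(df["flagged"].iloc[0])

    def test_gaussian_pair_matches_analytic_overlap(self):
        """Equal-sd normals separated by d overlap by 2*Phi(-d/(2*sd))."""
        rng = np.random.default_rng(7)
        sd, d = 0.1, 0.15
        w1 = UmbrellaWindow(1.0, 400.0, rng.normal(1.0, sd, 200000))
        w2 = UmbrellaWindow(1.0 + d, 400.0,
                            rng.normal(1.0 + d, sd, 200000))
        _, df = overlap_histograms([w1, w2], np.linspace(0.5, 1.8, 200))
        analytic = 2 * norm.cdf(-d / (2 * sd))
        assert df["overlap"].iloc[0] == pytest.approx(analytic, rel=0.02)


class TestBlocksAndBootstrap:
    def _windows(self, seed=8, n=1200):
        rng = np.random.default_rng(seed)
        out = []
        for r in (0.5, 0.8, 1.1):
            out.append(UmbrellaWindow(r, 400.0, rng.normal(r, 0.12, n),
                                      times_ps=np.arange(n, dtype=float),
                                      window_id=f"w{r}"))
        return out

    def test_final_block_equals_full_solution(self):
        windows = self._windows()
        cfg = WhamConfig(n_bins=40)
        profiles, _, dropped = block_convergence(windows,
                                                 [300.0, 700.0, 1199.0], cfg)
        full = wham_solve(windows, cfg)
        np.testing.assert_array_equal(profiles[-1].free_energy,
                                      full.free_energy)
        assert all(not d for d in dropped)

    def test_single_block(self):
        profiles, deltas, _ = block_convergence(self._windows(), [500.0],
                                                WhamConfig(n_bins=30))
        assert len(profiles) == 1 and deltas == []

    def test_bootstrap_deterministic_under_seed(self):
        windows = self._windows(n=400)
        cfg = WhamConfig(n_bins=25)
        a = bootstrap_pmf(windows, cfg, n_boot=4, seed=11)
        b = bootstrap_pmf(windows, cfg, n_boot=4, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_bands_shrink_with_sample_size(self):
        small = self._windows(seed=9, n=150)
        large = self._windows(seed=9, n=6000)
        cfg = WhamConfig(n_bins=25)
        sd_small = np.nanmean(bootstrap_pmf(small, cfg, n_boot=8, seed=1))
        sd_large = np.nanmean(bootstrap_pmf(large, cfg, n_boot=8, seed=1))
        assert sd_large < sd_small

    def test_single_sample_windows_tolerated(self):
        windows = [UmbrellaWindow(r, 400.0, np.array([0.52]))
                   for r in (0.5, 0.52, 0.54)]
        sd = bootstrap_pmf(windows, WhamConfig(n_bins=5), n_boot=3, seed=0)
        assert np.all(np.isfinite(sd[~np.isnan(sd)]))


class TestBindingEnergy:
    def _pmf(self, g, x=None):
        if x is None:
            x = np.linspace(0.5, 3.0, g.size)
        return PmfProfile(x, g - g.min(), "kcal/mol", np.zeros(1), 1,
                          "full", 310.0)

    def test_flat_pmf_zero_binding_energy(self):
        est = extract_binding_energy(self._pmf(np.zeros(50)))
        assert est.delta_g == pytest.approx(0.0, abs=1e-9)

    def test_well_plus_plateau_depth_recovered(self):
        x = np.linspace(0.3, 3.0, 120)
        g = np.where(x < 1.5, 5.0 * (1 - np.cos(np.pi * (x - 0.3) / 1.2)) / 2,
                     5.0)
        est = extract_binding_energy(self._pmf(g, x))
        assert est.delta_g == pytest.approx(5.0, abs=0.1)
        assert est.minimum_nm == pytest.approx(0.3, abs=0.05)

    def test_monotonically_rising_pmf_raises(self):
        x = np.linspace(0.5, 3.0, 80)
        with pytest.raises(NoPlateauError):
            extract_binding_energy(self._pmf(8.0 * x, x))

    def test_fixed_xi_readout(self):
        x = np.linspace(0.5, 3.0, 60)
        g = 2.0 * (x - 0.5)
        est = extract_binding_energy(self._pmf(g, x), at_xi_nm=2.5)
        assert est.delta_g == pytest.approx(4.0, abs=0.1)
        assert "fixed-xi" in est.criterion


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        windows = [UmbrellaWindow(r, 400.0, rng.normal(r, 0.1, 50),
                                  times_ps=np.arange(50, dtype=float),
                                  window_id=f"w{i}")
                   for i, r in enumerate((0.5, 1.0))]
        manifest = write_window_manifest(windows, tmp_path / "us")
        back = read_window_manifest(manifest)
        assert len(back) == 2
        for w0, w1 in zip(windows, back):
            assert w1.r_nm == w0.r_nm and w1.k == w0.k
            np.testing.assert_allclose(w1.samples, w0.samples, rtol=1e-6)
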