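import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from fieldpmf.errors import (
    InsufficientDataError,
    NoBarrierError,
)
from fieldpmf.structures_io import WindowSeries
from fieldpmf.synthetic_data import GeneratorSpec, sample_umbrella_windows
from fieldpmf.wham import (
    BiasSpec,
    FreeEnergyProfile,
    UmbrellaWindow,
    WhamConfig,
    barrier_from_profile,
    bootstrap_pmf,
    convergence_check,
    overlap_diagnostic,
    wham_solve,
)

R = 1.987204e-3


def _profile(values, centers=None):
    values = np.asarray(values, dtype=float)
    centers = np.arange(len(values), dtype=float) if centers is None else centers
    return FreeEnergyProfile(
        bin_centers=centers,
        pmf=values,
        pmf_std=np.zeros_like(values),
        window_offsets=np.zeros(1),
        occupied_mask=np.ones(len(values), dtype=bool),
    )


# ---------------------------------------------------------------------------
# independent maximum-likelihood WHAM oracle (gradient solve, no fixed point)
# ---------------------------------------------------------------------------

def ml_wham_oracle(windows, config):
    """Solve WHAM by direct minimisation of the pooled-histogram negative
    log-likelihood over the window offsets — an algorithmically independent
    route to the same stationary equations as the package's fixed-point
    iteration."""
    samples = [np.asarray(w.series.values, float) for w in windows]
    samples = [s[int(np.floor(config.discard_fraction * len(s))):] for s in samples]
    lo = min(s.min() for s in samples) - config.bin_width
    hi = max(s.max() for s in samples) + config.bin_width
    nbins = int(np.ceil((hi - lo) / config.bin_width))
    edges = lo + config.bin_width * np.arange(nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(nbins)
    for s in samples:
        counts += np.histogram(s, bins=edges)[0]
    occ = counts > 0
    rt = R * config.temperature
    b = np.array([w.bias.energy(centers) for w in windows]) / rt
    n_w = np.array([len(s) for s in samples], float)

    def objective(g):
        d = logsumexp(np.log(n_w)[:, None] + g[:, None] - b[:, occ], axis=0)
        val = -np.sum(n_w * g) + np.sum(counts[occ] * d)
        w = np.exp(np.log(n_w)[:, None] + g[:, None] - b[:, occ] - d[None, :])
        grad = -n_w + w @ counts[occ]
        return val, grad

    res = minimize(objective, np.zeros(len(windows)), jac=True, method="L-BFGS-B",
                   options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 5000})
    assert res.success
    g = res.x
    d = logsumexp(np.log(n_w)[:, None] + g[:, None] - b[:, occ], axis=0)
    pmf = rt * (d - np.log(counts[occ]))
    return centers[occ], pmf - pmf.min()


class TestWhamSolve:
    def test_single_unbiased_window_recovers_harmonic_potential(self):
        windows = sample_umbrella_windows(
            lambda x: 2.0 * np.asarray(x) ** 2,
            [BiasSpec(0.0, 0.0)],
            temperature=343.15,
            n_samples=100_000,
            spec=GeneratorSpec(seed=1),
            support=(-3.0, 3.0),
            stratified=True,
        )
        prof = wham_solve(windows, WhamConfig(bin_width=0.02, discard_fraction=0.0))
        m = np.abs(prof.occupied_centers) <= 1.0
        v = 2.0 * prof.occupied_centers[m] ** 2
        assert np.max(np.abs(prof.occupied_pmf[m] - (v - v.min()))) < 0.1

    def test_flat_potential_gives_flat_pmf(self):
        windows = sample_umbrella_windows(
            lambda x: np.zeros_like(np.asarray(x, float)),
            [BiasSpec(c, 10.0) for c in np.linspace(0.0, 1.0, 11)],
            temperature=343.15,
            n_samples=10_000,
            spec=GeneratorSpec(seed=3),
            support=(-3.0, 4.0),
            stratified=True,
        )
        prof = wham_solve(windows, WhamConfig(bin_width=0.02, discard_fraction=0.0))
        m = (prof.occupied_centers >= 0.0) & (prof.occupied_centers <= 1.0)
        assert np.ptp(prof.occupied_pmf[m]) < 0.1

    def test_double_well_barrier_recovery_within_bootstrap_error(
        self, double_well_windows, wham_config
    ):
        prof = wham_solve(double_well_windows, wham_config)
        dg, dg_rxn = barrier_from_profile(prof)
        bs = bootstrap_pmf(double_well_windows, wham_config)
        assert bs.barrier_std is not None
        assert abs(dg - 5.0) <= 2 * bs.barrier_std
        assert abs(dg_rxn) < 0.1  # symmetric well

    def test_matches_maximum_likelihood_oracle_per_bin(
        self, double_well_windows, wham_config, double_well_profile
    ):
        centers, pmf_oracle = ml_wham_oracle(double_well_windows, wham_config)
        np.testing.assert_allclose(centers, double_well_profile.occupied_centers)
        assert np.max(np.abs(double_well_profile.occupied_pmf - pmf_oracle)) < 0.05

    def test_minimum_is_shifted_to_zero(self, double_well_profile):
        assert np.nanmin(double_well_profile.occupied_pmf) == pytest.approx(0.0, abs=1e-12)

    def test_bias_constant_shift_invariance(self, wham_config):
        """Adding a constant to every window's restraint energy leaves the
        PMF unchanged — the per-window offsets absorb it exactly."""

        class ShiftedBias(BiasSpec):
            def energy(self, x):
                return super().energy(x) + 7.3

        windows = sample_umbrella_windows(
            lambda x: 2.0 * np.asarray(x) ** 2,
            [BiasSpec(c, 5.0) for c in np.linspace(-1.0, 1.0, 9)],
            temperature=343.15,
            n_samples=5_000,
            spec=GeneratorSpec(seed=9),
            support=(-4.0, 4.0),
            stratified=True,
        )
        shifted = [
            UmbrellaWindow(ShiftedBias(w.bias.center, w.bias.force_constant), w.series)
            for w in windows
        ]
        p1 = wham_solve(windows, wham_config)
        p2 = wham_solve(shifted, wham_config)
        np.testing.assert_allclose(p2.occupied_pmf, p1.occupied_pmf, atol=1e-8)
        np.testing.assert_allclose(
            p2.window_offsets - p1.window_offsets, 7.3, atol=1e-6
        )

    def test_half_k_flag_halves_the_effective_stiffness(self):
        b = BiasSpec(0.5, 10.0)
        h = BiasSpec(0.5, 10.0, half_k=True)
        x = np.array([0.0, 1.0])
        np.testing.assert_allclose(b.energy(x), 2 * h.energy(x))

    def test_temperature_scaling_of_unbiased_solve(self):
        """With one unbiased window, the PMF is exactly -RT ln(histogram):
        solving the same samples at 2T doubles the profile."""
        windows = sample_umbrella_windows(
            lambda x: 2.0 * np.asarray(x) ** 2,
            [BiasSpec(0.0, 0.0)],
            temperature=343.15,
            n_samples=20_000,
            spec=GeneratorSpec(seed=13),
            support=(-3.0, 3.0),
        )
        p1 = wham_solve(windows, WhamConfig(temperature=343.15, discard_fraction=0.0))
        p2 = wham_solve(windows, WhamConfig(temperature=686.30, discard_fraction=0.0))
        np.testing.assert_allclose(p2.occupied_pmf, 2.0 * p1.occupied_pmf, rtol=1e-9)

    def test_zero_overlap_warns_but_returns(self):
        t = np.arange(1, 51) * 0.001
        w1 = UmbrellaWindow(BiasSpec(0.0, 100.0), WindowSeries(t, np.linspace(-0.05, 0.05, 50)))
        w2 = UmbrellaWindow(BiasSpec(5.0, 100.0), WindowSeries(t, np.linspace(4.95, 5.05, 50)))
        with pytest.warns(UserWarning, match="zero histogram overlap"):
            prof = wham_solve([w1, w2], WhamConfig(bin_width=0.02, discard_fraction=0.0))
        assert np.sum(prof.occupied_mask) > 0


class TestBootstrap:
    def test_degenerate_point_mass_windows_have_zero_std(self):
        t = np.arange(1, 101) * 0.001
        windows = [
            UmbrellaWindow(BiasSpec(c, 10.0), WindowSeries(t, np.full(100, c)))
            for c in (0.0, 1.0)
        ]
        cfg = WhamConfig(bin_width=0.5, n_bootstrap=10, discard_fraction=0.0)
        bs = bootstrap_pmf(windows, cfg)
        occupied = ~np.isnan(bs.pmf_std)
        assert np.all(bs.pmf_std[occupied] <= 1e-12)  # identical resamples

    def test_same_seed_is_bit_reproducible(self, double_well_windows):
        cfg = WhamConfig(bin_width=0.05, n_bootstrap=8, seed=21, discard_fraction=0.0)
        a = bootstrap_pmf(double_well_windows, cfg)
        b = bootstrap_pmf(double_well_windows, cfg)
        np.testing.assert_array_equal(a.pmf_std, b.pmf_std)
        assert a.barrier_std == b.barrier_std

    def test_doubling_replicates_is_stable(self, double_well_windows):
        cfg1 = WhamConfig(bin_width=0.05, n_bootstrap=20, seed=5, discard_fraction=0.0)
        cfg2 = WhamConfig(bin_width=0.05, n_bootstrap=40, seed=5, discard_fraction=0.0)
        s1 = np.nanmean(bootstrap_pmf(double_well_windows, cfg1).pmf_std)
        s2 = np.nanmean(bootstrap_pmf(double_well_windows, cfg2).pmf_std)
        assert abs(s2 - s1) / s1 < 0.2


class TestBarrierExtraction:
    def test_three_bin_pass_through(self):
        assert barrier_from_profile(_profile([0.0, 20.4, 15.3])) == (20.4, 15.3)

    def test_binding_style_profile(self):
        assert barrier_from_profile(_profile([0.0, 10.7, 2.7])) == (10.7, 2.7)

    def test_symmetric_profile_from_either_side(self):
        p = _profile([0.0, 5.0, 0.0])
        assert barrier_from_profile(p, "left") == (5.0, 0.0)
        assert barrier_from_profile(p, "right") == (5.0, 0.0)

    def test_right_reactant_orientation(self):
        dg, dg_rxn = barrier_from_profile(_profile([0.0, 20.4, 15.3]), "right")
        assert dg == pytest.approx(20.4 - 15.3)
        assert dg_rxn == pytest.approx(-15.3)

    def test_monotonic_profile_has_no_barrier(self):
        with pytest.raises(NoBarrierError):
            barrier_from_profile(_profile([0.0, 1.0, 2.0, 3.0]))

    def test_too_few_bins(self):
        with pytest.raises(InsufficientDataError):
            barrier_from_profile(_profile([0.0, 1.0]))


class TestDiagnostics:
    def test_identical_windows_overlap_fully(self):
        t = np.arange(1, 101) * 0.001
        vals = np.linspace(-0.2, 0.2, 100)
        w = [UmbrellaWindow(BiasSpec(0.0, 10.0), WindowSeries(t, vals)) for _ in range(2)]
        ov = overlap_diagnostic(w, WhamConfig(discard_fraction=0.0))
        assert ov.min_adjacent == pytest.approx(1.0)

    def test_disjoint_windows_overlap_zero(self):
        t = np.arange(1, 101) * 0.001
        w1 = UmbrellaWindow(BiasSpec(0.0, 10.0), WindowSeries(t, np.linspace(-0.2, 0.2, 100)))
        w2 = UmbrellaWindow(BiasSpec(9.0, 10.0), WindowSeries(t, np.linspace(8.8, 9.2, 100)))
        ov = overlap_diagnostic([w1, w2], WhamConfig(discard_fraction=0.0))
        assert ov.min_adjacent == 0.0

    def test_two_gaussians_two_sigma_apart(self):
        """Closed form: the overlap of two unit Gaussians 2 sigma apart is
        2 Phi(-1) ~ 0.3173."""
        rng = np.random.default_rng(0)
        n = 100_000
        t = np.arange(1, n + 1) * 0.001
        w1 = UmbrellaWindow(BiasSpec(0.0, 0.0), WindowSeries(t, rng.normal(0.0, 1.0, n)))
        w2 = UmbrellaWindow(BiasSpec(2.0, 0.0), WindowSeries(t, rng.normal(2.0, 1.0, n)))
        ov = overlap_diagnostic([w1, w2], WhamConfig(bin_width=0.05, discard_fraction=0.0))
        assert ov.min_adjacent == pytest.approx(2 * norm.cdf(-1.0), abs=0.02)

    def test_half_split_agreement_on_exact_sampler(self, double_well_windows, wham_config):
        assert convergence_check(double_well_windows, wham_config) < 0.3

    def test_duplicated_data_halves_agree_exactly(self):
        t = np.arange(1, 201) * 0.001
        vals = np.tile(np.linspace(-0.3, 0.3, 100), 2)
        # first half == second half by construction
        w = [UmbrellaWindow(BiasSpec(0.0, 10.0), WindowSeries(t, vals))]
        cfg = WhamConfig(bin_width=0.05, discard_fraction=0.0)
        assert convergence_check(w, cfg) == 0.0

    def test_three_sample_window_is_insufficient(self):
        t = np.array([0.001, 0.002, 0.003])
        w = [UmbrellaWindow(BiasSpec(0.0, 10.0), WindowSeries(t, np.zeros(3)))]
        with pytest.raises(InsufficientDataError):
            convergence_check(w, WhamConfig(discard_fraction=0.0))
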