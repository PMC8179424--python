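import itertools

import numpy as np
import pytest

import fretdyn as fd
from fretdyn.pda import (BurstSizeDistribution, DistanceState,
                         EfficiencyHistogram, PDAModel, apparent_probability,
                         predict_histogram, proximity_histogram)
from fretdyn.kinetics import forster_efficiency, efficiency_to_distance


def _single_size_model(p_target, N, R0=65.0, **kw):
    mu = float(efficiency_to_distance(p_target, R0))
    sizes = BurstSizeDistribution(np.array([N]), np.array([1.0]))
    return PDAModel([DistanceState(mu, 0.0, 1.0)], R0, sizes, **kw)


def _enumerate_outcomes(p, N, bin_edges):
    """Exhaustive enumeration over all 2^N photon routing outcomes."""
    hist = np.zeros(len(bin_edges) - 1)
    for outcome in itertools.product((0, 1), repeat=N):
        k = sum(outcome)
        prob = p ** k * (1 - p) ** (N - k)
        idx = np.searchsorted(bin_edges, k / N, side="right") - 1
        hist[idx] += prob
    return hist


class TestForwardModel:
    @pytest.mark.parametrize("p,N", [(0.5, 10), (0.3, 7), (0.85, 12)])
    def test_matches_exhaustive_photon_enumeration(self, p, N):
        """Shot-noise histogram equals brute-force enumeration of every
        photon partition, to machine precision."""
        model = _single_size_model(p, N)
        pred = predict_histogram(model)
        oracle = _enumerate_outcomes(p, N, model.bin_edges)
        assert np.allclose(pred.counts, oracle, atol=1e-12)

    def test_midpoint_bin_probability(self):
        """All bursts N = 10 at efficiency 1/2: the bin holding F_A = 5 has
        probability C(10,5)/2^10."""
        model = _single_size_model(0.5, 10)
        pred = predict_histogram(model)
        idx = np.searchsorted(model.bin_edges, 0.5, side="right") - 1
        assert pred.counts[idx] == pytest.approx(252 / 1024, abs=1e-12)

    def test_normalisation_across_models(self):
        sizes = BurstSizeDistribution(np.array([20, 50, 120]),
                                      np.array([0.3, 0.4, 0.3]))
        model = PDAModel([DistanceState(45.0, 2.0, 0.6),
                          DistanceState(60.0, 4.0, 0.4)], 65.0, sizes,
                         bg_D=1.5, bg_A=2.0, alpha=0.05)
        assert predict_histogram(model).counts.sum() == pytest.approx(1.0)

    def test_degenerate_mixture_equals_single_state(self):
        sizes = BurstSizeDistribution(np.array([30, 80]), np.array([0.5, 0.5]))
        single = PDAModel([DistanceState(50.0, 2.0, 1.0)], 65.0, sizes)
        mixed = PDAModel([DistanceState(50.0, 2.0, 1.0),
                          DistanceState(70.0, 3.0, 0.0),
                          DistanceState(40.0, 1.0, 0.0)], 65.0, sizes)
        assert np.allclose(predict_histogram(single).counts,
                           predict_histogram(mixed).counts, atol=1e-12)

    def test_well_separated_states_give_two_modes(self):
        sizes = BurstSizeDistribution(np.array([150]), np.array([1.0]))
        mus = efficiency_to_distance(np.array([0.2, 0.8]), 65.0)
        model = PDAModel([DistanceState(mus[0], 0.0, 0.5),
                          DistanceState(mus[1], 0.0, 0.5)], 65.0, sizes)
        dens = predict_histogram(model).counts
        centers = 0.5 * (model.bin_edges[:-1] + model.bin_edges[1:])
        lo = dens[np.abs(centers - 0.2) < 0.05].max()
        hi = dens[np.abs(centers - 0.8) < 0.05].max()
        mid = dens[np.abs(centers - 0.5) < 0.08].max()
        assert lo > 5 * mid and hi > 5 * mid

    def test_sigma_widens_distribution(self):
        sizes = BurstSizeDistribution(np.array([100]), np.array([1.0]))
        centers = None
        variances = []
        for sigma in (0.0, 2.0, 5.0):
            model = PDAModel([DistanceState(55.0, sigma, 1.0)], 65.0, sizes)
            dens = predict_histogram(model).counts
            centers = 0.5 * (model.bin_edges[:-1] + model.bin_edges[1:])
            m = (dens * centers).sum()
            variances.append((dens * (centers - m) ** 2).sum())
        assert variances[0] < variances[1] < variances[2]

    def test_empty_size_distribution_rejected(self):
        with pytest.raises(ValueError):
            BurstSizeDistribution(np.array([]), np.array([]))

    def test_background_convolution_against_monte_carlo(self):
        """Poisson background added to both channels: forward model matches
        a direct Monte-Carlo simulation of the counting process."""
        rng = np.random.default_rng(0)
        N, p, lam = 60, 0.7, 3.0
        model = _single_size_model(p, N, bg_D=lam, bg_A=lam)
        pred = predict_histogram(model)
        n_mc = 400_000
        a = rng.poisson(lam, n_mc)
        d = rng.poisson(lam, n_mc)
        sig = np.maximum(N - a - d, 0)
        fa = a + rng.binomial(sig, p)
        h, _ = np.histogram(np.minimum(fa, N) / N, bins=model.bin_edges)
        assert np.allclose(pred.counts, h / n_mc, atol=4e-3)


class TestForwardConsistencyWithSimulator:
    def test_simulated_bursts_match_prediction(self, three_state_burst_table):
        """Histogram of generator bursts converges to the forward model
        evaluated at the generating parameters (KS distance small)."""
        from fretdyn.workflows import STATE_MU_R, STATE_SIGMA_R, condition_weights
        from fretdyn.bursts import window_extension

        mid, cfg = three_state_burst_table
        hist = proximity_histogram(mid["F_DA"], mid["F_DD"])
        sizes = BurstSizeDistribution.from_counts(
            (mid["F_DA"] + mid["F_DD"]).to_numpy(), mid["duration"].to_numpy())
        ell = window_extension(mid["n_photons"], mid["duration"], 20, 5e-4)
        bg = 1000.0 * (mid["duration"].mean() + 2 * ell)
        w = condition_weights(1.61, 0.20)
        model = PDAModel([DistanceState(m, s, wi) for m, s, wi in
                          zip(STATE_MU_R, STATE_SIGMA_R, w)], 65.0, sizes,
                         bg_D=bg, bg_A=bg, alpha=cfg.alpha)
        pred = predict_histogram(model)
        ks = np.abs(np.cumsum(hist.density) - np.cumsum(pred.counts)).max()
        assert ks < 0.03


@pytest.fixture(scope="module")
def two_state_fixture():
    """10^4 bursts drawn from a known 2-state model."""
    rng = np.random.default_rng(5)
    sizes = BurstSizeDistribution(np.array([60, 100, 160, 240]),
                                  np.array([0.3, 0.3, 0.25, 0.15]))
    truth = PDAModel([DistanceState(45.0, 2.0, 0.5),
                      DistanceState(55.0, 2.0, 0.5)], 65.0, sizes)
    pred = predict_histogram(truth)
    counts = rng.multinomial(10_000, pred.counts).astype(float)
    hist = EfficiencyHistogram(pred.bin_edges, counts, 10_000)
    return hist, sizes


class TestFitting:
    def test_free_fit_recovers_two_state_model(self, two_state_fixture):
        hist, sizes = two_state_fixture
        fit = fd.fit_pda(hist, 2, R0=65.0, burst_sizes=sizes, seed=0,
                         n_starts=10)
        mus = sorted(s.mu_R for s in fit.model.states)
        ws = [s.weight for s in fit.model.states]
        assert abs(mus[0] - 45.0) < 1.0 and abs(mus[1] - 55.0) < 1.0
        assert all(abs(w - 0.5) < 0.05 for w in ws)

    def test_nested_model_dominance(self, two_state_fixture):
        hist, sizes = two_state_fixture
        f1 = fd.fit_pda(hist, 1, R0=65.0, burst_sizes=sizes, seed=0, n_starts=6)
        f2 = fd.fit_pda(hist, 2, R0=65.0, burst_sizes=sizes, seed=0, n_starts=6)
        assert f1.chi2_red > f2.chi2_red

    def test_constrained_fit_recovers_weights(self, two_state_fixture):
        hist, sizes = two_state_fixture
        fit = fd.fit_pda(hist, 2, R0=65.0, burst_sizes=sizes,
                         fixed_mu=np.array([45.0, 55.0]), seed=0)
        for s in fit.model.states:
            assert abs(s.weight - 0.5) < 0.03
            assert abs(s.sigma_R - 2.0) < 1.0


class TestModelSelection:
    def test_single_state_data_selects_one(self):
        rng = np.random.default_rng(2)
        sizes = BurstSizeDistribution(np.array([80, 150]), np.array([0.6, 0.4]))
        truth = PDAModel([DistanceState(55.0, 2.0, 1.0)], 65.0, sizes)
        counts = rng.multinomial(4000, predict_histogram(truth).counts).astype(float)
        hist = EfficiencyHistogram(truth.bin_edges, counts, 4000)
        k, _ = fd.select_n_states(hist, K_max=3, R0=65.0, burst_sizes=sizes,
                                  seed=0, n_starts=6)
        assert k == 1

    def test_under_resolved_close_states_prefer_one(self):
        """Two states closer than shot noise at small N are not resolvable;
        the criterion must not overfit."""
        rng = np.random.default_rng(3)
        sizes = BurstSizeDistribution(np.array([15]), np.array([1.0]))
        truth = PDAModel([DistanceState(53.0, 0.0, 0.5),
                          DistanceState(57.0, 0.0, 0.5)], 65.0, sizes)
        counts = rng.multinomial(2000, predict_histogram(truth).counts).astype(float)
        hist = EfficiencyHistogram(truth.bin_edges, counts, 2000)
        k, _ = fd.select_n_states(hist, K_max=3, R0=65.0, burst_sizes=sizes,
                                  seed=0, n_starts=6)
        assert k == 1


class TestStateRatioAndFiltering:
    def test_ratio_arithmetic(self):
        sizes = BurstSizeDistribution(np.array([50]), np.array([1.0]))
        model = PDAModel([DistanceState(70.0, 2.0, 0.2),
                          DistanceState(55.0, 2.0, 0.5),
                          DistanceState(45.0, 2.0, 0.3)], 65.0, sizes)
        w = model.weights
        assert w[2] / w[1] == pytest.approx(0.6)

    def test_symmetric_weights_unit_ratio(self):
        rng = np.random.default_rng(4)
        sizes = BurstSizeDistribution(np.array([120]), np.array([1.0]))
        truth = PDAModel([DistanceState(45.0, 1.0, 0.5),
                          DistanceState(58.0, 1.0, 0.5)], 65.0, sizes)
        counts = rng.multinomial(6000, predict_histogram(truth).counts).astype(float)
        hist = EfficiencyHistogram(truth.bin_edges, counts, 6000)
        fit = fd.fit_pda(hist, 2, R0=65.0, burst_sizes=sizes,
                         fixed_mu=np.array([45.0, 58.0]), seed=0)
        res = fd.state_ratio(fit, 0, 1, n_boot=20, seed=0)
        assert abs(res["ratio"] - 1.0) < 0.1
        assert res["ci_low"] < 1.0 < res["ci_high"]

    def test_shot_noise_filtered_expectations(self):
        sizes = BurstSizeDistribution(np.array([50]), np.array([1.0]))
        model = PDAModel([DistanceState(50.0, 0.0, 0.5),
                          DistanceState(60.0, 3.0, 0.5)], 65.0, sizes)
        res = fd.shot_noise_filtered_distribution(model)
        assert res["expectations"][0] == pytest.approx(50.0)
        assert res["expectations"][1] == pytest.approx(60.0)
        # densities normalised on the grid
        dr = res["r_grid"][1] - res["r_grid"][0]
        assert res["total_density"].sum() * dr == pytest.approx(1.0, abs=0.01)

    def test_efficiency_distance_midpoint(self):
        assert efficiency_to_distance(0.5, 65.0) == pytest.approx(65.0)
        assert forster_efficiency(130.0, 65.0) == pytest.approx(1 / 65)

    def test_apparent_probability_includes_leakage(self):
        # at zero transfer only leakage routes photons to the red channel
        assert apparent_probability(1e6, 65.0, alpha=0.05) == pytest.approx(
            0.05 / 1.05, rel=1e-6)
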