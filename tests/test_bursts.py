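import numpy as np
import pytest

import fretdyn as fd
from fretdyn.bursts import (Burst, correct_counts, compute_ES,
                            estimate_burst_lifetime, truncated_exp_mean)
from fretdyn.photonsim import PhotonStream


def _stream_from_times(times, channels=None):
    times = np.asarray(times, float)
    ch = np.zeros(len(times), np.int8) if channels is None else np.asarray(channels, np.int8)
    order = np.argsort(times)
    return PhotonStream(times[order], ch[order], np.zeros(len(times)))


def _brute_force_in_burst(times, m, T):
    times = np.sort(np.asarray(times, float))
    return np.array([np.sum(np.abs(times - t) <= T / 2.0) >= m for t in times])


class TestFindBursts:
    def test_two_clusters_found_against_brute_force(self):
        rng = np.random.default_rng(0)
        cluster1 = 0.010 + np.arange(100) * 1e-6
        cluster2 = 0.050 + np.arange(100) * 1e-6
        bg = rng.uniform(0, 0.1, 10)        # ~100 Hz background
        times = np.concatenate([cluster1, cluster2, bg])
        stream = _stream_from_times(times)
        bursts = fd.find_bursts(stream, m=10, T=500e-6, L_min=50)
        assert len(bursts) == 2
        assert all(b.n_photons >= 100 for b in bursts)

        in_burst = _brute_force_in_burst(times, 10, 500e-6)
        n_in = sum(b.n_photons for b in bursts)
        assert n_in == in_burst.sum()

    def test_pure_background_gives_no_bursts(self):
        rng = np.random.default_rng(1)
        stream = _stream_from_times(rng.uniform(0, 10, 1000))  # 100 Hz
        assert fd.find_bursts(stream, m=10, T=500e-6, L_min=50) == []

    def test_l_min_filter_dominates(self):
        times = 0.01 + np.arange(40) * 1e-6
        stream = _stream_from_times(times)
        assert fd.find_bursts(stream, m=10, T=500e-6, L_min=50) == []

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        times = np.sort(np.concatenate([0.02 + np.arange(200) * 2e-6,
                                        rng.uniform(0, 0.2, 50)]))
        s1 = _stream_from_times(times)
        s2 = _stream_from_times(times + 5.0)
        b1 = fd.find_bursts(s1)
        b2 = fd.find_bursts(s2)
        assert len(b1) == len(b2) == 1
        assert b1[0].n_photons == b2[0].n_photons
        assert b2[0].t_start == pytest.approx(b1[0].t_start + 5.0)

    def test_empty_stream(self):
        stream = _stream_from_times([])
        assert fd.find_bursts(stream) == []


class TestCorrections:
    def test_crosstalk_correction_hand_value(self):
        b = Burst(0, 150, 0.0, 1e-3, F_DD=60, F_DA=40, F_AA=50)
        cf = fd.CorrectionFactors(alpha=0.05, delta=0.10)
        correct_counts(b, cf)
        assert b.F_DA_corr == pytest.approx(40 - 3 - 5)

    def test_identity_when_no_corrections(self):
        b = Burst(0, 150, 0.0, 1e-3, F_DD=60, F_DA=40, F_AA=50)
        correct_counts(b, fd.CorrectionFactors())
        assert (b.F_DD_corr, b.F_DA_corr, b.F_AA_corr) == (60, 40, 50)

    def test_zero_duration_rejected(self):
        b = Burst(0, 150, 1.0, 1.0, F_DD=60, F_DA=40, F_AA=50)
        with pytest.raises(ValueError):
            correct_counts(b, fd.CorrectionFactors())

    def test_negative_counts_flagged_not_fatal(self):
        b = Burst(0, 10, 0.0, 1e-3, F_DD=2, F_DA=1, F_AA=0)
        cf = fd.CorrectionFactors(bg_rates={"DD": 5000.0, "DA": 0.0, "AA": 0.0})
        correct_counts(b, cf)
        assert b.negative_counts

    def test_es_hand_value_and_boundaries(self):
        b = Burst(0, 150, 0.0, 1e-3, F_DD=60, F_DA=32, F_AA=50)
        e, s = compute_ES(b, fd.CorrectionFactors(gamma_=1.2))
        assert e == pytest.approx(32 / (32 + 1.2 * 60))

        b0 = Burst(0, 10, 0.0, 1e-3, F_DD=50, F_DA=0, F_AA=10)
        assert compute_ES(b0, fd.CorrectionFactors())[0] == 0.0
        b1 = Burst(0, 10, 0.0, 1e-3, F_DD=0, F_DA=50, F_AA=10)
        assert compute_ES(b1, fd.CorrectionFactors())[0] == 1.0

    def test_donor_only_stoichiometry_limit(self):
        b = Burst(0, 10, 0.0, 1e-3, F_DD=80, F_DA=20, F_AA=0)
        _, s = compute_ES(b, fd.CorrectionFactors())
        assert s == pytest.approx(1.0)

    def test_zero_signal_burst_rejected(self):
        b = Burst(0, 10, 0.0, 1e-3, F_DD=0, F_DA=0, F_AA=10)
        with pytest.raises(ZeroDivisionError):
            compute_ES(b, fd.CorrectionFactors())


class TestLifetime:
    def test_mle_recovers_exponential_lifetime(self):
        rng = np.random.default_rng(0)
        tau, period = 2.0, 25.0
        raw = rng.exponential(tau, 20000)
        sample = raw[raw < period][:10000]
        est, err, low = estimate_burst_lifetime(sample, period)
        assert abs(est - tau) < 0.05
        assert err == pytest.approx(est / 100.0)
        assert not low

    def test_degenerate_zero_sample(self):
        est, _, _ = estimate_burst_lifetime(np.zeros(50), 25.0)
        assert est == 0.0

    def test_truncation_correction_beats_naive_mean(self):
        """Near the excitation period the naive mean is biased low; the
        corrected estimator stays within 5%."""
        rng = np.random.default_rng(1)
        tau, period = 10.0, 25.0
        raw = rng.exponential(tau, 400000)
        sample = raw[raw < period][:100000]
        est, _, _ = estimate_burst_lifetime(sample, period)
        assert abs(est - tau) / tau < 0.05
        assert sample.mean() < 0.8 * tau  # naive estimator clearly biased

    def test_few_photons_flagged(self):
        est, _, low = estimate_burst_lifetime(np.array([1.0, 2.0]), 25.0)
        assert low

    def test_truncated_mean_formula(self):
        # against numerical integration
        tau, period = 3.0, 25.0
        x = np.linspace(0, period, 200001)
        pdf = np.exp(-x / tau)
        num = np.trapezoid(x * pdf, x) / np.trapezoid(pdf, x)
        assert truncated_exp_mean(tau, period) == pytest.approx(num, rel=1e-6)


class TestFretLines:
    def test_static_line_endpoints(self):
        lines = fd.fret_lines(4.0, 1.0, 3.0)
        assert lines.static_line(4.0) == pytest.approx(0.0)
        assert lines.static_line(0.0) == pytest.approx(1.0)

    def test_dynamic_line_endpoints_on_static_line(self):
        lines = fd.fret_lines(4.0, 1.0, 3.0)
        assert lines.dynamic_line(1.0) == pytest.approx(lines.static_line(1.0))
        assert lines.dynamic_line(3.0) == pytest.approx(lines.static_line(3.0))

    def test_dynamic_line_hand_value_and_curvature(self):
        lines = fd.fret_lines(4.0, 1.0, 3.0)
        assert lines.dynamic_line(2.0) == pytest.approx(0.625)
        ts = np.linspace(1.0, 3.0, 21)
        assert np.all(lines.dynamic_line(ts)[1:-1] > lines.static_line(ts)[1:-1])

    def test_dynamic_curvature_against_two_species_mixing(self):
        """Brute-force oracle: mixing two static exponential species with
        varying fractions traces intensity-weighted (tau, E) points that lie
        on the dynamic line."""
        tau_d0, tau1, tau2 = 4.0, 1.0, 3.0
        lines = fd.fret_lines(tau_d0, tau1, tau2)
        for x1 in (0.2, 0.5, 0.8):
            x2 = 1.0 - x1
            # species-averaged donor quantum-yield weighting
            tau_mean = (x1 * tau1 ** 2 + x2 * tau2 ** 2) / (x1 * tau1 + x2 * tau2)
            e_mix = 1.0 - (x1 * tau1 + x2 * tau2) / tau_d0
            assert lines.dynamic_line(tau_mean) == pytest.approx(e_mix, abs=1e-12)

    def test_domain_errors(self):
        lines = fd.fret_lines(4.0, 1.0, 3.0)
        with pytest.raises(ValueError):
            lines.dynamic_line(0.5)
        with pytest.raises(ValueError):
            fd.fret_lines(4.0, 5.0, 3.0)


def test_burst_table_scatters_on_static_line(clean_single_state_stream):
    """Static single-state data: mean (E, tau_DA) lies on the static FRET
    line within statistical scatter."""
    stream, cfg = clean_single_state_stream
    df = fd.process_bursts(stream, fd.CorrectionFactors(), estimate_lifetimes=True)
    mid = df[df["species"] == "mid"]
    lines = fd.fret_lines(cfg.tau_D0, cfg.tau_D0 / 2, cfg.tau_D0 * 0.999)
    e_pred = lines.static_line(mid["tau_DA"].median())
    assert abs(mid["E"].mean() - e_pred) < 0.05
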