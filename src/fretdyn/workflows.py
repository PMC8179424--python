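"""End-to-end parameter-recovery workflows.

These functions define the synthetic study conditions — the kinetic schemes,
measurement settings and analysis settings under which the pipeline is
expected to recover its own generating parameters — and run the full chain
(simulate -> burst search -> PDA fit / FCS global fit) at one call.

Two experiments are covered:

* **State-population recovery** (:func:`recover_state_ratio`): a three-state
  scheme (open / closed A / contracted closed B) in the quasi-static
  exchange regime; a constrained PDA fit recovers the closed-B/closed-A
  weight ratio.  Preset nucleotide-condition ratios follow the values this
  package's validation targets: apo 0.23 (open weight 0.40), ATPγS 1.21
  (0.25), AMPPNP 1.61 (0.20).
* **Exchange-timescale recovery** (:func:`recover_fcs_timescales`): a
  four-state scheme built as the product of two independent symmetric
  two-state (telegraph) switches with relaxation times 1 μs and 60 μs, each
  contributing a 10% kinetic weight to the FRET-channel correlation; a
  three-channel global FCS fit recovers times, weights and the
  anti-correlated donor-FRET cross-correlation signature.
"""

from __future__ import annotations

import numpy as np

from .bursts import CorrectionFactors, process_bursts, window_extension
from .fcs import correlate, global_fit
from .kinetics import KineticScheme, efficiency_to_distance, three_state_scheme
from .pda import (BurstSizeDistribution, fit_pda, proximity_histogram,
                  state_ratio)
from .photonsim import SimConfig, simulate_photon_stream

#: preset closed-B/closed-A ratios and open-state weights per condition
STATE_RATIO_CONDITIONS = {
    "apo": {"ratio": 0.23, "open_weight": 0.40},
    "ATPgS": {"ratio": 1.21, "open_weight": 0.25},
    "AMPPNP": {"ratio": 1.61, "open_weight": 0.20},
}

#: state mean distances, Å (open, closed A, closed B) and widths
STATE_MU_R = (75.0, 55.0, 45.0)
STATE_SIGMA_R = (3.0, 2.0, 2.0)


def condition_weights(ratio: float, open_weight: float) -> np.ndarray:
    """(open, closedA, closedB) stationary weights for a given B/A ratio."""
    w_a = (1.0 - open_weight) / (1.0 + ratio)
    return np.array([open_weight, w_a, ratio * w_a])


def recover_state_ratio(ratio: float, open_weight: float, seed: int,
                        duration: float = 5200.0, n_boot: int = 40,
                        m: int = 20, T: float = 5e-4,
                        R0: float = 65.0) -> dict:
    """Simulate bursts at a planted closed-B/closed-A ratio and recover it
    with a mean-constrained three-state PDA fit.

    The scheme exchanges far slower than a transit (quasi-static bursts) and
    the sample is dilute (2.5 bursts/s), the regime in which burst-wise PDA
    weights estimate state populations.  Background exposure per burst is
    corrected for the sliding-window span extension.
    """
    scheme = three_state_scheme(condition_weights(ratio, open_weight),
                                STATE_MU_R, STATE_SIGMA_R, relax_rate=1.0)
    cfg = SimConfig(duration=duration, seed=seed, burst_rate=2.5,
                    delta=0.0, R0=R0)
    stream = simulate_photon_stream(scheme, cfg)
    cf = CorrectionFactors(alpha=cfg.alpha, delta=0.0,
                           bg_rates=cfg.background_rates)
    bursts = process_bursts(stream, cf, m=m, T=T, estimate_lifetimes=False)
    mid = bursts[bursts["species"] == "mid"]

    hist = proximity_histogram(mid["F_DA"], mid["F_DD"])
    sizes = BurstSizeDistribution.from_counts(
        (mid["F_DA"] + mid["F_DD"]).to_numpy(), mid["duration"].to_numpy())
    ell = window_extension(mid["n_photons"], mid["duration"], m, T)
    exposure = mid["duration"].mean() + 2.0 * ell
    bg = cfg.background_rates["DD"] * exposure
    fit = fit_pda(hist, 3, R0=R0, burst_sizes=sizes, bg_D=bg, bg_A=bg,
                  alpha=cfg.alpha, fixed_mu=np.asarray(STATE_MU_R), seed=0)
    # states sorted by mean: [closedB(45), closedA(55), open(75)]
    res = state_ratio(fit, a=1, b=0, n_boot=n_boot, seed=seed + 1)
    res.update({"n_bursts": len(mid), "chi2_red": fit.chi2_red,
                "weights": fit.model.weights, "fit": fit,
                "truth": ratio})
    return res


def two_timescale_scheme(tau_fast: float = 1e-6, tau_slow: float = 60e-6,
                         weight: float = 0.10, eps0: float = 0.54,
                         R0: float = 65.0) -> KineticScheme:
    """Four-state scheme as a product of two symmetric telegraph switches.

    Each switch multiplies the FRET efficiency by (1 ± a); for a symmetric
    telegraph with relaxation time tau the correlation contributes
    a^2 exp(-t/tau), so a is chosen to give each term the requested relative
    weight a^2/(1 + 2 a^2) in the FRET-channel correlation.
    """
    if not 0 < weight < 0.5:
        raise ValueError("weight must lie in (0, 0.5)")
    a = np.sqrt(weight / (1.0 - 2.0 * weight))
    eps = np.array([eps0 * (1 + sl * a) * (1 + sk * a)
                    for sl in (-1, 1) for sk in (-1, 1)])
    if np.any(eps >= 1.0):
        raise ValueError("efficiency modulation exceeds 1; lower eps0 or weight")
    mu = efficiency_to_distance(eps, R0)
    r_fast, r_slow = 1.0 / (2 * tau_fast), 1.0 / (2 * tau_slow)
    q = np.zeros((4, 4))
    for l in range(2):
        for k in range(2):
            i = 2 * l + k
            q[i, 2 * l + (1 - k)] = r_fast
            q[i, 2 * (1 - l) + k] = r_slow
    return KineticScheme([f"{'lh'[l]}{'lh'[k]}" for l in range(2) for k in range(2)],
                         mu, np.zeros(4), q)


def recover_fcs_timescales(seed: int, duration: float = 100.0,
                           tau_fast: float = 1e-6, tau_slow: float = 60e-6,
                           weight: float = 0.10, brightness: float = 3e5,
                           segments: int = 10) -> dict:
    """Simulate a two-timescale exchange stream, correlate three channel
    pairs and recover the shared kinetic times by a global fit.

    Burst durations follow the diffusive-transit distribution so the
    diffusion factor of the fit model is well specified; channels are
    crosstalk-free so the planted kinetic weight is the stream's actual
    FRET-channel weight.
    """
    scheme = two_timescale_scheme(tau_fast, tau_slow, weight)
    cfg = SimConfig(duration=duration, seed=seed, burst_rate=20.0,
                    brightness=brightness, alpha=0.0, delta=0.0,
                    burst_mean_duration=2e-3, burst_duration_model="diffusive")
    stream = simulate_photon_stream(scheme, cfg)
    curves = {p: correlate(stream, p, segments=segments)
              for p in ("DonxDon", "FRETxFRET", "DonxFRET")}
    fit = global_fit(curves, n_terms=2, fit_range=(0, 2e-3))
    weights_fret = fit.kinetic_weights("FRETxFRET")
    cross_amps = [a for a, _ in fit.models["DonxFRET"].kinetic_terms]
    return {
        "tau_fast_us": fit.shared_taus[0] * 1e6,
        "tau_slow_us": fit.shared_taus[-1] * 1e6,
        "weight_slow_pct": float(weights_fret[-1] * 100.0),
        "weight_fast_pct": float(weights_fret[0] * 100.0),
        "cross_amplitudes": cross_amps,
        "chi2_red": fit.chi2_red,
        "curves": curves,
        "fit": fit,
        "truth": {"tau_fast_us": tau_fast * 1e6, "tau_slow_us": tau_slow * 1e6,
                  "weight_pct": weight * 100.0},
    }
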