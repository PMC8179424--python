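"""Synthetic confocal smFRET photon streams with PIE excitation.

Emulates a dilute-sample two-colour confocal experiment: molecules diffuse
through the focus producing photon bursts, donor-excited photons are routed
to the donor (DD) or FRET (DA) channel according to the Förster efficiency
of the current hidden conformational state, and acceptor-excitation slots
produce AA photons used for stoichiometry.  Bursts are rectangular (constant
peak brightness over an exponential transit time); the hidden state evolves
by exact stochastic simulation during each burst and is resampled from the
stationary distribution at each burst start (every burst is a fresh
molecule).  Spectral crosstalk (donor leakage ``alpha``), acceptor direct
excitation (``delta``), detection-efficiency imbalance (``gamma_``),
excitation-flux imbalance (``beta_``) and uniform per-channel background are
modelled so that the standard burst-correction chain inverts them exactly in
expectation.

Randomness: one root seed spawns independent child streams in documented
order (burst placement, state paths, photon routing, microtimes,
background), so every component is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .kinetics import KineticScheme, forster_efficiency, simulate_state_path

# fixed channel alphabet
DD, DA, AA = 0, 1, 2
CHANNEL_LABELS = {"DD": DD, "DA": DA, "AA": AA}
BACKGROUND_STATE = -1


@dataclass
class SimConfig:
    """Measurement and photophysics parameters of the synthetic experiment.

    Dye constants default to values typical for a mid-60-Å Förster-radius
    pair (Atto550/Atto647N class): ``R0`` 65 Å, donor-only lifetime 3.5 ns.
    Brightness and background defaults (1e5 counts/s peak, 1 kHz/channel)
    are generator choices for a realistic confocal setting.
    """

    R0: float = 65.0                 # Förster radius, Å
    tau_D0: float = 3.5              # donor-only lifetime, ns
    tau_A: float = 3.0               # acceptor lifetime, ns
    brightness: float = 1e5         # peak detected photon rate per molecule, counts/s
    background_rates: dict = field(
        default_factory=lambda: {"DD": 1000.0, "DA": 1000.0, "AA": 1000.0})
    alpha: float = 0.05              # donor leakage fraction
    delta: float = 0.05              # acceptor direct-excitation fraction
    gamma_: float = 1.0              # detection/quantum-yield factor
    beta_: float = 1.0               # excitation-flux normalisation
    pie_period: float = 50.0         # ns; donor half [0, T/2), acceptor half [T/2, T)
    burst_mean_duration: float = 2e-3   # s; tau_diff when model="diffusive"
    burst_rate: float = 10.0         # bursts per second (dilute: rare pile-up)
    burst_duration_model: str = "exponential"   # or "diffusive"
    focus_kappa: float = 5.0         # focal aspect ratio for "diffusive"
    duration: float = 60.0           # total stream length, s
    dark_fraction: float = 0.0       # optional static acceptor-dark molecule fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.R0, self.tau_D0, self.tau_A, self.brightness,
               self.pie_period, self.burst_mean_duration, self.burst_rate,
               self.duration) <= 0:
            raise ValueError("rates, durations and dye constants must be positive")
        if not (0 <= self.alpha < 1 and 0 <= self.delta < 1):
            raise ValueError("alpha and delta must lie in [0, 1)")
        if self.gamma_ <= 0 or self.beta_ <= 0:
            raise ValueError("gamma_ and beta_ must be positive")
        if any(v < 0 for v in self.background_rates.values()):
            raise ValueError("background rates must be non-negative")
        if self.pie_period / 2.0 < 5.0 * max(self.tau_D0, self.tau_A):
            warnings.warn(
                "PIE half-period shorter than ~5 fluorescence lifetimes: "
                "microtime truncation will bias lifetime estimates",
                stacklevel=2)


@dataclass
class PhotonStream:
    """Time-ordered photon records.

    ``macrotime`` in seconds (sorted), ``channel`` in {DD, DA, AA},
    ``microtime`` the TCSPC delay in ns within the PIE period, and
    ``state_truth`` the hidden conformational state index of the emitting
    molecule (−1 for background), kept only for validation.
    """

    macrotime: np.ndarray
    channel: np.ndarray
    microtime: np.ndarray
    state_truth: np.ndarray | None = None
    pie_period: float = 50.0
    duration: float | None = None

    def __len__(self) -> int:
        return len(self.macrotime)

    def select(self, channel: int | str) -> np.ndarray:
        """Macrotimes of one detection channel."""
        code = CHANNEL_LABELS[channel] if isinstance(channel, str) else channel
        return self.macrotime[self.channel == code]

    def microtimes_of(self, channel: int | str) -> np.ndarray:
        code = CHANNEL_LABELS[channel] if isinstance(channel, str) else channel
        return self.microtime[self.channel == code]


def _sample_diffusive_durations(rng: np.random.Generator, n: int,
                                tau_d: float, kappa: float) -> np.ndarray:
    """Transit durations whose rectangular-burst on/off correlation equals
    the 3D Gaussian-focus diffusion factor.

    For Poisson-started rectangular pulses the normalised intensity
    correlation is proportional to E[(D - tau)+], so choosing the duration
    survival function 1 - F(tau) = G'(tau)/G'(0), with
    G(tau) = (1+tau/tau_d)^-1 (1+tau/(kappa^2 tau_d))^-1/2, makes the
    stream's burst-structure correlation exactly G (in expectation) and the
    diffusion term of an FCS fit well specified.
    """
    grid = tau_d * np.logspace(-4, 3, 4000)
    g = 1.0 / (1.0 + grid / tau_d) / np.sqrt(1.0 + grid / (kappa ** 2 * tau_d))
    rate = 1.0 / (tau_d + grid) + 0.5 / (kappa ** 2 * tau_d + grid)
    surv = g * rate / (1.0 / tau_d + 0.5 / (kappa ** 2 * tau_d))
    cdf = 1.0 - surv
    u = rng.random(n) * cdf[-1]
    return np.interp(u, cdf, grid)


def _truncated_exp(rng: np.random.Generator, tau: np.ndarray, limit: float) -> np.ndarray:
    """Exponential delays with scale ``tau`` conditioned on being < ``limit``
    (photons arriving after the excitation window are wrapped by TCSPC)."""
    u = rng.random(tau.shape if np.ndim(tau) else 1)
    cdf_max = -np.expm1(-limit / tau)
    return -tau * np.log1p(-u * cdf_max)


def simulate_photon_stream(
    scheme: KineticScheme, cfg: SimConfig, rng: np.random.Generator | None = None
) -> PhotonStream:
    """Generate a PIE photon stream for molecules exchanging per ``scheme``.

    Per burst: a Poisson number of photons at the peak brightness, uniform
    arrival times over the rectangular transit, excitation slot split evenly
    between donor and acceptor PIE halves.  Each donor-excited photon is
    emitted by the acceptor with probability E(R_state) and routed through
    leakage/detection thinning; AA photons come from acceptor-excitation
    slots; direct excitation adds Poisson extra DA photons proportional to
    the burst's AA count.  DD microtimes are exponential with the apparent
    lifetime tau_D0 * (1 − E_state).
    """
    root = np.random.default_rng(cfg.seed) if rng is None else rng
    # documented child-stream order
    r_burst, r_state, r_route, r_micro, r_bg = root.spawn(5)

    pi = scheme.stationary_distribution()
    half = cfg.pie_period / 2.0

    # --- burst placement: exponential waiting times, exponential durations
    n_exp = max(16, int(cfg.duration * cfg.burst_rate * 2))
    waits = r_burst.exponential(1.0 / cfg.burst_rate, size=n_exp)
    starts = np.cumsum(waits)
    starts = starts[starts < cfg.duration]
    if cfg.burst_duration_model == "diffusive":
        durs = _sample_diffusive_durations(r_burst, starts.size,
                                           cfg.burst_mean_duration, cfg.focus_kappa)
    else:
        durs = r_burst.exponential(cfg.burst_mean_duration, size=starts.size)
    durs = np.minimum(durs, cfg.duration - starts)
    dark = r_burst.random(starts.size) < cfg.dark_fraction

    # detection thinning implementing gamma_ = eta_A / eta_D
    eta_A = min(1.0, cfg.gamma_)
    eta_D = min(1.0, 1.0 / cfg.gamma_)
    # a detected donor-emission photon leaks to DA with prob alpha/(1+alpha)
    # so that E[leak] = alpha * E[F_DD]
    p_leak = cfg.alpha / (1.0 + cfg.alpha)

    times, chans, micros, truth = [], [], [], []

    for t0, dur, is_dark in zip(starts, durs, dark):
        n_phot = r_burst.poisson(cfg.brightness * dur)
        if n_phot == 0:
            continue
        path = simulate_state_path(scheme, dur, r_state)
        # distance drawn from the state's Gaussian once per dwell (static
        # heterogeneity within a state, the PDA picture)
        r_dwell = r_state.normal(scheme.mu_R[path.states],
                                 scheme.sigma_R[path.states])
        r_dwell = np.maximum(r_dwell, 1.0)
        t = np.sort(r_route.random(n_phot) * dur)
        dwell_idx = np.clip(np.searchsorted(path.t_start, t, side="right") - 1,
                            0, len(path.states) - 1)
        st = path.states[dwell_idx]
        eps = forster_efficiency(r_dwell[dwell_idx], cfg.R0)
        if is_dark:
            eps = np.zeros_like(eps)
        # PIE slot: donor half vs acceptor half
        donor_slot = r_route.random(n_phot) < 0.5

        # donor-excitation photons
        dmask = donor_slot
        acc_emit = r_route.random(n_phot) < eps          # acceptor emission (FRET)
        det_a = r_route.random(n_phot) < eta_A
        det_d = r_route.random(n_phot) < eta_D
        leak = r_route.random(n_phot) < p_leak

        keep_fret = dmask & acc_emit & det_a
        keep_donor = dmask & ~acc_emit & det_d
        ch = np.full(n_phot, -1, dtype=np.int8)
        ch[keep_fret] = DA
        ch[keep_donor & leak] = DA
        ch[keep_donor & ~leak] = DD

        # acceptor-excitation (AA) photons
        amask = ~donor_slot & (~is_dark)
        keep_aa = amask & (r_route.random(n_phot) < min(1.0, 1.0 / cfg.beta_))
        ch[keep_aa] = AA

        sel = ch >= 0
        tb, chb, stb = t[sel] + t0, ch[sel], st[sel]

        # microtimes
        mt = np.empty(tb.size)
        is_dd = chb == DD
        is_da = chb == DA
        is_aa = chb == AA
        eps_sel = eps[sel] if not is_dark else np.zeros(tb.size)
        tau_app = np.maximum(cfg.tau_D0 * (1.0 - eps_sel), 1e-3)
        mt[is_dd] = _truncated_exp(r_micro, tau_app[is_dd], half)
        # DA: FRET/direct photons decay with the acceptor lifetime; leaked
        # donor photons keep the donor decay — approximate all DA by the
        # acceptor response (leak fraction is small)
        mt[is_da] = _truncated_exp(r_micro, np.full(is_da.sum(), cfg.tau_A), half)
        mt[is_aa] = half + _truncated_exp(r_micro, np.full(is_aa.sum(), cfg.tau_A), half)

        # direct excitation: extra DA photons, E[direct] = delta * E[F_AA]
        n_dir = r_route.poisson(cfg.delta * keep_aa.sum())
        if n_dir:
            td = t0 + r_route.random(n_dir) * dur
            times.append(td)
            chans.append(np.full(n_dir, DA, dtype=np.int8))
            micros.append(_truncated_exp(r_micro, np.full(n_dir, cfg.tau_A), half))
            truth.append(path.state_at(td - t0))

        times.append(tb)
        chans.append(chb)
        micros.append(mt)
        truth.append(stb)

    # --- uniform background
    for name, code in CHANNEL_LABELS.items():
        rate = cfg.background_rates.get(name, 0.0)
        n_bg = r_bg.poisson(rate * cfg.duration)
        if n_bg == 0:
            continue
        times.append(r_bg.random(n_bg) * cfg.duration)
        chans.append(np.full(n_bg, code, dtype=np.int8))
        off = 0.0 if code in (DD, DA) else half
        micros.append(off + r_bg.random(n_bg) * half)
        truth.append(np.full(n_bg, BACKGROUND_STATE, dtype=np.int64))

    if not times:
        empty = np.empty(0)
        return PhotonStream(empty, empty.astype(np.int8), empty,
                            empty.astype(np.int64), cfg.pie_period, cfg.duration)

    macrotime = np.concatenate(times)
    order = np.argsort(macrotime, kind="stable")
    return PhotonStream(
        macrotime[order],
        np.concatenate(chans)[order],
        np.concatenate(micros)[order],
        np.concatenate(truth).astype(np.int64)[order],
        cfg.pie_period,
        cfg.duration,
    )


# ---------------------------------------------------------------------------
# photon-HDF5-style persistence

_CLOCK = 1e-9          # timestamp unit, s
_TCSPC_BINS = 4096


def save_photon_hdf5(path, stream: PhotonStream) -> None:
    """Write a photon-HDF5-style file: ``photon_data/{timestamps, detectors,
    nanotimes}`` plus setup metadata.  Timestamps are integer multiples of a
    1 ns clock; nanotimes are TCSPC bin indices over the PIE period."""
    tcspc_unit = stream.pie_period / _TCSPC_BINS
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=np.round(stream.macrotime / _CLOCK).astype(np.int64))
        g.create_dataset("detectors", data=stream.channel.astype(np.int8))
        g.create_dataset("nanotimes", data=np.minimum(
            (stream.microtime / tcspc_unit).astype(np.int32), _TCSPC_BINS - 1))
        if stream.state_truth is not None:
            g.create_dataset("state_truth", data=stream.state_truth.astype(np.int64))
        setup = f.create_group("setup")
        setup.attrs["timestamps_unit"] = _CLOCK
        setup.attrs["tcspc_unit_ns"] = tcspc_unit
        setup.attrs["pie_period_ns"] = stream.pie_period
        setup.attrs["duration_s"] = stream.duration if stream.duration is not None else -1.0
        setup.attrs["detector_map"] = "0=DD,1=DA,2=AA"


def load_photon_hdf5(path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        clock = float(f["setup"].attrs["timestamps_unit"])
        tcspc_unit = float(f["setup"].attrs["tcspc_unit_ns"])
        pie = float(f["setup"].attrs["pie_period_ns"])
        dur = float(f["setup"].attrs.get("duration_s", -1.0))
        truth = g["state_truth"][:] if "state_truth" in g else None
        return PhotonStream(
            g["timestamps"][:] * clock,
            g["detectors"][:],
            g["nanotimes"][:] * tcspc_unit,
            truth,
            pie,
            dur if dur > 0 else None,
        )
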