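"""Photon correlation (FRET-FCS) and global kinetic fitting.

Correlations are computed directly on photon timestamps over a
multi-tau-style logarithmic lag grid (geometric spacing, a fixed number of
points per octave): for every lag bin the photon-pair count is obtained by
binary search, normalised by the uncorrelated expectation, giving

    G(tau) = <dI_a(t) dI_b(t+tau)> / (<I_a><I_b>).

Per-lag uncertainties come from splitting the stream into equal segments.
The physical model is a single-species 3D Gaussian-focus diffusion term
multiplied by exponential kinetic relaxations,

    G(tau) = offset + 1/N (1+tau/tau_D)^-1 (1+tau/(kappa^2 tau_D))^-1/2
             (1 + sum_i A_i exp(-tau/tau_i)),

with signed kinetic amplitudes: conformational exchange that moves photons
between the donor and FRET channels produces positive kinetic amplitudes in
the autocorrelations and a negative amplitude in the DonxFRET
cross-correlation (anti-correlated fluctuations).  The global fit shares
the kinetic times across channel pairs while amplitudes stay free per
curve, the standard way to extract exchange timescales from FRET-FCS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .photonsim import CHANNEL_LABELS, PhotonStream

PAIRS = {
    "DonxDon": ("DD", "DD"),
    "FRETxFRET": ("DA", "DA"),
    "DonxFRET": ("DD", "DA"),
}


@dataclass
class CorrelationCurve:
    lag: np.ndarray            # bin-centre delays, s
    G: np.ndarray
    sem: np.ndarray
    channel_pair: str = ""

    def valid(self) -> "CorrelationCurve":
        ok = np.isfinite(self.G) & np.isfinite(self.sem) & (self.sem > 0)
        return CorrelationCurve(self.lag[ok], self.G[ok], self.sem[ok],
                                self.channel_pair)


@dataclass
class FCSModel:
    """Diffusion plus kinetic-relaxation correlation model."""

    N_eff: float
    tau_diff: float
    kappa: float = 5.0
    kinetic_terms: list = field(default_factory=list)   # [(A_i, tau_i), ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_diff <= 0 or self.kappa < 1 or self.N_eff <= 0:
            raise ValueError("require tau_diff > 0, kappa >= 1, N_eff > 0")
        for _, tau in self.kinetic_terms:
            if tau <= 0:
                raise ValueError("kinetic times must be positive")

    def kinetic_weights(self) -> np.ndarray:
        """Relative weights A_i / (1 + sum_j A_j)."""
        amps = np.array([a for a, _ in self.kinetic_terms])
        return amps / (1.0 + amps.sum())


def fcs_model_eval(model: FCSModel, lag) -> np.ndarray:
    tau = np.asarray(lag, dtype=float)
    diff = (1.0 / model.N_eff
            / (1.0 + tau / model.tau_diff)
            / np.sqrt(1.0 + tau / (model.kappa ** 2 * model.tau_diff)))
    kin = 1.0
    for a, t in model.kinetic_terms:
        kin = kin + a * np.exp(-tau / t)
    return model.offset + diff * kin


def lag_grid(lag_min: float, lag_max: float, points_per_octave: int = 8) -> np.ndarray:
    """Geometric lag-bin edges with ``points_per_octave`` bins per factor 2."""
    n = int(np.ceil(np.log2(lag_max / lag_min) * points_per_octave))
    return lag_min * 2.0 ** (np.arange(n + 1) / points_per_octave)


def correlate_times(t_a: np.ndarray, t_b: np.ndarray, duration: float,
                    lag_edges: np.ndarray, segments: int = 10) -> CorrelationCurve:
    """Pair-count photon correlation between two sorted timestamp arrays."""
    edges = np.asarray(lag_edges, float)
    centers = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    seg_len = duration / segments
    g_segs = []
    for k in range(segments):
        lo, hi = k * seg_len, (k + 1) * seg_len
        a = t_a[(t_a >= lo) & (t_a < hi)]
        b = t_b[(t_b >= lo) & (t_b < hi)]
        if a.size < 2 or b.size < 2:
            continue
        counts = np.empty(len(centers))
        right = np.searchsorted(b, a[:, None] + edges[None, 1:]).sum(axis=0)
        left = np.searchsorted(b, a[:, None] + edges[None, :-1]).sum(axis=0)
        counts = (right - left).astype(float)
        # uncorrelated expectation with finite-window (triangular) correction
        expect = a.size * b.size * widths / seg_len * np.maximum(1.0 - centers / seg_len, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            g_segs.append(counts / expect - 1.0)
    if not g_segs:
        return CorrelationCurve(centers, np.full_like(centers, np.nan),
                                np.full_like(centers, np.nan))
    g = np.asarray(g_segs)
    mean = g.mean(axis=0)
    sem = g.std(axis=0, ddof=1) / np.sqrt(len(g_segs)) if len(g_segs) > 1 \
        else np.full_like(mean, np.nan)
    return CorrelationCurve(centers, mean, sem)


def correlate(stream: PhotonStream, pair: str = "DonxDon",
              lag_min: float = 2e-7, lag_max: float = 3e-2,
              points_per_octave: int = 8, segments: int = 10) -> CorrelationCurve:
    """Correlate one channel pair of a photon stream.

    ``pair`` is one of DonxDon, FRETxFRET, DonxFRET (or an explicit tuple of
    channel labels).  Fewer than ~1e3 photons per channel gives a noisy
    curve; it is computed regardless.
    """
    chans = PAIRS[pair] if isinstance(pair, str) else pair
    name = pair if isinstance(pair, str) else "x".join(chans)
    t_a = stream.select(chans[0])
    t_b = stream.select(chans[1])
    duration = stream.duration if stream.duration else float(stream.macrotime[-1])
    curve = correlate_times(t_a, t_b, duration,
                            lag_grid(lag_min, lag_max, points_per_octave),
                            segments)
    curve.channel_pair = name
    return curve


def direct_intensity_correlation(trace_a: np.ndarray, trace_b: np.ndarray,
                                 dt: float, max_lag_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force normalised correlation of two binned intensity traces,
    used as an independent oracle for the photon-pair estimator."""
    a = np.asarray(trace_a, float)
    b = np.asarray(trace_b, float)
    n = len(a)
    lags = np.arange(1, max_lag_bins + 1)
    g = np.empty(len(lags))
    ma, mb = a.mean(), b.mean()
    for i, L in enumerate(lags):
        g[i] = np.mean(a[:n - L] * b[L:]) / (ma * mb) - 1.0
    return lags * dt, g


# ---------------------------------------------------------------------------
# global fitting

@dataclass
class GlobalFitResult:
    models: dict            # curve name -> FCSModel
    shared_taus: np.ndarray             # sorted ascending, s
    tau_stderr: np.ndarray
    chi2_red: float
    resolved: bool          # False when the two times are degenerate within CI
    params: object = None   # underlying lmfit result

    def kinetic_weights(self, name: str) -> np.ndarray:
        return self.models[name].kinetic_weights()


def global_fit(curves: dict, n_terms: int = 2, kappa: float = 5.0,
               fit_range: tuple[float, float] | None = None,
               tau_inits=None, offset_free: bool = False) -> GlobalFitResult:
    """Weighted global fit of several correlation curves.

    Kinetic relaxation times are shared across all curves; amplitude,
    diffusion time and signed kinetic amplitudes are free per curve.
    Multi-start over log-spaced initial time pairs; weights are 1/sem^2.
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    clean = {}
    for name, c in curves.items():
        c = c.valid()
        if fit_range is not None:
            ok = (c.lag >= fit_range[0]) & (c.lag <= fit_range[1])
            c = CorrelationCurve(c.lag[ok], c.G[ok], c.sem[ok], c.channel_pair)
        if c.lag.size < 8:
            raise ValueError(f"curve {name!r} has too few valid lags")
        clean[name] = c

    lag_lo = min(c.lag.min() for c in clean.values())
    lag_hi = max(c.lag.max() for c in clean.values())

    def build_params(taus0):
        p = lmfit.Parameters()
        for i, t0 in enumerate(taus0):
            # kinetic relaxations live well below the diffusion plateau
            p.add(f"tau_k{i}", value=t0, min=lag_lo / 4, max=lag_hi / 30)
        for j, (name, c) in enumerate(clean.items()):
            # robust plateau amplitude and half-decay diffusion-time guesses
            n_head = max(3, len(c.G) // 8)
            g0 = float(np.median(c.G[:n_head]))
            if g0 == 0:
                g0 = 1e-3
            below = np.flatnonzero(c.G < 0.5 * g0)
            taud0 = c.lag[below[0]] if below.size else lag_hi / 5
            p.add(f"g0_{j}", value=abs(g0), min=1e-6)
            p.add(f"sign_{j}", value=1.0 if g0 >= 0 else -1.0, vary=False)
            p.add(f"taud_{j}", value=taud0, min=lag_lo * 4, max=lag_hi * 10)
            # autocorrelation kinetic amplitudes are variance contributions
            # and cannot be negative; cross-correlations may anti-correlate
            chans = PAIRS.get(c.channel_pair or name)
            is_auto = chans is not None and chans[0] == chans[1]
            for i in range(len(taus0)):
                p.add(f"A_{j}_{i}", value=0.05,
                      min=0.0 if is_auto else -0.95, max=3.0)
            p.add(f"off_{j}", value=0.0, vary=offset_free)
        return p

    def model_curve(p, j, lag, n_taus):
        taus = [p[f"tau_k{i}"].value for i in range(n_taus)]
        g0 = p[f"g0_{j}"].value * p[f"sign_{j}"].value
        diff = (g0 / (1 + lag / p[f"taud_{j}"].value)
                / np.sqrt(1 + lag / (kappa ** 2 * p[f"taud_{j}"].value)))
        kin = 1.0
        for i, t in enumerate(taus):
            kin = kin + p[f"A_{j}_{i}"].value * np.exp(-lag / t)
        return p[f"off_{j}"].value + diff * kin

    names = list(clean)

    def residual(p):
        res = []
        for j, name in enumerate(names):
            c = clean[name]
            res.append((model_curve(p, j, c.lag, n_terms) - c.G) / c.sem)
        return np.concatenate(res)

    if tau_inits is None:
        # dense log-spaced multi-start grid over the admissible range
        grid = np.geomspace(lag_lo * 2, lag_hi / 40, 6)
        if n_terms == 2:
            tau_inits = [(grid[i], grid[j]) for i in range(len(grid))
                         for j in range(i + 1, len(grid)) if grid[j] / grid[i] > 4]
        else:
            span = np.log10(grid[-1] / grid[0])
            tau_inits = [grid[0] * 10 ** (span * np.linspace(s, 1, n_terms))
                         for s in (0.0, 0.3)]

    best = None
    for taus0 in tau_inits:
        out = lmfit.minimize(residual, build_params(taus0), method="leastsq")
        if best is None or out.chisqr < best.chisqr:
            best = out
    p = best.params

    order = np.argsort([p[f"tau_k{i}"].value for i in range(n_terms)])
    taus = np.array([p[f"tau_k{i}"].value for i in range(n_terms)])[order]
    errs = np.array([p[f"tau_k{i}"].stderr or np.nan for i in range(n_terms)])[order]

    models = {}
    for j, name in enumerate(names):
        amps = np.array([p[f"A_{j}_{i}"].value for i in range(n_terms)])[order]
        g0 = p[f"g0_{j}"].value * p[f"sign_{j}"].value
        models[name] = FCSModel(
            N_eff=1.0 / abs(g0) if g0 != 0 else np.inf,
            tau_diff=p[f"taud_{j}"].value,
            kappa=kappa,
            kinetic_terms=[(float(a), float(t)) for a, t in zip(amps, taus)],
            offset=p[f"off_{j}"].value,
        )
        models[name].amplitude = g0  # signed zero-lag diffusion amplitude

    resolved = True
    if n_terms >= 2 and np.all(np.isfinite(errs[:2])):
        resolved = (taus[0] + errs[0]) < (taus[1] - errs[1])
    elif n_terms >= 2:
        resolved = taus[1] / taus[0] > 3.0
    return GlobalFitResult(models, taus, errs, best.redchi, resolved, best)
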