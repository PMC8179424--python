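"""Photon Distribution Analysis (PDA).

PDA separates true inter-dye distance heterogeneity from photon-counting
(shot) noise.  Conformational states are Gaussian distributions in distance
space (mean ``mu_R``, width ``sigma_R``); for a burst of ``N``
donor-excitation photons the acceptor count is binomial with the apparent
transfer probability of the momentary distance, and Poisson background
counts add to both channels.  The forward model predicts the proximity-ratio
(E = F_DA / (F_DA + F_DD)) histogram of a burst ensemble exactly:

    P(E-bin) = sum_N P(N) sum_s w_s  int dR N(R; mu_s, sigma_s)
               sum_{a,d} Pois(a) Pois(d) Binom(F_A - a | N - a - d, p_app(R))

with p_app(R) = E(R) + (1 - E(R)) alpha/(1+alpha) folding donor leakage
into the routing probability.  The burst-size distribution P(N) is taken
empirically from the analysed burst set.

Fits minimise Pearson chi^2 on merged bins (>= 5 observed counts per merged
bin) over state widths and weights, optionally over the means, with a
multi-start strategy; state means can be constrained, the standard way to
transfer a well-resolved condition's states onto other conditions.  Model
evaluation inside the optimiser uses a precomputed single-state basis on a
(mu, sigma) grid with linear interpolation; reported statistics are always
recomputed with the exact forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln
from scipy.stats import poisson

from .kinetics import forster_efficiency, efficiency_to_distance

DEFAULT_BIN_EDGES = np.linspace(-0.1, 1.1, 42)  # 41 bins admitting overshoot
_SQRT2 = np.sqrt(2.0)


@dataclass
class DistanceState:
    mu_R: float
    sigma_R: float
    weight: float

    def __post_init__(self) -> None:
        if self.mu_R <= 0 or self.sigma_R < 0 or self.weight < 0:
            raise ValueError("require mu_R > 0, sigma_R >= 0, weight >= 0")


@dataclass
class BurstSizeDistribution:
    """Empirical distribution over total donor-excitation photon counts.

    ``durations`` (optional, seconds) holds the mean burst duration per size
    group: background counts accrue in proportion to the transit time, so a
    short (small-N) burst carries proportionally less background than a long
    one.  Without durations, background is treated as constant per burst.
    """

    sizes: np.ndarray
    probs: np.ndarray
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.sizes.size == 0:
            raise ValueError("empty burst-size distribution")
        s = self.probs.sum()
        if s <= 0:
            raise ValueError("burst-size probabilities must have positive mass")
        self.probs = self.probs / s
        if self.durations is not None:
            self.durations = np.asarray(self.durations, dtype=float)
            if self.durations.shape != self.sizes.shape:
                raise ValueError("durations must match sizes")

    def bg_scale(self) -> np.ndarray:
        """Per-group background multiplier: duration relative to the mean."""
        if self.durations is None:
            return np.ones_like(self.probs)
        mean = float(np.sum(self.probs * self.durations))
        return self.durations / mean if mean > 0 else np.ones_like(self.probs)

    @classmethod
    def from_counts(cls, counts, durations=None, max_unique: int = 64,
                    max_size: int = 512) -> "BurstSizeDistribution":
        """Empirical sizes; compressed to at most ``max_unique`` quantile
        groups (weighted-mean representative), with sizes clipped at
        ``max_size``, to bound forward-model cost (shot noise is already
        negligible at several hundred photons)."""
        counts = np.asarray(counts, dtype=np.int64)
        keep = counts > 0
        counts = np.minimum(counts[keep], max_size)
        durs = None if durations is None else np.asarray(durations, float)[keep]
        order = np.argsort(counts)
        counts = counts[order]
        if durs is not None:
            durs = durs[order]
        vals, start, cnt = np.unique(counts, return_index=True, return_counts=True)
        mean_dur = None
        if durs is not None:
            mean_dur = np.array([durs[s:s + c].mean() for s, c in zip(start, cnt)])
        if len(vals) <= max_unique:
            return cls(vals, cnt.astype(float), mean_dur)
        cum = np.cumsum(cnt)
        targets = np.linspace(0, cum[-1], max_unique + 1)[1:]
        idx = np.searchsorted(cum, targets)
        sizes, probs, gdur, lo = [], [], [], 0
        for hi in idx:
            hi = max(hi, lo)
            sl = slice(lo, hi + 1)
            w = cnt[sl].astype(float)
            if w.sum() > 0:
                sizes.append(int(round(np.average(vals[sl], weights=w))))
                probs.append(w.sum())
                if mean_dur is not None:
                    gdur.append(np.average(mean_dur[sl], weights=w))
            lo = hi + 1
            if lo >= len(vals):
                break
        return cls(np.asarray(sizes), np.asarray(probs),
                   np.asarray(gdur) if mean_dur is not None else None)


@dataclass
class PDAModel:
    states: list[DistanceState]
    R0: float
    burst_sizes: BurstSizeDistribution
    bg_D: float = 0.0      # mean donor-channel background counts per burst
    bg_A: float = 0.0      # mean acceptor-channel background counts per burst
    alpha: float = 0.0     # donor leakage folded into the routing probability
    bin_edges: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_EDGES.copy())

    def __post_init__(self) -> None:
        w = sum(s.weight for s in self.states)
        if not np.isclose(w, 1.0, atol=1e-6):
            for s in self.states:
                s.weight /= w

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.states])


@dataclass
class EfficiencyHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray          # observed counts or model probabilities
    n_bursts: int

    @property
    def density(self) -> np.ndarray:
        """Probability mass per bin (sums to 1)."""
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def proximity_histogram(f_da, f_dd, bin_edges=None) -> EfficiencyHistogram:
    """Histogram of raw proximity ratios F_DA / (F_DA + F_DD)."""
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges)
    f_da = np.asarray(f_da, float)
    f_dd = np.asarray(f_dd, float)
    tot = f_da + f_dd
    ok = tot > 0
    e = f_da[ok] / tot[ok]
    counts, _ = np.histogram(e, bins=edges)
    return EfficiencyHistogram(edges, counts.astype(float), int(ok.sum()))


def apparent_probability(R, R0: float, alpha: float = 0.0):
    """Probability that a detected donor-excitation photon falls in the
    acceptor channel: FRET plus leakage routing."""
    e = forster_efficiency(R, R0)
    return e + (1.0 - e) * alpha / (1.0 + alpha)


def _bg_weights(mean_counts: float, scale: np.ndarray, size_probs: np.ndarray,
                tail: float = 1e-4):
    """Per-size-group truncated Poisson weights for background counts.

    Returns ``(k, w, marginal)`` with ``w[s, k]`` the probability of ``k``
    background photons in a burst of size group ``s`` (mean
    ``mean_counts * scale[s]``); truncation is chosen on the size-marginal
    background distribution so rare long bursts cannot blow up the support.
    """
    if mean_counts <= 0:
        return np.array([0]), np.ones((len(scale), 1)), np.array([1.0])
    lam = mean_counts * scale
    # support from the marginal over size groups
    kmax = 1
    while np.sum(size_probs * poisson.sf(kmax, lam)) > tail and kmax < 200:
        kmax += 1
    k = np.arange(kmax + 1)
    w = poisson.pmf(k[None, :], lam[:, None])
    w = w / w.sum(axis=1, keepdims=True)
    return k, w, size_probs @ w


def _state_bin_probs(mu: float, sigma: float, model: PDAModel,
                     n_quad: int = 15) -> np.ndarray:
    """Exact forward model for a single Gaussian distance state: probability
    per E bin, marginalised over burst size, shot noise and background."""
    if sigma < 1e-9:
        Rs = np.array([max(mu, 1.0)])
        qw = np.array([1.0])
    else:
        x, w = np.polynomial.hermite.hermgauss(n_quad)
        Rs = np.maximum(mu + _SQRT2 * sigma * x, 1.0)
        qw = w / np.sqrt(np.pi)
    p = np.clip(apparent_probability(Rs, model.R0, model.alpha), 1e-12, 1 - 1e-12)
    logp, log1mp = np.log(p), np.log1p(-p)

    all_sizes = model.burst_sizes.sizes
    all_probs = model.burst_sizes.probs
    edges = model.bin_edges
    n_bins = len(edges) - 1
    hist = np.zeros(n_bins)

    scale = model.burst_sizes.bg_scale()
    ka, wa, marg_a = _bg_weights(model.bg_A, scale, all_probs)
    kd, wd, marg_d = _bg_weights(model.bg_D, scale, all_probs)

    # chunk the (sorted) size groups so small bursts do not pay the k-range
    # of the largest burst
    order = np.argsort(all_sizes)
    n_chunks = min(3, len(order))
    for chunk in np.array_split(order, n_chunks):
        sizes = all_sizes[chunk]
        size_probs = all_probs[chunk]
        wa_c, wd_c = wa[chunk], wd[chunk]
        kmax = int(sizes.max())
        kk = np.arange(kmax + 1)
        lgk = gammaln(kk + 1.0)
        # the binomial tensor depends on the background only through B = a + d
        for B in range(ka[-1] + kd[-1] + 1):
            n = sizes - B
            valid = n >= 0
            if not np.any(valid):
                continue
            nv = n[valid].astype(float)
            Nv = sizes[valid]
            PNv = size_probs[valid]
            nmk = nv[:, None] - kk[None, :]
            ok = nmk >= 0
            nmk_c = np.where(ok, nmk, 0.0)
            kk_c = np.where(ok, kk[None, :], 0.0)
            logpmf = (gammaln(nv + 1.0)[:, None, None]
                      - lgk[None, :, None]
                      - gammaln(nmk_c + 1.0)[:, :, None]
                      + kk_c[:, :, None] * logp[None, None, :]
                      + nmk_c[:, :, None] * log1mp[None, None, :])
            pmf = np.exp(logpmf)
            pmf[~ok] = 0.0
            base = (pmf * qw[None, None, :]).sum(axis=-1)       # (n_sizes, k)
            for a in range(max(0, B - kd[-1]), min(B, ka[-1]) + 1):
                d = B - a
                if marg_a[a] * marg_d[d] < 1e-7:   # negligible combo
                    continue
                w_vec = wa_c[:, a] * wd_c[:, d]        # per size group
                contrib = base * (PNv * w_vec[valid])[:, None]
                e_val = (kk[None, :] + a) / Nv[:, None]
                idx = np.clip(np.searchsorted(edges, e_val, side="right") - 1,
                              0, n_bins - 1)
                idx = np.broadcast_to(idx, contrib.shape)
                hist += np.bincount(idx.ravel(), weights=contrib.ravel(),
                                    minlength=n_bins)
    total = hist.sum()
    return hist / total if total > 0 else hist


def predict_histogram(model: PDAModel, n_quad: int = 15) -> EfficiencyHistogram:
    """Predicted shot-noise-limited proximity-ratio histogram (probability
    per bin; sums to 1)."""
    if model.burst_sizes.sizes.size == 0:
        raise ValueError("empty burst-size distribution")
    probs = np.zeros(len(model.bin_edges) - 1)
    for s in model.states:
        probs += s.weight * _state_bin_probs(s.mu_R, s.sigma_R, model, n_quad)
    return EfficiencyHistogram(model.bin_edges, probs, 0)


# ---------------------------------------------------------------------------
# fitting

def _merge_map(counts: np.ndarray, min_count: float = 5.0) -> list[np.ndarray]:
    """Group adjacent bins so each merged bin holds >= min_count observed
    counts (fixed from the data, so the chi^2 binning does not move during
    optimisation).  A trailing light group merges into its neighbour."""
    groups, cur, acc = [], [], 0.0
    for i, c in enumerate(counts):
        cur.append(i)
        acc += c
        if acc >= min_count:
            groups.append(np.array(cur))
            cur, acc = [], 0.0
    if cur:
        if groups:
            groups[-1] = np.concatenate([groups[-1], np.array(cur)])
        else:
            groups.append(np.array(cur))
    return groups


def _merged(vec: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    return np.array([vec[g].sum() for g in groups])


class _StateBasis:
    """Single-state forward-model histograms tabulated on a (mu, sigma) grid
    for fast interpolated evaluation inside the optimiser."""

    def __init__(self, model_template: PDAModel, mu_grid, sigma_grid, n_quad=9):
        self.mu_grid = np.asarray(mu_grid, float)
        self.sigma_grid = np.asarray(sigma_grid, float)
        self.H = np.empty((len(self.mu_grid), len(self.sigma_grid),
                           len(model_template.bin_edges) - 1))
        for i, mu in enumerate(self.mu_grid):
            for j, sg in enumerate(self.sigma_grid):
                self.H[i, j] = _state_bin_probs(mu, sg, model_template, n_quad)

    def eval(self, mu: float, sigma: float) -> np.ndarray:
        mg, sg = self.mu_grid, self.sigma_grid
        i = np.clip(np.searchsorted(mg, mu) - 1, 0, max(len(mg) - 2, 0))
        j = np.clip(np.searchsorted(sg, sigma) - 1, 0, max(len(sg) - 2, 0))
        if len(mg) == 1:
            fi, i1 = 0.0, i
        else:
            fi = np.clip((mu - mg[i]) / (mg[i + 1] - mg[i]), 0.0, 1.0)
            i1 = i + 1
        if len(sg) == 1:
            fj, j1 = 0.0, j
        else:
            fj = np.clip((sigma - sg[j]) / (sg[j + 1] - sg[j]), 0.0, 1.0)
            j1 = j + 1
        return ((1 - fi) * (1 - fj) * self.H[i, j] + fi * (1 - fj) * self.H[i1, j]
                + (1 - fi) * fj * self.H[i, j1] + fi * fj * self.H[i1, j1])


@dataclass
class PDAFitResult:
    model: PDAModel
    chi2_red: float
    logL: float
    n_params: int
    n_bursts: int
    hist: EfficiencyHistogram
    converged: bool
    fixed_mu: np.ndarray | None = None
    _basis: object = None

    @property
    def bic(self) -> float:
        return -2.0 * self.logL + self.n_params * np.log(max(self.n_bursts, 1))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([logits, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _default_mu_bounds(hist: EfficiencyHistogram, R0: float, alpha: float):
    """Distance range covered by the occupied part of the histogram."""
    c = hist.centers[hist.counts > 0]
    e_lo = max(min(c.min() - 0.05, 0.95), 0.02)
    e_hi = min(max(c.max() + 0.05, 0.05), 0.98)
    return (float(efficiency_to_distance(e_hi, R0)),
            float(efficiency_to_distance(e_lo, R0)))


def fit_pda(hist: EfficiencyHistogram, K: int, *, R0: float,
            burst_sizes: BurstSizeDistribution, bg_D: float = 0.0,
            bg_A: float = 0.0, alpha: float = 0.0, fixed_mu=None,
            n_starts: int = 16, seed: int = 0,
            sigma_bounds: tuple[float, float] = (0.0, 8.0),
            mu_bounds: tuple[float, float] | None = None,
            bin_edges=None, basis: "_StateBasis | None" = None,
            refine_exact: bool = True) -> PDAFitResult:
    """Fit a K-state PDA model to an observed proximity-ratio histogram.

    Minimises Pearson chi^2 over state widths and weights (and means unless
    ``fixed_mu`` pins them) with ``n_starts`` random multi-starts; ties break
    to the lowest chi^2.  Returns the best model with reduced chi^2 and the
    multinomial log-likelihood used for model selection.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    edges = hist.bin_edges if bin_edges is None else np.asarray(bin_edges)
    template = PDAModel([DistanceState(R0, 0.0, 1.0)], R0, burst_sizes,
                        bg_D, bg_A, alpha, edges)
    rng = np.random.default_rng(seed)

    if fixed_mu is not None:
        fixed_mu = np.asarray(fixed_mu, float)
        if fixed_mu.shape != (K,):
            raise ValueError("fixed_mu must provide one mean per state")
    if basis is None:
        if fixed_mu is not None:
            mu_grid = np.unique(fixed_mu)
        else:
            lo, hi = mu_bounds if mu_bounds else _default_mu_bounds(hist, R0, alpha)
            mu_grid = np.linspace(lo, hi, max(8, int((hi - lo) / 1.5) + 1))
        sigma_grid = np.linspace(sigma_bounds[0], max(sigma_bounds[1], 0.5), 9)
        basis = _StateBasis(template, mu_grid, sigma_grid)
    mu_grid = basis.mu_grid

    groups = _merge_map(hist.counts)
    obs_m = _merged(hist.counts, groups)
    n_bursts = int(hist.counts.sum())

    def model_probs(mu, sigma, w, exact=False):
        if exact:
            m = PDAModel([DistanceState(m_, s_, w_) for m_, s_, w_ in zip(mu, sigma, w)],
                         R0, burst_sizes, bg_D, bg_A, alpha, edges)
            return predict_histogram(m).counts
        p = np.zeros(len(edges) - 1)
        for m_, s_, w_ in zip(mu, sigma, w):
            p += w_ * basis.eval(m_, s_)
        return p

    def unpack(x):
        if fixed_mu is not None:
            mu = fixed_mu
            sigma = x[:K]
            logits = x[K:]
        else:
            mu = x[:K]
            sigma = x[K:2 * K]
            logits = x[2 * K:]
        return mu, sigma, _softmax(logits)

    def residuals(x):
        mu, sigma, w = unpack(x)
        p = model_probs(mu, sigma, w)
        exp_m = np.maximum(_merged(p, groups) * n_bursts, 1e-9)
        return (obs_m - exp_m) / np.sqrt(exp_m)

    # bounds and starts
    s_lo = np.full(K, sigma_bounds[0])
    s_hi = np.full(K, max(sigma_bounds[1], 0.5))
    l_lo, l_hi = np.full(K - 1, -12.0), np.full(K - 1, 12.0)
    if fixed_mu is not None:
        lb = np.concatenate([s_lo, l_lo])
        ub = np.concatenate([s_hi, l_hi])
    else:
        lb = np.concatenate([np.full(K, mu_grid[0]), s_lo, l_lo])
        ub = np.concatenate([np.full(K, mu_grid[-1]), s_hi, l_hi])

    best = None
    for _ in range(max(1, n_starts)):
        sig0 = rng.uniform(0.5, 4.0, K)
        log0 = rng.normal(0, 0.5, K - 1)
        if fixed_mu is not None:
            x0 = np.concatenate([sig0, log0])
        else:
            mu0 = np.sort(rng.uniform(mu_grid[0], mu_grid[-1], K))
            x0 = np.concatenate([mu0, sig0, log0])
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub),
                                xtol=1e-10, ftol=1e-10, max_nfev=400)
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun ** 2))
        if best is None or chi2 < best[0]:
            best = (chi2, sol)
    converged = best is not None and best[1].status > 0
    if best is None:
        raise RuntimeError("PDA fit failed for every start")

    mu, sigma, w = unpack(best[1].x)
    order = np.argsort(mu)
    mu, sigma, w = mu[order], sigma[order], w[order]
    if fixed_mu is not None:
        mu = np.sort(fixed_mu)

    # exact recompute at the solution (interpolated when refine_exact=False,
    # e.g. inside bootstrap resampling where only weights matter)
    p_exact = model_probs(mu, sigma, w, exact=refine_exact)
    exp_m = np.maximum(_merged(p_exact, groups) * n_bursts, 1e-9)
    chi2 = float(np.sum((obs_m - exp_m) ** 2 / exp_m))
    n_params = (2 * K - 1) if fixed_mu is not None else (3 * K - 1)
    dof = max(len(groups) - 1 - n_params, 1)
    logL = float(np.sum(hist.counts * np.log(np.maximum(p_exact, 1e-300))))

    model = PDAModel([DistanceState(m_, s_, w_) for m_, s_, w_ in zip(mu, sigma, w)],
                     R0, burst_sizes, bg_D, bg_A, alpha, edges)
    return PDAFitResult(model, chi2 / dof, logL, n_params, n_bursts, hist,
                        converged, fixed_mu, basis)


def select_n_states(hist: EfficiencyHistogram, K_max: int = 4,
                    criterion: str = "bic", **fit_kwargs) -> tuple[int, list[PDAFitResult]]:
    """Fit K = 1..K_max and return the K minimising the information
    criterion (BIC by default, from the multinomial histogram likelihood);
    ties break to the smaller K."""
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    fits = []
    for k in range(1, K_max + 1):
        f = fit_pda(hist, k, **fit_kwargs)
        fit_kwargs.setdefault("basis", f._basis)  # reuse grid across K
        fits.append(f)
    if criterion == "bic":
        scores = [f.bic for f in fits]
    elif criterion == "aic":
        scores = [-2 * f.logL + 2 * f.n_params for f in fits]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best_k = int(np.argmin(np.round(scores, 6))) + 1
    return best_k, fits


def state_ratio(fit: PDAFitResult, a: int, b: int, n_boot: int = 50,
                seed: int = 0, ci: float = 0.95) -> dict:
    """Weight ratio w_b / w_a with a bootstrap confidence interval obtained
    by multinomial resampling of the observed histogram and refitting from
    the best-fit parameters."""
    w = fit.model.weights
    if w[a] == 0:
        raise ZeroDivisionError("state a has zero weight: ratio undefined")
    ratio = float(w[b] / w[a])
    rng = np.random.default_rng(seed)
    p_obs = fit.hist.density
    samples = []
    mu0 = np.array([s.mu_R for s in fit.model.states])
    sig0 = np.array([s.sigma_R for s in fit.model.states])
    for _ in range(n_boot):
        counts = rng.multinomial(fit.n_bursts, p_obs).astype(float)
        h = EfficiencyHistogram(fit.hist.bin_edges, counts, fit.n_bursts)
        try:
            f = fit_pda(h, len(mu0), R0=fit.model.R0,
                        burst_sizes=fit.model.burst_sizes,
                        bg_D=fit.model.bg_D, bg_A=fit.model.bg_A,
                        alpha=fit.model.alpha,
                        fixed_mu=fit.fixed_mu if fit.fixed_mu is not None else mu0,
                        n_starts=2, seed=int(rng.integers(2 ** 31)),
                        basis=fit._basis, refine_exact=False)
        except RuntimeError:
            continue
        wb = f.model.weights
        if wb[a] > 1e-6:
            samples.append(wb[b] / wb[a])
    lo, hi = (np.percentile(samples, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
              if samples else (np.nan, np.nan))
    return {"ratio": ratio, "ci_low": float(lo), "ci_high": float(hi),
            "n_boot": len(samples)}


def shot_noise_filtered_distribution(model: PDAModel,
                                     r_grid: np.ndarray | None = None) -> dict:
    """Distance-domain state densities (the shot-noise-deconvolved model
    component) and their expectation values.

    For a Gaussian distance state the expectation is its mean mu_R exactly;
    the overall expectation is the weight-average of the state means.
    """
    if r_grid is None:
        mus = np.array([s.mu_R for s in model.states])
        sds = np.array([max(s.sigma_R, 0.5) for s in model.states])
        r_grid = np.linspace(max((mus - 5 * sds).min(), 1.0),
                             (mus + 5 * sds).max(), 400)
    dens = []
    for s in model.states:
        if s.sigma_R < 1e-9:
            d = np.zeros_like(r_grid)
            i = np.argmin(np.abs(r_grid - s.mu_R))
            dr = r_grid[1] - r_grid[0] if len(r_grid) > 1 else 1.0
            d[i] = 1.0 / dr
        else:
            d = np.exp(-0.5 * ((r_grid - s.mu_R) / s.sigma_R) ** 2) \
                / (s.sigma_R * np.sqrt(2 * np.pi))
        dens.append(d)
    dens = np.asarray(dens)
    expectations = np.array([s.mu_R for s in model.states])
    weights = model.weights
    return {
        "r_grid": r_grid,
        "state_densities": dens,
        "total_density": (weights[:, None] * dens).sum(axis=0),
        "expectations": expectations,
        "weights": weights,
        "overall_expectation": float(np.sum(weights * expectations)),
    }
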