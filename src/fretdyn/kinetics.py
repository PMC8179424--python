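"""Continuous-time Markov schemes for conformational exchange.

A molecule hops between a small number of conformational states (for the
chaperone system that motivated this package: an N-terminally open state and
two closed states, A and a contracted B).  Each state carries a mean
inter-dye distance ``mu_R`` and a Gaussian width ``sigma_R``; exchange is
Markovian with first-order rates.  The scheme is the ground truth that every
downstream analysis (burst histograms, PDA, FRET-FCS) tries to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg


class NonErgodicSchemeError(ValueError):
    """Raised when a scheme cannot sustain exchange for the requested duration."""


@dataclass
class KineticScheme:
    """First-order exchange between labelled conformational states.

    Parameters
    ----------
    state_labels
        Names of the states, e.g. ``("open", "closedA", "closedB")``.
    mu_R
        Per-state mean inter-dye distance in Å (> 0).
    sigma_R
        Per-state Gaussian distance width in Å (>= 0).
    rate_matrix
        ``(n, n)`` array of transition rates in 1/s; entry ``[i, j]`` is the
        rate from state ``i`` to state ``j``.  The diagonal is ignored.
    """

    state_labels: Sequence[str]
    mu_R: np.ndarray
    sigma_R: np.ndarray
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.mu_R = np.asarray(self.mu_R, dtype=float)
        self.sigma_R = np.asarray(self.sigma_R, dtype=float)
        self.rate_matrix = np.array(self.rate_matrix, dtype=float)
        n = len(self.state_labels)
        if self.mu_R.shape != (n,) or self.sigma_R.shape != (n,):
            raise ValueError("mu_R and sigma_R must have one entry per state")
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix must be square with one row per state")
        off = self.rate_matrix[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("transition rates must be non-negative")
        if np.any(self.mu_R <= 0):
            raise ValueError("mu_R must be positive")
        if np.any(self.sigma_R < 0):
            raise ValueError("sigma_R must be non-negative")
        np.fill_diagonal(self.rate_matrix, 0.0)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q; rows sum to zero."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def exit_rates(self) -> np.ndarray:
        return self.rate_matrix.sum(axis=1)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary probabilities pi with pi Q = 0, sum(pi) = 1.

        Solved from the left null space of the generator; raises if the
        null space is not one-dimensional (reducible scheme).
        """
        q = self.generator()
        # pi Q = 0  <=>  Q^T pi^T = 0
        w, v = linalg.eig(q.T)
        idx = np.where(np.abs(w) < 1e-9 * max(1.0, np.abs(w).max()))[0]
        if len(idx) != 1:
            raise NonErgodicSchemeError(
                "scheme is reducible: stationary distribution not unique"
            )
        pi = np.real(v[:, idx[0]])
        pi = pi / pi.sum()
        if np.any(pi < -1e-12):
            raise NonErgodicSchemeError("invalid stationary distribution")
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()

    def relaxation_times(self) -> np.ndarray:
        """Relaxation times -1/Re(lambda_k) for the non-zero eigenvalues of Q,
        sorted slowest first."""
        w = np.real(linalg.eigvals(self.generator()))
        w = w[w < -1e-12]  # exclude the stationary eigenvalue
        return np.sort(-1.0 / w)[::-1]

    def efficiency(self, R0: float) -> np.ndarray:
        """Per-state FRET efficiency at the state mean distance,
        E = 1 / (1 + (mu_R/R0)^6)."""
        return forster_efficiency(self.mu_R, R0)


def forster_efficiency(R, R0: float):
    """E(R) = 1 / (1 + (R/R0)^6)."""
    R = np.asarray(R, dtype=float)
    return 1.0 / (1.0 + (R / R0) ** 6)


def efficiency_to_distance(E, R0: float):
    """Invert the Förster law: R = R0 (1/E - 1)^(1/6), defined for E in (0, 1)."""
    E = np.asarray(E, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return out


@dataclass
class StatePath:
    """Piecewise-constant state trajectory: state ``states[k]`` holds on
    ``[t_start[k], t_start[k+1])``; the final dwell ends at ``duration``."""

    states: np.ndarray        # int state indices per dwell
    t_start: np.ndarray       # dwell start times, s; t_start[0] == 0
    duration: float

    def state_at(self, t) -> np.ndarray:
        """State index at time(s) ``t`` (vectorised)."""
        idx = np.searchsorted(self.t_start, np.asarray(t, dtype=float), side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def occupancies(self, n_states: int) -> np.ndarray:
        """Fraction of total time spent in each state."""
        ends = np.append(self.t_start[1:], self.duration)
        dwell = ends - self.t_start
        occ = np.bincount(self.states, weights=dwell, minlength=n_states)
        return occ / self.duration


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    seed: int | np.random.Generator,
    initial_state: int | None = None,
) -> StatePath:
    """Exact stochastic (Gillespie) simulation of the exchange scheme.

    Dwell times are exponential with the state's total exit rate; the next
    state is drawn with probability proportional to the outgoing rate.

    Parameters
    ----------
    initial_state
        Starting state index; drawn from the stationary distribution when
        ``None``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exit_rates = scheme.exit_rates()
    n = scheme.n_states
    if initial_state is None:
        s = int(rng.choice(n, p=scheme.stationary_distribution()))
    else:
        s = int(initial_state)
    if n > 1 and np.all(exit_rates <= 0):
        raise NonErgodicSchemeError("absorbing states with no exit cannot sustain exchange")
    if n == 1 or exit_rates[s] <= 0 and initial_state is not None:
        return StatePath(np.array([s]), np.array([0.0]), float(duration))

    import bisect

    # cumulative jump probabilities per state as plain lists (fast bisect)
    cumprobs = [list(np.cumsum(scheme.rate_matrix[i] / exit_rates[i]))
                if exit_rates[i] > 0 else None for i in range(n)]
    inv_k = [1.0 / k if k > 0 else np.inf for k in exit_rates]

    states = [s]
    t_start = [0.0]
    t = 0.0
    # block-drawn randomness keeps the hot loop cheap
    block = 1 << 15
    exps = rng.exponential(size=block)
    unis = rng.random(block)
    i = 0
    while True:
        cp = cumprobs[s]
        if cp is None:
            break  # absorbing state reached: dwell covers the remainder
        if i >= block:
            exps = rng.exponential(size=block)
            unis = rng.random(block)
            i = 0
        t += exps[i] * inv_k[s]
        if t >= duration:
            break
        s = bisect.bisect_right(cp, unis[i])
        if s >= n:  # numerical edge: cumulative slightly below 1
            s = n - 1
        i += 1
        states.append(s)
        t_start.append(t)
    return StatePath(np.asarray(states, dtype=np.int64),
                     np.asarray(t_start, dtype=float), float(duration))


def two_state_scheme(k12: float, k21: float, mu_R=(45.0, 60.0),
                     sigma_R=(0.0, 0.0), labels=("s1", "s2")) -> KineticScheme:
    """Convenience constructor for a two-state exchange scheme."""
    return KineticScheme(labels, np.asarray(mu_R, float), np.asarray(sigma_R, float),
                         np.array([[0.0, k12], [k21, 0.0]]))


def three_state_scheme(
    weights: Sequence[float],
    mu_R: Sequence[float] = (75.0, 55.0, 45.0),
    sigma_R: Sequence[float] = (3.0, 2.0, 2.0),
    relax_rate: float = 4.0,
    labels: Sequence[str] = ("open", "closedA", "closedB"),
) -> KineticScheme:
    """Three-state scheme with a prescribed stationary distribution.

    Rates are chosen as ``k_ij = relax_rate * pi_j`` (Barker-style), which
    makes ``weights`` the exact stationary distribution while keeping
    exchange slow enough (default ~100 ms) that a diffusion burst samples a
    single state, the quasi-static regime assumed by photon distribution
    analysis.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("weights must be three non-negative numbers")
    w = w / w.sum()
    rates = relax_rate * np.tile(w, (3, 1))
    np.fill_diagonal(rates, 0.0)
    return KineticScheme(labels, np.asarray(mu_R, float), np.asarray(sigma_R, float), rates)
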