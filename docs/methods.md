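# Methods

This note documents the models, defaults and numerical choices behind
`fretdyn`, and what the synthetic-data validation does and does not show
about real measurements.

## Conformational kinetics

States are labelled conformations with a mean inter-dye distance `mu_R`
(Å) and a Gaussian width `sigma_R` (Å); exchange is a continuous-time
Markov chain given by off-diagonal rates (1/s).  Paths are sampled by
exact stochastic simulation (Gillespie); dwell times are exponential in
the state's total exit rate.  The stationary distribution comes from the
left null space of the generator and relaxation times from its non-zero
eigenvalues.  `three_state_scheme` builds an open / closed A / closed B
scheme with Barker-style rates `k_ij = relax_rate * pi_j`, so a requested
stationary distribution is planted exactly; the default `relax_rate` of
4 1/s keeps exchange far slower than a diffusion transit, the quasi-static
regime that burst-wise PDA assumes.  `two_timescale_scheme` composes two
independent symmetric telegraph switches (relaxation times `tau` mean
flip rates `1/(2 tau)`) that multiply the FRET efficiency by `(1 ± a)`;
each switch contributes a clean `a² exp(-t/tau)` term to the FRET-channel
correlation with relative weight `a²/(1+2a²)`.

## Photon generator

The generator emulates a dilute two-colour PIE confocal experiment:

- Bursts start at exponential waiting times (default 10 per second) and
  are rectangular: constant peak brightness (default 1e5 detected
  counts/s) over a random transit.  Transit durations are exponential
  (mean 2 ms) by default; the `"diffusive"` option draws them from the
  distribution whose rectangular-pulse on/off correlation equals the 3D
  Gaussian-focus diffusion factor `(1+t/τ_D)⁻¹(1+t/(κ²τ_D))^{-1/2}`
  (survival function `1−F(t) = G'(t)/G'(0)`), which makes the diffusion
  term of an FCS fit exactly well specified.  Rectangular bursts keep
  burst statistics analytically checkable; intensity variation across the
  focus is deliberately not modelled.
- Each burst is a fresh molecule: the hidden state is resampled from the
  stationary distribution at burst start and evolves by Gillespie during
  the transit.  The inter-dye distance is redrawn from the state's
  Gaussian once per dwell (static within-state heterogeneity, matching
  the PDA picture).
- Photon routing: each photon falls in the donor or acceptor PIE
  half-period with probability 1/2.  A donor-excitation photon is emitted
  by the acceptor with probability `E(R)`; detection thinning implements
  `γ = η_A/η_D`; a detected donor-emission photon leaks into the acceptor
  channel with probability `α/(1+α)` so that the standard correction
  `F_DA − α F_DD` is exact in expectation, and direct excitation adds
  Poisson DA photons with mean `δ F_AA`.  Microtimes are exponential with
  the apparent lifetime `τ_D0 (1−E)` (DD) or the acceptor lifetime
  (DA/AA), truncated to the half-period; a warning is raised when the
  half-period is shorter than ~5 lifetimes.
- Background is uniform in time per channel (default 1 kHz each).
- One root seed spawns child streams in a fixed order (burst placement,
  state paths, routing, microtimes, background), so components are
  individually reproducible.

Dye constants default to a mid-60s-Å Förster-radius pair: `R0 = 65 Å`,
`τ_D0 = 3.5 ns`, `τ_A = 3 ns`, PIE period 50 ns.  An optional static
acceptor-dark fraction emulates photophysics; polarisation, anisotropy
and dye photochemistry beyond that are out of scope.

## Burst analysis

The all-photon sliding-window search marks a photon as in-burst when at
least `m` photons (default 10) fall within a window `T` (default 500 μs)
centred on it; maximal runs with at least `L_min = 50` photons become
bursts, and a run is additionally split wherever the inter-photon gap
exceeds `T` (otherwise two molecules with no stray photon between them
would merge).  The search window also drags stray photons up to
`T/2 − m/rate` beyond the transit into the burst; `window_extension`
quantifies this so background exposure can be corrected (the recovery
workflows use `m = 20`, which tightens the edges).  Corrections follow
the community-standard chain; corrected E and S may fall slightly outside
[0, 1] under shot noise, which is expected and flagged rather than
clipped.  Burst lifetimes invert the truncated-exponential mean
`m(τ) = τ − T/(e^{T/τ}−1)`; no instrument-response reconvolution is
attempted (none is modelled).

## PDA

The forward model computes, per empirical burst-size group `N`,

    P(F_A | N) = Σ_{a,d} P(a) P(d) · Binom(F_A − a; N − a − d, p_app(R)),

with `p_app(R) = E(R) + (1−E(R)) α/(1+α)` and Gaussian distance states
integrated by 15-node Gauss–Hermite quadrature (9 nodes inside the
fitting basis).  Background counts are Poisson with a per-size-group mean
proportional to the group's mean burst duration — a constant-per-burst
background systematically over-widens the prediction because short
bursts collect proportionally less background.  Burst sizes are
compressed to at most 64 quantile groups and clipped at 512 photons
(shot noise is negligible there); size groups are processed in chunks so
small bursts do not pay the largest burst's count range.  For bursts of
at most ~12 photons the model is verified against exhaustive enumeration
of every photon partition to machine precision.

Fits minimise Pearson χ² on merged bins (≥ 5 observed counts, fixed from
the data) over widths and weights — and means, unless constrained — via
trust-region least squares on Pearson residuals, with 16 random
multi-starts and softmax-parameterised weights.  Model evaluation inside
the optimiser interpolates a precomputed single-state basis on a
(μ, σ) grid (≈1.5 Å / 1 Å resolution); reported statistics are always
recomputed with the exact forward model.  State counting minimises the
BIC of the multinomial histogram likelihood; ties prefer fewer states.
Population-ratio confidence intervals come from multinomial bootstrap
resampling of the histogram with refits started at the best solution
(interpolated evaluation only — only weights matter there).  The
bootstrap CI quantifies estimation noise for the realised burst sample;
the sample's own ratio fluctuates around the planted value with
`SE ≈ ratio · sqrt(1/n_B + 1/n_A)`, which at 10⁴ bursts is ±0.04 for a
ratio of 1.6.

## FRET-FCS

Correlations are photon-pair counts on a geometric lag grid (8 points
per octave, the multi-tau layout) normalised by the uncorrelated
expectation with a finite-window correction; uncertainties come from
10-segment splitting.  The global fit shares the kinetic times across
channel pairs, keeps amplitude, diffusion time and kinetic amplitudes
free per curve, weights by 1/sem², and multi-starts over a log-spaced
grid of time pairs.  Two physically motivated constraints stabilise the
otherwise multi-modal problem: autocorrelation kinetic amplitudes are
non-negative (they are variance contributions), and kinetic times are
bounded below the diffusion plateau.  The recovery workflow fits lags up
to 2 ms and uses crosstalk-free channels, so the planted kinetic weight
is the stream's actual FRET-channel weight (leakage and direct
excitation would otherwise dilute it by a predictable factor).  The
focal aspect ratio is fixed at κ = 5.

## Accessible volumes

The AV1 single-sphere model (defaults: linker 21 Å, width 4.5 Å, dye
radius 3.5 Å, uniform weighting, fixed atom radii) is evaluated on a
cubic grid.  Cells with an unobstructed straight line to the attachment
point receive the exact Euclidean geodesic; shadowed cells are reached by
multi-source Dijkstra over the 26-neighbour graph — the line-of-sight
initialisation avoids the chamfer-metric inflation of pure grid flood
fills, so free-space volumes converge to `(4/3)πL³` within discretisation
error.  A buried attachment yields an empty AV with a distinct flag.
Efficiency averaging is isotropic (κ² = 2/3 absorbed in R0) and
exhaustive over cell pairs when feasible, Monte-Carlo otherwise; pairs
closer than 1 Å are excluded and counted.  Ensembles use common random
numbers across models so frame-to-frame differences are not masked by
sampling noise.

## Trajectory observables

Superposition is Kabsch (SVD with reflection guard); domain RMSD fits on
one selection and measures on another without refitting.  Contact PCA
uses residue-bead distances with a 10 Å inclusion cutoff over the union
of frames, z-scores each retained coordinate, and eigendecomposes the
correlation matrix (correlation, not covariance, so stiff and soft
contacts contribute comparably); zero-variance coordinates are dropped
with a record.  The timescale report smooths each series with a 5-sample
running mean and reports first upward threshold crossings, ordered; it is
invariant under common monotone time rescaling.  Default selections use
1-based residue numbering with named middle-domain elements (M-loop
323–340, M-helix 376–408, piston residue 380).

## Validation scale and limitations

The recovery experiments use 10⁴ bursts per population-ratio condition
(dilute sample: 2.5 bursts/s over ~5200 s, chosen so two-molecule
pile-up stays below ~1%) and a 100 s stream at 3e5 counts/s peak for the
FCS recovery; `tests/` runs scaled-down versions of the same workflows.
Passing these recoveries shows the analysis chain is self-consistent and
unbiased under its own generative assumptions — rectangular bursts,
quasi-static or telegraph exchange, exponential decays, uniform
background, no detector dead time or afterpulsing, no dye photophysics
beyond an optional static dark fraction.  Real data violate several of
these (diffusion-path intensity variation, IRF, acceptor blinking),
so quantitative agreement there additionally requires the standard
experimental calibrations that this package takes as given inputs.
Residual known bias: mixed-state bursts from pile-up and in-burst
exchange are fitted as static mixtures (dynamic PDA is out of scope),
which can depress recovered population ratios by a few percent of their
value at the chosen conditions.
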