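# Methods

## Kinetic model

### State space and transitions

Each reaction center (RC) occupies one of 12 redox states, the product of
the dimer (P, P⁺), the primary quinone (Q_A, Q_A⁻) and the secondary
quinone site (Q_B, Q_B⁻, Q_BH₂). This is the minimal closure of the
reaction scheme under its four dark processes:

| process | transition | rate | units |
|---|---|---|---|
| photochemical closure | (P, Q_A, b) → (P⁺, Q_A⁻, b) | `k_I (1 − φ(x; p))`, shared over open states by occupancy | s⁻¹ |
| donor re-reduction | (P⁺, a, b) → (P, a, b) | `k₂ [donor]` | s⁻¹ |
| first inter-quinone transfer | (d, Q_A⁻, Q_B) → (d, Q_A, Q_B⁻) | `A1` | s⁻¹ |
| second transfer | (d, Q_A⁻, Q_B⁻) → (d, Q_A, Q_BH₂) | `A2` | s⁻¹ |
| quinol/quinone exchange | (d, a, Q_BH₂) → (d, a, Q_B) | `E` | s⁻¹ |

Assumptions built into the scheme:

* Only fully open RCs (P, Q_A, ·) are photochemically active; P⁺ and Q_A⁻
  both block stable charge separation, and no double reduction of Q_A is
  modelled.
* The membrane quinone pool is in large excess, so `E` regenerates Q_B
  directly with no empty-site state.
* The donor pool is a single effective species consumed by mass action
  (`d[donor]/dt = −k₂ [donor] P⁺ [RC]`) and never regenerated: cytochrome
  *bc*₁ recycling is absent by construction, matching the
  myxothiazol-blocked experimental regime. Tetraheme-carrying wild types
  are represented by an effective pool size and `k₂`, not by four explicit
  hemes. Donor re-binding is pure mass action; product inhibition of the
  donor site is not modelled.
* Ferricyanide treatment enters only as a reduced initial pool (the
  hours-long oxidation is static on the millisecond run timescale).

Useful closed forms used throughout the tests: with saturating continuous
light every RC closes once and each pool donor enables exactly one further
closure (if `A1 > 0`), so the asymptotic number of charge separations per
RC is `N = 1 + pool`; with `A1 = 0` (terbutryn) it is 1 regardless of pool;
with `E = 0` the acceptor side caps at 3.

### Connectivity yield maps

Two maps connect the closed fraction `x` to the normalized variable
fluorescence φ for hopping probability `p ∈ [0, 1)`:

* **cluster mean-field cubic** `φ = (1−p)x + (1−p)p x² + p²(x²/4 + 3x³/4)`
  — the forward map used by the simulator (both for the reported φ and
  for the closure flux);
* **hyperbolic (Joliot-type)** `φ = x(1−p)/(1−px)`, inverse
  `x = φ/(1 − p(1−φ))` — the map used to reconstruct redox states from
  measured traces.

Both maps satisfy φ(0) = 0, φ(1) = 1 and φ′(0) = 1−p, so the initial-slope
and single-turnover-area limits (`Slope = (1−p)k_I`, `Area·k_I = 1`) are
map-independent; at intermediate `x` they disagree for `p > 0`. The
simulator takes the map as an explicit `yield_map` argument
(`"cluster"` default, `"hyperbolic"` available) so reconstruction
round-trip tests can use matching maps; the two are never mixed silently.

### Parameters

| symbol | meaning | units | typical |
|---|---|---|---|
| `k_I` | photochemical rate constant (∝ light intensity) | s⁻¹ | 5×10³–2×10⁴ |
| `k2` | bimolecular donor rate constant | M⁻¹s⁻¹ | ≤ 10¹⁰ (diffusion limit; warning above) |
| `rc_conc` | RC concentration | M | 3–8×10⁻⁶ |
| `A1`, `A2` | inter-quinone transfer rates | s⁻¹ | 10³–3×10⁴; `A1=0` = terbutryn |
| `E` | quinol/quinone exchange rate | s⁻¹ | 10² |
| `p` | exciton hopping probability | – | 0.1–0.3 |
| `pool` | initial reduced donors per RC | – | 0–5 |

Two published simulation parameter sets ship as presets: `pool_scan`
(k_I = 8×10³ s⁻¹, k₂ = 10¹⁰ M⁻¹s⁻¹, [RC] = 8 µM, A1 = 3×10⁴ s⁻¹,
A2 = 2×10³ s⁻¹, E = 10² s⁻¹, p = 0.3), used for the donor-pool titration
and the φ(P⁺) curvature study, and `qa_redox` (k_I = 2×10⁴ s⁻¹,
k₂ = 6×10⁹ M⁻¹s⁻¹, [RC] = 3 µM, A1 = 3×10³ s⁻¹, A2 = 10³ s⁻¹,
E = 10² s⁻¹, p = 0.3) for the PQ_A⁻ rise/decay kinetics.

### Numerics

* Integrator: `scipy.integrate.solve_ivp` with LSODA (stiffness-switching;
  rates span 10² to ~10⁵ s⁻¹ within one run), `rtol = 1e-8`,
  `atol = 1e-12`. The light pulse is handled as two exact segments
  (k_I active, then zero) rather than a discontinuous right-hand side.
* Output grid: 2000 points, linear for the first 10 µs then log-spaced —
  the early rise fixes the slope estimate, the log tail covers donor-limited
  dynamics spanning up to six decades in time.
* Mass conservation is structural in the right-hand side (every term moves
  occupancy between two states); the tests require the 12 fractions to sum
  to 1 within 10⁻⁸ at every output point.
* `simulate_to_saturation` doubles the horizon until the final yield
  exceeds `phi_target` (default 0.995) *and* the cumulative separations
  have converged (relative change ≤ 10⁻⁴ between doublings) — the second
  condition matters for donor-limited strains whose supplementary area
  keeps accruing long after φ ≈ 1.
* Cumulative charge separations are integrated as a 14th ODE component
  (closure flux), avoiding post-hoc quadrature error.

### Stochastic oracle

`stochastic_oracle` runs the identical scheme as an exact-event
(Gillespie) simulation of `n_rc` centers sharing a discrete pool of
`round(pool · n_rc)` donor tokens. The photochemical channel fires at the
ensemble flux `n_rc · k_I (1 − φ(x; p))` and closes a uniformly chosen open
RC, mirroring the mean-field flux rule; event times are sampled
exponentially (ties are impossible by construction — no index-order
tie-breaking exists). The light-off boundary is handled by discarding the
pending event and resampling, which is exact for piecewise-constant rates.
With `n_batches > 1` the ensemble is split into independent batches so φ(t)
carries a standard error; the acceptance suite requires the ODE solution to
lie within 3 SEM of the 10⁴-center ensemble mean on ≥ 95 % of grid points.

## Induction analysis

* **F0**: intercept at t = 0 of a least-squares line through the first 5
  samples.
* **Fmax**: mean of the final 5 % of samples (the saturation plateau). A
  top-value average was rejected: order statistics of noisy samples select
  positive noise excursions, biasing Fmax high and, through the
  normalization, inflating the supplementary area.
* **φ**: `(F − F0)/(Fmax − F0)`, clipped to [0, 1]; the unclipped values
  are kept in trace metadata and used for the area integral, where
  clipping would rectify zero-mean plateau noise into a positive bias.
* **Supplementary area**: trapezoidal integral of (1 − φ) to the end of
  the trace, guarded by a saturation check (max φ ≥ 1 − `saturation_tol`,
  default 0.01) because the nominal upper limit is infinite. Unsaturated
  traces are rejected with the peak value named — the wild-type
  *Rvx. gelatinosus* "does not saturate on this timescale" failure mode.
* **Initial slope**: least-squares fit of `φ = a + s·t + c·t²` over the
  leading samples with φ < 0.15, reporting `s`. The quadratic term absorbs
  the curvature of the rise (a straight line fitted over this window is
  biased low by ~6 % at p = 0); the free intercept absorbs the constant
  offset that F0 noise leaves in the normalization, which a through-origin
  fit would amplify into a large slope error over the short window.
* Derived constants: `k_I = 1/Area` (single-turnover areas only),
  `p = 1 − Area·Slope` (clamped to 0 with a warning for products in
  (1, 1.05], error beyond), `N = A_m/A_s`.
* Replicate traces are averaged point-wise after linear interpolation onto
  the first trace's grid, emulating the experimental signal-averaging
  protocol; the noisy-recovery studies average three recordings per
  estimate.

## State reconstruction and φ(P⁺) curvature

`PQ_A⁻(t) = φ/(1 − p(1−φ)) − P⁺(t)` and
`PQ_A(t) = (1−p)(1−φ)/(1 − p(1−φ))`, applied point-wise after
interpolating P⁺ onto the φ grid. Negative excursions (noise) are clipped
at zero with a warning beyond −0.02. On simulator output generated with
the hyperbolic map the reconstruction is an algebraic identity, and the
four redox-state marginals close to 1 within 10⁻⁶.

The correlation curve pairs (P⁺, φ) normalized to their saturation values,
sorted by P⁺ with duplicates averaged. Its score is the signed area
`∫(φ − P⁺) dP⁺`: **positive = concave** (curve above the diagonal, φ runs
ahead of P⁺, donor-rich), **negative = convex** (below the diagonal,
donor-poor with connected units), |score| ≤ 0.01 = linear (bisectrix).
The sign convention follows the standard geometry of the experimental
curves: a donor-rich strain keeps P⁺ low while Q_A⁻ accumulates, so φ > P⁺
and the curve is concave like √x. `find_curvature_transition` simulates a
pool-size grid, scores each curve and interpolates the zero crossing;
|score| < 10⁻⁶ is treated as signless so the p = 0 bisectrix cannot fake a
transition.

## Relaxation analysis

The relaxation time of a normalized post-pulse decay is reported either as
the interpolated half-time (default) or as the time constant τ of a
single-exponential fit (half-time = τ·ln 2); the underlying decay need not
be exponential, which is why both operational definitions are exposed. The
time axis is seconds since light-off, and the first probe may arrive at
t > 0 — the crossing is interpolated on the absolute axis, not re-zeroed
to the first sample. `simulate_relaxation` runs the model with a 50 µs
pulse (default) and auto-sizes the dark horizon from the slowest re-opening
channel. Sparse flash-probe series are ordinary (time, value) samples; the
probe flashes are taken as non-actinic. Four-flash series fall below the
trace container's 8-sample minimum and are handled by the bare
`half_time_from_points` helper — a documented degraded regime.

## Synthetic data generator

The generator emulates the strain-panel experiments: induction traces are
simulated to saturation, truncated at 3× the saturation-crossing time (a
realistic recording window; integrating noise over an arbitrarily long
plateau would only degrade the area estimate), mapped to raw fluorescence
`F = F0 + (Fmax − F0)φ` (defaults F0 = 1, Fmax = 3 a.u.) and given
multiplicative Gaussian noise (default σ = 1 %; the experiments report
signal averaging but no noise figure). Relaxation datasets sample the
dense decay at 15 log-spaced probe times spanning two decades around the
half-time, with 2 % noise as the default study condition. Every dataset
writes a ground-truth sidecar (`*.truth.json`) with the generating
parameters; identical seeds give byte-identical files.

Strain presets place published induction constants (k_I, p) with pool
sizes calibrated on the measured electron counts via the asymptotic
relation N = 1 + pool — gelatinosus_wt pool 3.8 (N ≈ 4.8),
sphaeroides_241 pool 1.4 (N ≈ 2.4), pufC pool 1.2 (N ≈ 2.2), cycA pool 1.0
with a slow donor constant (k₂ = 2×10⁵ M⁻¹s⁻¹) reproducing its
donor-limited, much slower re-opening. Absolute per-strain pool sizes are
not published; the presets are N-calibrated, not literature-calibrated.
Ferricyanide treatment maps duration to pool as an exponential decay with
a 1.2 h e-folding time, chosen so the electron count converges to ~1 after
about 4 h; the exponential shape is a modelling choice.

What the generator does *not* emulate: photon shot noise, detector
nonlinearity, actinic probe flashes, baseline drift, or the confined
diffusion of carriers. Passing recovery tests therefore demonstrate the
correctness and noise-robustness of the analysis chain under multiplicative
Gaussian noise, not its robustness to every instrumental artifact of real
recordings.

## Known limitations

* The mean-field closure flux uses a single ensemble `x`; cell-to-cell
  heterogeneity beyond the modelled ensemble is absent (the Gillespie
  oracle shares this mean-field flux rule by design, so it validates the
  integrator, not the mean-field approximation itself).
* Donor exhaustion is smooth in the ODE; the discrete-pool oracle shows
  the granularity effects are below 3 SEM at 10⁴ centers.
* No Marcus-type distance/driving-force rate estimation, no explicit
  tetraheme chain, no spatial diffusion of carriers, and no multiphase
  (OJIP-like) induction decomposition — bacterial induction is treated as
  a single rise.
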