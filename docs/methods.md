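# Methods

## Model

Two binary sensors (spins) `s₁, s₂ = ±1` form a continuous-time Markov
chain on four states, ordered canonically `(−−, −+, ++, +−)` so that
"cyclic" means increasing index modulo 4. Sensor `i` flips with rate
`Γᵢ = exp[−β sᵢ(hᵢ − bᵢ + J_ij s_j)]`, with directed couplings
`J₁₂ = J + t/2`, `J₂₁ = J − t/2`. The overall timescale constant is fixed
to 1 — it cancels from every steady-state quantity — and the generator
builder additionally rescales all rates by a common factor (largest rate
= 1) purely for floating-point range.

Parameters and units (all energies in units of the signal field; rates in
units of the bare attempt frequency):

| parameter | meaning | default |
|---|---|---|
| `β ≥ 0` | sensor reliability = inverse intrinsic noise | — |
| `J` | symmetric coupling; `J>0` favours correlated states | 0 |
| `t` | nonequilibrium drive = `J₁₂ − J₂₁`; breaks detailed balance | 0 |
| `b₁, b₂` | signal-independent biases, enter as `hᵢ − bᵢ` | 0 |
| `α ∈ (−1,1)` | signal correlation of the bivariate Gaussian prior | — |
| `Δ, δ` | readout potentials `δμ₁,₂ = (Δ ± δ)/2` | 1, 0 |
| `r₀` | maximum readout population | 10 |

`t = 0` is exactly the detailed-balance point (Kolmogorov cycle ratio
`e^{4βt}`); the stationary law is then Boltzmann in
`F = −Σ(hᵢ−bᵢ)sᵢ − J s₁s₂`. For `t ≠ 0` the exact stationary law is
`P ∝ exp[−β(F + δF)]` with a drive correction `δF` built from
`cosh β(h₁ − t s₂)` and `cosh β(h₂ + t s₁)` terms; it vanishes as `t → 0`.
Each completed cycle dissipates free energy `4t` (the equilibrium parts of
the four effective free-energy changes telescope to zero). Both signs of
`t` describe time-reversed twins with identical information; nothing in the
package canonicalises the sign.

## Numerics

**Steady states.** Two independent routes: the closed form (log-domain,
max-subtracted softmax; stable to at least `β = 30`) and the SVD null space
of the generator, which also serves the 44-state readout chain. The null
vector from a double-precision SVD carries error ~`eps/gap`; when the
relative singular-value gap falls below `1e−6` (or negative entries appear)
the solve is repeated with GTH state reduction, which is cancellation-free
and attains entrywise relative accuracy however stiff the generator.
Structural reducibility is decided by strong connectivity of the
transition graph, not by the gap. Tiny negative entries
(≥ −1e−12) are clipped and the vector renormalised.

**Quadrature.** Averages over Gaussian priors use a uniform trapezoidal
grid truncated at ±8σ (discarded mass ~1e−14): 401 nodes for 1-D priors,
201 per dimension for the bivariate prior, laid out along the principal
axes `(h₁±h₂)/√2` with variances `1±α` so ridge-like high-`α` priors are
resolved as well as isotropic ones. A uniform rule is deliberate: the
integrands (conditional entropies) are analytic but their nearest complex
singularities sit ~`π/(4β)` off the real axis, so Gauss-type polynomial
rules converge slowly at moderate `β`, while the trapezoidal rule on a
smooth decaying integrand converges geometrically, with error
~`exp(−2π d/Δh)`. At `β = 4` the default grid agrees with a 10⁵-point
reference integration to below 1e−12 bits; the defaults are adequate
through `β ≈ 10`, beyond which the node count should be scaled ∝ `β`.
`mutual_information(..., check_convergence=True)` re-runs with doubled
nodes and raises if the value moves by more than 1e−8 bits.

**Optimisation.** Deterministic by construction (bit-identical reruns).
Equilibrium (1-D in `J`): an 81-point grid on `[−J_max, J_max]` with
plateau tie-breaking toward the largest `|J|`, then bounded scalar
refinement. 2-D/3-D modes: Nelder-Mead from a fixed start lattice
(`J ∈ {−3,0,3}` crossed with drive/bias/δ starts), always seeded
additionally with the equilibrium optimum so constraint nesting
`I*(noninteracting) ≤ I*(equilibrium) ≤ I*(full)` can never be violated by
optimiser noise. Coupling magnitudes are capped at `J_max = 20`: beyond
`βJ ≫ 1` the suppressed states are frozen out and the information is flat
to < 1e−9 bits, so an optimum at the bound with information nondecreasing
there (operationally: `I(J_max) ≥ I* − 1e−9`) is reported as *divergent*
rather than as a number. `t* = 0` classification uses `|t*| < 1e−3` and
gain `< 1e−6` bits. Critical reliabilities are located by bisection to
`Δβ = 0.01`; the divergence, sign-change and gain-onset thresholds move by
< 0.02 under node doubling.

## Readout model

The joint chain has `4(r₀+1)` states indexed `4r + state`. Sensor flips
acquire the feedback term `δμᵢ r`; readout steps `r → r±1` occur at rates
`exp[±½β(δμ₁s₁ + δμ₂s₂)]`, independent of `r` except at the boundaries,
where moves out of `[0, r₀]` carry zero rate — the unique
probability-conserving choice that adds no states (the boundary behaviour
is isolated in `build_joint_rate_matrix`). Sensor biases are pinned to
`bᵢ = δμᵢ r₀/2`, centring the feedback so the full population range is
used; `SensorParams` biases are rejected in this context to avoid double
counting. At `t = 0` the joint free energy separates into signal–sensor and
sensor–readout parts, so `P(r|S,H) = P(r|S)` and the data-processing
inequality `I(S;H) ≥ I(r;H)` holds identically; `dpi_check` audits both
facts over random equilibrium draws through the numeric solver (the
factorisation on a fixed 5-point signal set, since it holds pointwise and
each stiff 44-state solve costs ~0.1 s). Out of equilibrium both fail, and
the readout can hold more signal information than the instantaneous sensor
state. Equilibrium readout optimisation uses the vectorised Boltzmann path;
the nonequilibrium path solves the joint chain per node.

## Design choices that were genuinely open

- *Divergence handling*: a flag plus the bound value, never `∞`, so results
  stay serialisable and comparable.
- *Sign of the drive*: reported as `|t*|`; the two signs are exact
  time-reversed partners under the symmetric priors used here.
- *Biases in the sensor-only model* enter exactly as field shifts
  `hᵢ − bᵢ`, so the biased-equilibrium strategy needs no separate model.
- *Region classification* of the strategy map: region I = divergent
  equilibrium coupling, II = finite coupling and zero drive, III = nonzero
  drive, with the gain threshold (1e−6 bits) deciding "nonzero" — an
  explicit convention, since near the boundary the optimum is genuinely
  shallow.

## What the tests do and do not show

All quantitative tests run on the synthetic Gaussian-prior conditions the
model defines — there is no external data in this problem. Passing them
shows the package solves *this* model to the stated precisions; it says
nothing about how well two-state sensors, Gaussian priors or
r-independent readout kinetics describe any particular biological system.
Known limitations: exactly two sensors (plus readout); stationary signals
only; no sensor–signal crosstalk or false ligands; quadrature defaults
sized for `β ≲ 10` (scale nodes for larger `β`); the `full` readout
optimisation is the one expensive path (stiff 44-state solves per node ×
Nelder-Mead evaluations) and is sized accordingly in tests.
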