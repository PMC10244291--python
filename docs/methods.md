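# Methods

## The model

`calcalk` simulates a two-variable ocean carbon-cycle oscillator in which
glacial–interglacial sawtooth cycles emerge from the interplay of ocean
alkalinity `A` (mol eq m⁻³) and a calcifier population `C` (mol eq m⁻³,
integrated internally as `P = ln C` for numerical range). Weathering
supplies alkalinity; calcifiers grow at rate `kA`, and their shell burial
(at sedimentation rate `M`) removes alkalinity through the reaction term
`kAC`:

    dA/dt = I0 (1 + γ S(A)) − k(t) A e^P
    dP/dt = k(t) A − M

Two extensions around the base oscillator carry the physics of interest:

- **Bounded positive weathering feedback.** The alkalinity input is
  modulated by `γ S(A)` with the saturating sigmoid
  `S(A) = (2/π) arctan(π (A − A0) / (2 z0))` — odd about the midpoint
  `A0`, slope `1/z0` there, limits ±1. It idealizes enhanced carbonate
  weathering from continental shelves exposed at glacial (high-alkalinity)
  times and reduced input during interglacials. `γ` is the feedback
  strength; `γ ≤ 0.12` keeps the input within ~12% of its mean.
- **Periodic astronomical forcing.** The reaction rate is modulated as
  `k(t) = k0 (1 + α cos(2π t / T))`, default period `T = 40` kyr
  (obliquity-like) and amplitude `α` of a few per mil. A multi-component
  extension `k0 (1 + Σ αᵢ cos(2π t / Tᵢ + φᵢ))` supports mixed
  obliquity/precession forcing. The phase is 0 at `t = 0` and is tied to
  absolute time, so feedback-schedule changes never reset it.

Reference parameters (the shipped defaults): `I0 = 4×10⁻⁶` mol eq m⁻³
yr⁻¹, `k0 = 0.05` (mol eq)⁻¹ m³ yr⁻¹, `M = 0.1` yr⁻¹, `A0 = 2.0`,
`z0 = 0.1` mol eq m⁻³. Units: "mM eq" quantities are read as mol eq m⁻³
(numerically identical; this keeps `A* = M/k0 = 2.0` equal to `A0`), and
time is in years throughout. `P` is the log of the numeric value of `C`
in mol eq m⁻³ (taking logs of a dimensional quantity is by convention).

## Local analysis

The unforced (α = 0) system has the unique equilibrium `A* = M/k0`,
`C* = I0 (1 + γ S(A*))/M`; at the defaults `A* = A0`, so `S(A*) = 0` and
the equilibrium is γ-independent at `(2.0, 4×10⁻⁵)`. The Jacobian there
has positive determinant `k0 M C*`, so stability is governed by the
trace `I0 γ S′(A*) − k0 C*`: the equilibrium loses stability through a
supercritical Hopf bifurcation at `γ_H = k0 z0 / M = 0.05` (closed form
when `A* = A0`; located by root finding otherwise; supercriticality is
verified numerically by the small stable limit cycle just above
threshold rather than by first-Lyapunov-coefficient algebra). Below
threshold the damped spiral has the linearized period
`2π / Im λ ≈ 14.05` kyr, which depends only weakly on γ.

## Cycle observables

Periodicity is the time between successive local maxima of alkalinity;
amplitude is the drop from a maximum to the following minimum. Peaks are
found with `scipy.signal.find_peaks` with prominence ≥ 1% of the overall
alkalinity range (rejects sub-percent ripple, does not touch the
sawtooth; the threshold is this package's choice), max/min alternation is
enforced, boundary-truncated cycles are dropped, and peak *times* are
refined to sub-grid precision by parabolic interpolation (values stay
on-sample). Two asymptotic observables follow:

- **Internal period T0**: the periodicity the unforced system approaches
  (mean of the trailing 50 cycles of a long run).
- **Average duration D**: the same under non-zero forcing. Plotting D
  against T0 (or γ) exposes the frequency-locking staircase with
  plateaus at integer multiples of T.

The reference protocol is a 100-Myr run averaging the final 50 cycles;
the long-run observables are insensitive to the horizon once the
transient has decayed (convergence typically takes ~20 Myr), so this
package defaults to `horizon = 1e8` yr but the test and acceptance
workflows use 20–50 Myr for the constant-γ observables and 150 Myr for
the step experiments. A convergence diagnostic — trailing-spread ≤ 5% of
the mean — is attached to every estimate (this package's addition; never
silently hidden).

## Locked orbits, Floquet analysis, envelopes

A D = n·T locked state is a fixed point of the n-period stroboscopic map
(state advanced by exactly n forcing periods from forcing phase 0).
`find_periodic_orbit` solves `Φₙ(x) = x` by Newton iteration, using the
monodromy matrix of the variational flow `dΦ/dt = J(t) Φ` as the map
Jacobian; it converges to stable and unstable orbits alike, so orbits can
be continued in γ past their loss of stability. Monodromy eigenvalues
(Floquet multipliers μ) convert to an e-folding time
`τ = |period / ln |μ_dom||`; every monodromy computation is checked
against the Liouville identity `det Φ = exp(∫ tr J dt)` to < 10⁻⁶
relative. Orbit residuals are required < 10⁻⁸ in state units.

The independent cross-check fits the *envelope* of the per-cycle
periodicity during transients: deviations |periodicity − n·T| oscillate
under an exponentially decaying (or growing) envelope; the envelope
maxima are fitted log-linearly in time. Decay windows run from the
envelope maximum until 10% of the initial deviation remains; growth
windows are capped where the deviation exceeds half the inter-multiple
gap (T/2), i.e. before the intermittent phase between multiples.
Non-exponential envelopes are flagged (`ok=False`), never silently
fitted. Chaos is diagnosed by the largest Lyapunov exponent via
Benettin-style tangent-vector renormalization, cadence one forcing
period, first 20% of the horizon discarded.

## Feedback-shift experiments

`step_experiment` / `ramp_experiment` drive γ through a step (γ₁ → γ₂ at
`t_c`, default 5×10⁷ yr) or a linear ramp over `Δt`, under α = 0.003 and
T = 40 kyr. The γ discontinuities are integration breakpoints (the solver
restarts there, so the jump is never smoothed). "Sustained locking" is
operationalized as 20 consecutive cycles within 2% of the locked
periodicity; the transition delay is the time from `t_c` to the first
such run at the new multiple — the reference for the delay being of
order 10 Myr for 0.06 → 0.09. Censoring (no sustained lock within the
horizon) is reported, not hidden.

## Numerical choices

- **Solver**: scipy's adaptive DOP853 with rtol = atol = 10⁻¹² defaults.
  The governing contract is accuracy, not solver identity: halving both
  tolerances changes any reported periodicity by < 0.1% (asserted in the
  suite; it holds already at rtol 10⁻⁹, which the long-horizon workflows
  use). Trial-step overflow of `e^P` is rejected by the error controller;
  genuine blow-up raises a diagnosable error with the last valid time.
- **Output grid**: uniform 100-yr spacing (≪ the 14-kyr shortest internal
  period); periodicity estimates are grid-invariant to < 0.1% against a
  50-yr grid.
- **Initial conditions**: the reference protocol does not pin them; the
  default is the equilibrium with A perturbed by +0.05 mol eq m⁻³.
  Long-run observables are insensitive to this within an attractor's
  basin — but see the multistability note below.
- **Orbit search**: Newton tolerance 10⁻¹⁰, seeded from converged runs or
  from a neighbouring-γ orbit when continuing into the unstable regime.

## Behaviour at the top of the staircase, and multistability

With the shipped parameters the internal period grows nearly linearly
above the bifurcation: T0 ≈ 37 kyr at γ = 0.06, 55 kyr at 0.07, 120 kyr
at γ ≈ 0.11, and ≈ 136 kyr at γ = 0.12. Under α = 0.003 the average
duration locks cleanly at 40 kyr (γ ≈ 0.06), 80 kyr (γ ≈ 0.085–0.09) and
120 kyr (γ ≈ 0.105–0.115). At γ = 0.12 the cold-started forced system
settles into a quasi-periodic ≈ 136-kyr state that is *not* an integer
multiple of the forcing — yet a stable, exactly locked 120-kyr orbit
coexists at the same parameters (a trajectory settled into the 120-kyr
lock at γ = 0.115 and continued to γ = 0.12 stays locked indefinitely).
Which state is reached is an initial-condition effect, consistent with
the documented sensitivity of the 0.09 → 0.12 step response to the
pre-step state (an exactly-80-kyr-locked pre-state transitions to the
136-kyr attractor; an unlocked ≈ 87-kyr pre-state relocks at 120 kyr
within ~1 Myr). Reported 120-kyr figures at "γ ≈ 0.12" should therefore
be read against our curve at γ ≈ 0.11.

## What the simulations do and do not show

All inputs are generated by the simulator itself; there is no external
data. The model idealizes the ocean's alkalinity cycle to two variables:
no carbonate speciation (CO₂/DIC/pH), no noise forcing, no quasi-periodic
astronomical solution — the forcing is a pure cosine (or a two-cosine
mixture). Passing tests therefore demonstrate the internal consistency of
the dynamical mechanism (feedback-controlled internal period, frequency
locking, delayed relocking after feedback shifts), not a quantitative
reconstruction of the Pleistocene record. Known limitations: time
constants from envelope fits carry a ~10–20% method spread against the
Floquet values (window-selection sensitivity); the transition delay
depends on the operational sustained-lock criterion and on how settled
the pre-step state is; and the fine structure of the staircase between
the integer plateaus (rational locks, quasi-periodicity) is resolved only
as far as the γ grid is refined.
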