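# Methods

## Model family

The simulator implements four variants of the Piecewise Quadratic Neuron
(PQN) model.  All variables are dimensionless; time is carried in
seconds.  `I_stim` enters only the `v` equation, scaled by `k` and offset
by the bias `I₀`.

**Two-variable** (`v`, `n`): the fast subsystem

    dv/dt = (φ/τ)(f(v) − n + I₀ + k I_stim)
    dn/dt = (1/τ)(g(v) − n)

**Three-variable** adds a slow variable `q` subtracted from the `v`
drive:

    dv/dt = (φ/τ)(f(v) − n − q + I₀ + k I_stim)
    dq/dt = (ε_q/τ)(h(v) − q)

**Four-variable** adds a linear slow variable `u` *added* to the drive:

    dv/dt = (φ/τ)(f(v) − n − q + u + I₀ + k I_stim)
    du/dt = (ε_u/τ)(v + v₀ − α_u u)

**Extended four-variable** keeps `u` out of the `v` equation and instead
gates the recovery rate:

    dn/dt = (η(u)/τ)(g(v) − n),   η(u) = η₀ if u < r_u else η₁.

`f`, `g`, `h` are two-branch quadratics `a(v−b)² + c` with junctions at
`0`, `r_g`, `r_h`.  The negative-branch coefficients and the
positive-branch curvature are free; the positive-branch vertex and
offset are always *completed* from value- and slope-continuity at the
junction and never read from a file.  Branch selection is
right-inclusive (`v ≥ r` takes the positive branch); for `f`, `g`, `h`
continuity makes the choice invisible, while for the genuinely
discontinuous `η` switch the threshold value belongs to the upper state.

An equivalent formulation assembles the same right-hand sides from the
core functions `P1(x,x0) = x0 − x`, `L1(x,x0,x1,x2) = x1 + x2(x−x0)`,
`S1(x,x0,x1,x2) = x1 if x < x0 else x2` of the
polynomial/piecewise-linear/step framework, with the `v`, `q`, `u`
equations carrying time scales `τ/φ`, `τ/ε_q`, `τ/(ε_u α_u)` and no bias
term.  The package keeps this second formulation (`pls_derivatives`)
purely as an independent cross-check; tests require pointwise agreement
with the direct equations to 1e−12 at `I₀ = 0`.

## Integration

Explicit Euler on a uniform grid, synchronous semantics: every
derivative is evaluated from the time-`t` state before any assignment,
exactly as a pipelined hardware engine computes `v_next … u_next` from
the current registers.  The `η` switch likewise reads the time-`t` `u`.
The step is 1 ms for the parabolic burster (whose time constant `τ` is
ten times larger) and 0.1 ms for every other mode; `dt` is stored with
the parameters but overridable per run, since convergence tests need
other values.  The float backend aborts when `|v| > 1e6` (the quadratic
right-hand side grows without bound under bad parameters) and reports
the offending step index.  Initial state defaults to the resting
equilibrium at `I_stim = 0` when the nullcline-intersection scan finds
one (1000-point bracket scan + Brent refinement, leftmost root), else
zeros; the choice is recorded in the trace metadata.

## Fixed-point backend

State words live in Q-format two's complement: `total_bits` wide with an
`integer_bits` integer part that *includes* the sign bit, so q18.8
carries 10 fraction bits and q28.8 twenty.  The defaults per mode —
28-bit for Class II, 18-bit otherwise — follow the precision the Class II
phase-resetting curve needs.

The datapath folds `dt` and the time-scale factors into per-term
constants (a bare `dt` of 1e−4 is below the resolution of a
10-fraction-bit word, so folding is the only faithful arrangement).  For
each state equation and each nullcline branch the engine holds three
constants — for `v²`, for `v`, and an additive constant — plus coupling
constants for `n`, `q`, `u`, and the stimulus.  `v²` comes from the one
true multiplier (full integer product, arithmetic right shift, i.e.
truncation toward −∞); every constant multiplication is a shifter/adder
network applied to the raw word, each right shift truncating its low
bits independently before the terms are summed.  Constants are planned
with 8 extra fraction bits beyond the state format: shifts act on raw
integers, so coefficient bits below the state resolution still
contribute.  Consequences that the tests pin down: a single 28-bit step
tracks the float step to a few raw units (one truncation per term, ~5
terms per equation), and trace error versus the float backend falls
monotonically as the word grows from 10 to 30 fraction bits.  Overflow
policy is configurable — wrap (two's complement, the hardware default),
saturate, or error — with a wrap counter surfaced in the trace metadata
so silent divergence is visible.

## Hardware planning

Multiplying a state variable by a constant costs one shifter/adder pair
per set bit of the constant's plain binary representation, so
`decompose_coefficient` quantizes the magnitude to a given number of
fraction bits and returns the set-bit positions; plain binary (not
canonical signed digit) is used because the resource model counts ones
in the binary representation.  Negative constants carry a sign and the
hardware subtracts.  A single DSP slice multiplies 25×18 bits; squaring
a `w`-bit word therefore tiles `ceil(w/25)·ceil(w/18)` slices — 1 for
18-bit states, 4 for 28-bit.  Real-time capacity of one shared engine is
`round(clock·dt)` cycles per step minus the engine pipeline depth
(4 cycles) and FIFO read/write latency (3 cycles): 9,993 neurons at
100 MHz and 0.1 ms, 99,993 at 1 ms.

## Analysis toolbox

Spikes are upward crossings of `v` through a threshold (default 0, the
`f` junction), debounced by a minimum separation of `2·dt` and refined
by linear interpolation between the bracketing samples.  ISI statistics
follow the Shinomoto conventions with `m` = number of *intervals*:

    CV = sqrt((1/(m−1)) Σ (T_i − T̄)²) / T̄
    LV = (1/(m−1)) Σ_{i<m} 3 (T_i − T_{i+1})² / (T_i + T_{i+1})²

Both are exactly zero for constant ISIs, and LV's coefficient 3 makes
its Poisson expectation 1 — the seeded exponential-interval generator in
the package reproduces 1.00 ± 0.02 at 10⁵ intervals for both statistics.
Burst segmentation opens a new burst wherever an ISI exceeds a gap
threshold (default 5× the median ISI, scale-free across the bursting
classes); window-clipped leading/trailing bursts are flagged, not
dropped.  The phase-resetting curve measures the first-order shift only:
after the train settles (≥ 10 consecutive ISIs within 2·dt of their
mean; the first 20 % of the run is discarded as transient), a probe
pulse lands at phase `θ` of a late cycle starting at spike time `t_s`,
and `Δ(θ) = (T − T_i)/T` where `T_i` is that cycle's perturbed length.
Second-order (next-cycle) effects are out of scope.

## Bundled parameter sets

No externally fitted per-class parameter values ship with this package:
the bundled modes are qualitative sets designed here by numerical
exploration, and each file says so in a comment.  They reproduce the
class *signatures*, not any particular conductance model's traces:

- `class2` — rest on the middle `f` branch near a subcritical Hopf
  (`φ f′(v*) < 1` at rest); the f–I curve jumps discontinuously to
  ~250 Hz at onset, spike peaks grade with pulse amplitude, and the PRC
  is biphasic.
- `rs_exc` / `rs_inh` — a shallower `g` creates a saddle-node onset
  (Class I-like), so the first ISI is the shortest and the slow `q`
  (`h ≈ 0` at rest, positive over the spiking range) lengthens ISIs
  monotonically; the inhibitory set adapts more strongly.  Clean
  monotone ranges: drive ≥ 0.4 (exc), ≥ 0.5 (inh); below that the
  adapted state sits near the bifurcation and the ISI sequence stutters.
- `fs` — higher `φ`, small fast `q`: high rates with weak adaptation
  confined to stimulus onset.
- `eb` — the Class II fast subsystem is bistable (spiking persists below
  the Hopf point down to a fold of cycles); `q` with a junction at
  `r_h = −0.25` sweeps the drive through the window, giving repetitive
  bursting over drives ≈ 3.8–4.4 with spikes-per-burst rising and
  interburst intervals shrinking as drive grows.
- `pb` — `τ = 10 ms`; the slow pair is an activator–inhibitor
  oscillator: `u` (gain `1/α_u = 2`, time constant 0.25 s) feeds drive
  back positively, `q` (2 s) terminates bursts; bursts over drives
  ≈ 0.2–1.0, burst length growing with drive.
- `ib` — `u` starts below `r_u`, so the fast recovery `η₀ = 3` produces
  an onset burst; after `u` crosses `r_u` the slower `η₁ = 1` regime
  yields sparse regular firing (first ISI < 0.6× asymptotic).
- `lts` — `h` is negative below rest, so hyperpolarization charges `q`
  negative (a deinactivation-style reservoir) and release fires a
  rebound burst, slowed `η₀ = 0.8` while `u < r_u`; positive steps show
  strong adaptation (clean monotone range: drive ≥ 0.8).

What passing tests show — and what they do not: the qualitative suite
demonstrates that each mode has its class's dynamical structure under
the stated stimulus protocols.  It does not show quantitative agreement
with ionic-conductance models or with any published fitted set; ISI
magnitudes, burst periods, and operating ranges here are properties of
the designed sets.

## Numerical choices

- ISI monotonicity comparisons allow one Euler step (`dt`) of slack:
  spike times carry O(dt) discretization error even with sub-grid
  interpolation (observed jitter ≈ 0.07 dt).
- Junction-smoothness oracles use 3-point one-sided finite differences,
  exact for quadratics, with the left probe one ulp below the junction;
  residuals are pure float rounding (< 1e−12, asserted < 1e−10).
- Equilibrium refinement uses `xtol = 1e−14` Brent; "no equilibrium"
  means no sign change on a 1000-point scan of the bracket.
- The exhaustive fixed-point multiplication check runs the full 8/4
  format (65,536 raw pairs) against integer rational truncation.
- Experiment problem sizes (8 s runs for the elliptic burster, 30 s for
  the parabolic one, 10⁵ Poisson intervals) are chosen so that every
  statistic rests on tens of bursts or better while the whole suite
  stays interactive.

## Known limitations

- No synapse model, no networks, no parameter fitting: single neurons
  under programmed stimuli only.
- Adaptive or higher-order integrators are deliberately absent; Euler is
  part of the modeled system, not an approximation choice.
- The fixed-point engine emulates one specific datapath (per-term
  truncation, pre-scaled constants); other constant-multiplier layouts
  would differ in the low bits.
- LUT/FF resource counts of a synthesized design are tool- and
  device-dependent and are not modeled; only the arithmetic-level
  proxies (ones counts, DSP tiles, cycle budgets) are computed.
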