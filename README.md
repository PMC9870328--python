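# pqnsim — Piecewise Quadratic Neuron model simulator

`pqnsim` simulates the Piecewise Quadratic Neuron (PQN) model family: a
qualitative spiking-neuron model whose nullclines are built from two
quadratic branches joined so that each nullcline is continuous and smooth.
Because the right-hand sides contain nothing but quadratics, comparisons,
and constant multiplications, the model maps directly onto digital
arithmetic circuits — a single hardware multiplier squares the membrane
variable, and every constant multiplication becomes a short chain of
shifters and adders.  The package is aimed at computational
neuroscientists who want qualitatively faithful neuron classes at
integrate-and-fire cost, and at hardware designers sizing real-time
neuromorphic pipelines.

## The model

The two-variable core is a FitzHugh–Nagumo-like fast subsystem

    dv/dt = (φ/τ) (f(v) − n + I₀ + k·I_stim)
    dn/dt = (1/τ) (g(v) − n)

where each nullcline is piecewise quadratic,

    f(v) = a_fn (v − b_fn)² + c_fn   (v < 0)
           a_fp (v − b_fp)² + c_fp   (v ≥ 0)

and likewise `g` with junction `r_g`.  The positive-branch vertex and
offset are not free: they are *completed* from the continuity and
smoothness conditions at the junction,

    b_fp = a_fn b_fn / a_fp,
    c_fp = a_fn b_fn² + c_fn − a_fp b_fp².

Three- and four-variable variants add slow variables: `q` relaxes toward
a third piecewise-quadratic nullcline `h(v)` (adaptation and burst
termination), and `u` integrates `v` linearly
(`du/dt = (ε_u/τ)(v + v₀ − α_u u)`), either feeding back into `dv/dt`
(parabolic bursting) or switching the recovery rate `η(u) ∈ {η₀, η₁}` at
a threshold `r_u` (onset bursting and rebound bursting).  All variables
are dimensionless; time is in seconds.  Integration is explicit Euler —
the scheme the hardware pipeline implements — with a 1 ms step for the
parabolic burster and 0.1 ms for every other mode.

Eight neuronal modes are bundled (`class2`, `rs_exc`, `rs_inh`, `fs`,
`lts`, `ib`, `eb`, `pb`).  They are qualitative parameter sets designed
with this package to exhibit each class's firing signature — graded
response and Type II phase resetting (Class II), spike-frequency
adaptation (RS), onset bursts (IB), rebound bursts (LTS), repetitive
bursting (EB/PB) — not fits to any particular conductance model.

Two integration backends share one interface: `float` (IEEE doubles) and
`fixed`, a bit-exact emulation of the hardware datapath in Q-format
two's-complement arithmetic (18-bit words with an 8-bit integer part by
default, 28-bit for Class II), with per-term truncating shift-add
constant multiplication.

## Worked example

Simulate the Class II mode under a current step and measure its spike
statistics:

```
$ pqn simulate --mode class2 --stim step:t0=0.05,amp=0.3 --tmax 0.4 --out c2.csv
```

```python
from pqnsim.io import read_trace
from pqnsim.analysis import detect_spikes, cv_stat, lv_stat

tr = read_trace("c2.csv")
train = detect_spikes(tr)
isis = train.isis()
print("spikes:", len(train), "| mean ISI (ms): %.3f" % (isis.mean * 1e3),
      "| CV: %.4f" % cv_stat(isis), "| LV: %.4f" % lv_stat(isis))
```

    spikes: 95 | mean ISI (ms): 3.703 | CV: 0.0034 | LV: 0.0000

The step drives the neuron across its Hopf bifurcation into tonic
spiking at ~270 Hz; CV ≈ 0 and LV = 0 say the train is metronome-regular
(both statistics are calibrated so a Poisson train gives 1).

Hardware planning uses the same package.  How many neurons can one
100 MHz update engine serve in real time at a 0.1 ms step, and what does
multiplying by a coefficient cost?

```
$ pqn hw budget --clock 1e8 --dt 1e-4
{ "cycles_per_step": 10000, "engine_latency_cycles": 4,
  "fifo_cycles": 3, "capacity": 9993, ... }

$ pqn hw coeff 0.037109375 --frac 10
{ "shifts": [5, 8, 9], "ones_count": 3,
  "reconstructed_value": 0.037109375, ... }
```

10,000 cycles per step minus the 4-cycle engine and 3-cycle FIFO latency
leaves capacity for 9,993 neurons; the coefficient 0.037109375 is binary
`0.000010011`, so multiplying by it costs three shifter/adder pairs
(right-shifts by 5, 8, and 9).

Other subcommands: `pqn prc` (phase-resetting curves), `pqn graded`
(peak-versus-pulse-amplitude curves), `pqn stats` / `pqn bursts` (ISI and
burst statistics of a spike-time CSV), `pqn hw dsp` (DSP tiling).

## Layout

- `src/pqnsim/params.py` — parameter model, smoothness completion, JSON I/O
- `src/pqnsim/dynamics.py` — right-hand sides, Euler backends, equilibria,
  core-function (P/L/S) formulation
- `src/pqnsim/fixedpoint.py` — Q-format arithmetic, truncating multiply,
  shift-add networks
- `src/pqnsim/analysis.py` — spike detection, CV/LV, bursts, PRC, response
  curves
- `src/pqnsim/hardware.py` — coefficient decomposition, DSP tiling, cycle
  budgets
- `src/pqnsim/cli.py`, `io.py` — `pqn` command line and CSV formats
- `docs/methods.md` — model details, parameter-set design, numerical
  choices, limitations
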