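"""Right-hand sides, Euler integration, and equilibria of PQN neurons.

The fast subsystem is a FitzHugh-Nagumo-like pair (v, n) whose nullclines
are piecewise-quadratic; three- and four-variable variants add slow
variables q and u that shape adaptation and bursting.  Integration is
explicit Euler on a uniform grid — the scheme the shared-pipeline digital
implementation realizes — with two interchangeable backends:

* ``float``: IEEE double arithmetic, the reference trajectory;
* ``fixed``: bit-exact emulation of the hardware datapath, in which dt and
  the time-scale factors are folded into per-term constants, each constant
  is applied by its shifter/adder network, and v**2 is the single true
  multiply (see :mod:`pqnsim.fixedpoint`).

All state variables and stimulus values are dimensionless; time is carried
in seconds.  Updates are synchronous: every derivative is evaluated from
the time-t state before any assignment, matching the pipelined engine
where v_next/n_next/q_next/u_next are produced from the current registers.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from . import fixedpoint as fx
from .fixedpoint import QFormat
from .hardware import ShiftAddPlan, decompose_coefficient
from .params import PQNParams, Variant

__all__ = [
    "NeuronState",
    "StimulusProgram",
    "Trace",
    "SimulationError",
    "eval_piecewise_quadratic",
    "eval_eta",
    "derivatives",
    "euler_step",
    "simulate",
    "find_equilibrium",
    "pls_core",
    "pls_derivatives",
    "FixedEngine",
]

Backend = Literal["float", "fixed"]

#: divergence guard for the float backend; the quadratic RHS grows without
#: bound under bad parameters, so runaway |v| is cut off early.
DIVERGENCE_LIMIT = 1e6


class SimulationError(RuntimeError):
    """Float-backend divergence or other unrecoverable integration failure."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


@dataclass(frozen=True)
class NeuronState:
    """State vector of one neuron: (v, n) plus q and u where the variant has them."""

    v: float
    n: float
    q: float | None = None
    u: float | None = None

    def as_tuple(self) -> tuple[float, ...]:
        out = [self.v, self.n]
        if self.q is not None:
            out.append(self.q)
        if self.u is not None:
            out.append(self.u)
        return tuple(out)

    def matches(self, variant: Variant) -> bool:
        need_q = variant is not Variant.TWO_VAR
        need_u = variant in (Variant.FOUR_VAR, Variant.FOUR_VAR_EXT)
        return (self.q is not None) == need_q and (self.u is not None) == need_u


def _check_state(s: NeuronState, p: PQNParams) -> None:
    if not s.matches(p.variant):
        raise ValueError(
            f"state {s} does not match variant {p.variant.value} of mode {p.mode.value}"
        )


@dataclass(frozen=True)
class StimulusProgram:
    """Right-continuous piecewise-constant stimulus; zero outside the program.

    ``amplitudes[i]`` applies on [breakpoints[i], breakpoints[i+1]); the
    final amplitude applies from the last breakpoint onward (append a
    trailing 0-amplitude breakpoint to end a pulse).
    """

    breakpoints: tuple[float, ...] = ()
    amplitudes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.amplitudes):
            raise ValueError("breakpoints and amplitudes must have equal length")
        if any(b >= a for a, b in zip(self.breakpoints[1:], self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, amp: float) -> "StimulusProgram":
        return cls((0.0,), (amp,))

    @classmethod
    def step(cls, t0: float, amp: float) -> "StimulusProgram":
        return cls((t0,), (amp,))

    @classmethod
    def pulse(cls, t0: float, dur: float, amp: float) -> "StimulusProgram":
        if dur <= 0:
            raise ValueError("pulse duration must be positive")
        return cls((t0, t0 + dur), (amp, 0.0))

    def value(self, t: float) -> float:
        i = bisect.bisect_right(self.breakpoints, t) - 1
        if i < 0:
            return 0.0
        return self.amplitudes[i]

    def sample(self, times: np.ndarray) -> np.ndarray:
        if not self.breakpoints:
            return np.zeros_like(times, dtype=float)
        idx = np.searchsorted(self.breakpoints, times, side="right") - 1
        amps = np.concatenate([[0.0], np.asarray(self.amplitudes, dtype=float)])
        return amps[idx + 1]

    def overlay(self, other: "StimulusProgram") -> "StimulusProgram":
        """Pointwise sum of two programs (used to add a probe pulse)."""
        bps = sorted(set(self.breakpoints) | set(other.breakpoints))
        amps = tuple(self.value(b) + other.value(b) for b in bps)
        return StimulusProgram(tuple(bps), amps)


@dataclass
class Trace:
    """Time-indexed record of one simulation on the uniform Euler grid."""

    times: np.ndarray
    v: np.ndarray
    n: np.ndarray
    q: np.ndarray | None
    u: np.ndarray | None
    stimulus: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.meta["dt"])

    def state_at(self, j: int) -> NeuronState:
        return NeuronState(
            v=float(self.v[j]),
            n=float(self.n[j]),
            q=None if self.q is None else float(self.q[j]),
            u=None if self.u is None else float(self.u[j]),
        )

    def columns(self) -> dict[str, np.ndarray]:
        cols = {"time": self.times, "v": self.v, "n": self.n}
        if self.q is not None:
            cols["q"] = self.q
        if self.u is not None:
            cols["u"] = self.u
        cols["I_stim"] = self.stimulus
        return cols


# ---------------------------------------------------------------------------
# right-hand sides

def eval_piecewise_quadratic(
    v: float,
    branch: tuple[float, float, float, float, float, float],
    r: float = 0.0,
) -> float:
    """a_n (v-b_n)^2 + c_n for v < r, a_p (v-b_p)^2 + c_p for v >= r."""
    a_n, b_n, c_n, a_p, b_p, c_p = branch
    if v < r:
        return a_n * (v - b_n) ** 2 + c_n
    return a_p * (v - b_p) ** 2 + c_p


def eval_eta(u: float, p: PQNParams) -> float:
    """Slow-gated time-scale switch: eta0 below r_u, eta1 at and above."""
    if p.variant is not Variant.FOUR_VAR_EXT:
        raise ValueError(f"eta is defined only for FOUR_VAR_EXT, not {p.variant.value}")
    return p.eta0 if u < p.r_u else p.eta1


def derivatives(s: NeuronState, I_stim: float, p: PQNParams) -> tuple[float, ...]:
    """Time derivatives of the state, evaluated from the current state only."""
    _check_state(s, p)
    fv = eval_piecewise_quadratic(s.v, p.f_branch(), 0.0)
    gv = eval_piecewise_quadratic(s.v, p.g_branch(), p.r_g)
    drive = p.I0 + p.k * I_stim
    variant = p.variant
    if variant is Variant.TWO_VAR:
        dv = p.phi / p.tau * (fv - s.n + drive)
        dn = (gv - s.n) / p.tau
        return (dv, dn)
    hv = eval_piecewise_quadratic(s.v, p.h_branch(), p.r_h)
    dq = p.eps_q / p.tau * (hv - s.q)
    if variant is Variant.THREE_VAR:
        dv = p.phi / p.tau * (fv - s.n - s.q + drive)
        dn = (gv - s.n) / p.tau
        return (dv, dn, dq)
    du = p.eps_u / p.tau * (s.v + p.v0 - p.alpha_u * s.u)
    if variant is Variant.FOUR_VAR:
        dv = p.phi / p.tau * (fv - s.n - s.q + s.u + drive)
        dn = (gv - s.n) / p.tau
        return (dv, dn, dq, du)
    # FOUR_VAR_EXT: u gates the recovery time constant instead of feeding dv
    dv = p.phi / p.tau * (fv - s.n - s.q + drive)
    dn = eval_eta(s.u, p) / p.tau * (gv - s.n)
    return (dv, dn, dq, du)


# ---------------------------------------------------------------------------
# PLS-framework formulation (polynomial / piecewise-linear / step core functions)

def pls_core(kind: Literal["P1", "L1", "S1"], *args: float) -> float:
    """Core functions of the piecewise-polynomial model framework.

    P1(x, x0) = x0 - x;  L1(x, x0, x1, x2) = x1 + x2 (x - x0);
    S1(x, x0, x1, x2) = x1 if x < x0 else x2.
    """
    if kind == "P1":
        x, x0 = args
        return x0 - x
    if kind == "L1":
        x, x0, x1, x2 = args
        return x1 + x2 * (x - x0)
    if kind == "S1":
        x, x0, x1, x2 = args
        return x1 if x < x0 else x2
    raise ValueError(f"unknown core function {kind!r}")


def _pls_quad(v: float, r: float, branch) -> float:
    """Branch-selected quadratic assembled purely from P1 and S1."""
    a_n, b_n, c_n, a_p, b_p, c_p = branch
    return pls_core(
        "S1", v, r,
        a_n * pls_core("P1", v, b_n) ** 2 + c_n,
        a_p * pls_core("P1", v, b_p) ** 2 + c_p,
    )


def pls_derivatives(s: NeuronState, I_stim: float, p: PQNParams) -> tuple[float, ...]:
    """RHS assembled from the P1/L1/S1 core functions.

    The framework form omits the bias I0 and writes the v equation with
    time scale tau/phi (and the slow equations with tau/eps_q and
    tau/(eps_u*alpha_u)); it must agree with :func:`derivatives` exactly
    when I0 = 0.  Kept as an independent formulation for cross-checking.
    """
    _check_state(s, p)
    fv = _pls_quad(s.v, 0.0, p.f_branch())
    gv = _pls_quad(s.v, p.r_g, p.g_branch())
    variant = p.variant
    if variant is Variant.TWO_VAR:
        dv = (fv - s.n + p.k * I_stim) / (p.tau / p.phi)
        dn = (gv - s.n) / p.tau
        return (dv, dn)
    hv = _pls_quad(s.v, p.r_h, p.h_branch())
    dq = (hv - s.q) / (p.tau / p.eps_q)
    if variant is Variant.THREE_VAR:
        dv = (fv - s.n - s.q + p.k * I_stim) / (p.tau / p.phi)
        dn = (gv - s.n) / p.tau
        return (dv, dn, dq)
    du = (pls_core("L1", s.v, 0.0, p.v0 / p.alpha_u, 1.0 / p.alpha_u) - s.u) / (
        p.tau / (p.eps_u * p.alpha_u)
    )
    if variant is Variant.FOUR_VAR:
        dv = (fv - s.n - s.q + s.u + p.k * I_stim) / (p.tau / p.phi)
        dn = (gv - s.n) / p.tau
        return (dv, dn, dq, du)
    dv = (fv - s.n - s.q + p.k * I_stim) / (p.tau / p.phi)
    dn = (gv - s.n) / pls_core("S1", s.u, p.r_u, p.tau / p.eta0, p.tau / p.eta1)
    return (dv, dn, dq, du)


# ---------------------------------------------------------------------------
# fixed-point engine

def _plan(c: float, frac_bits: int) -> ShiftAddPlan:
    return decompose_coefficient(c, frac_bits, rounding="nearest")


class FixedEngine:
    """Bit-exact datapath for one mode: pre-planned shift-add constants.

    dt and the time-scale factors are folded into per-term constants — for
    each state equation and each nullcline branch, a v**2 coefficient, a v
    coefficient, and an additive constant — because a bare dt (1e-4) is far
    below the resolution of the 18/8 state format.  Each constant is
    realized as a shifter/adder plan applied to the raw state word; v**2
    comes from the one true multiplier (truncating).  Branches are chosen
    by comparators on the raw words, and the recovery-gate switch of the
    extended variant reads the *current* u, as the pipeline does.
    """

    def __init__(
        self,
        p: PQNParams,
        fmt: QFormat,
        dt: float,
        coeff_frac_bits: int | None = None,
        overflow: fx.OverflowPolicy = "wrap",
    ):
        if not p.is_complete:
            raise ValueError("parameters must be completed before building an engine")
        self.p = p
        self.fmt = fmt
        self.dt = dt
        self.overflow = overflow
        # constants get extra fractional depth: shift-add acts on the raw
        # word, so coefficient bits below the state resolution still matter
        self.coeff_frac_bits = (
            fmt.fraction_bits + 8 if coeff_frac_bits is None else coeff_frac_bits
        )
        fb = self.coeff_frac_bits
        variant = p.variant
        sv = dt * p.phi / p.tau  # v-equation scale
        sn = dt / p.tau  # n-equation scale (TWO/THREE/FOUR_VAR)

        def quad_plans(scale: float, branch):
            a_n, b_n, c_n, a_p, b_p, c_p = branch
            out = []
            for a, b, c in ((a_n, b_n, c_n), (a_p, b_p, c_p)):
                out.append(
                    (
                        _plan(scale * a, fb),
                        _plan(-2.0 * scale * a * b, fb),
                        self._const(scale * (a * b * b + c)),
                    )
                )
            return tuple(out)

        # v equation: quadratic f plus linear couplings
        self.v_quad = quad_plans(sv, p.f_branch())
        self.v_bias = self._const(sv * p.I0)
        self.v_n = _plan(sv, fb)  # applied to n, subtracted
        self.v_I = _plan(sv * p.k, fb)  # applied to I_stim
        self.v_q = _plan(sv, fb) if variant is not Variant.TWO_VAR else None
        self.v_u = _plan(sv, fb) if variant is Variant.FOUR_VAR else None

        # n equation; the extended variant needs one coefficient set per
        # eta value, selected by the comparator on u
        if variant is Variant.FOUR_VAR_EXT:
            self.n_quad_eta = (
                quad_plans(dt * p.eta0 / p.tau, p.g_branch()),
                quad_plans(dt * p.eta1 / p.tau, p.g_branch()),
            )
            self.n_n_eta = (_plan(dt * p.eta0 / p.tau, fb), _plan(dt * p.eta1 / p.tau, fb))
            self.r_u_raw = fx.quantize(p.r_u, fmt).raw
        else:
            self.n_quad = quad_plans(sn, p.g_branch())
            self.n_n = _plan(sn, fb)
        self.r_g_raw = fx.quantize(p.r_g, fmt).raw

        # q equation
        if variant is not Variant.TWO_VAR:
            sq = dt * p.eps_q / p.tau
            self.q_quad = quad_plans(sq, p.h_branch())
            self.q_q = _plan(sq, fb)
            self.r_h_raw = fx.quantize(p.r_h, fmt).raw

        # u equation
        if variant in (Variant.FOUR_VAR, Variant.FOUR_VAR_EXT):
            su = dt * p.eps_u / p.tau
            self.u_v = _plan(su, fb)
            self.u_c = self._const(su * p.v0)
            self.u_u = _plan(su * p.alpha_u, fb)  # subtracted

        self.overflows = fx.OverflowCounter()

    # -- helpers ----------------------------------------------------------
    def _const(self, value: float) -> int:
        """An additive constant, pre-quantized once to the state format."""
        return fx.quantize(value, self.fmt, rounding="nearest", overflow="error").raw

    def _shift_add_raw(self, raw: int, plan: ShiftAddPlan) -> int:
        acc = 0
        for pos in plan.shifts:
            acc += (raw >> pos) if pos >= 0 else (raw << (-pos))
        return plan.sign * acc

    def _clip(self, raw: int, step: int) -> int:
        if self.fmt.raw_min <= raw <= self.fmt.raw_max:
            return raw
        self.overflows.note(step)
        if self.overflow == "error":
            raise fx.OverflowError_(f"fixed-point overflow at step {step}")
        if self.overflow == "saturate":
            return self.fmt.raw_max if raw > self.fmt.raw_max else self.fmt.raw_min
        span = 1 << self.fmt.total_bits
        return (raw - self.fmt.raw_min) % span + self.fmt.raw_min

    def quantize_state(self, s: NeuronState) -> tuple[int, ...]:
        qs = [fx.quantize(s.v, self.fmt).raw, fx.quantize(s.n, self.fmt).raw]
        if s.q is not None:
            qs.append(fx.quantize(s.q, self.fmt).raw)
        if s.u is not None:
            qs.append(fx.quantize(s.u, self.fmt).raw)
        return tuple(qs)

    def state_from_raw(self, raws: tuple[int, ...]) -> NeuronState:
        res = self.fmt.resolution
        vals = [r * res for r in raws]
        variant = self.p.variant
        if variant is Variant.TWO_VAR:
            return NeuronState(vals[0], vals[1])
        if variant is Variant.THREE_VAR:
            return NeuronState(vals[0], vals[1], vals[2])
        return NeuronState(vals[0], vals[1], vals[2], vals[3])

    # -- one synchronous update -------------------------------------------
    def step_raw(self, raws: tuple[int, ...], I_stim: float, step: int = 0) -> tuple[int, ...]:
        p, fmt = self.p, self.fmt
        variant = p.variant
        v_raw, n_raw = raws[0], raws[1]
        q_raw = raws[2] if len(raws) > 2 else None
        u_raw = raws[3] if len(raws) > 3 else None
        I_raw = fx.quantize(I_stim, fmt, rounding="nearest", overflow="saturate").raw

        # stage 1: the one true multiply
        vv_raw = (v_raw * v_raw) >> fmt.fraction_bits

        # stage 2/3: shift-add constant multiplications, branch-muxed
        fi = 0 if v_raw < 0 else 1
        gi = 0 if v_raw < self.r_g_raw else 1

        a, b, c = self.v_quad[fi]
        dv = self._shift_add_raw(vv_raw, a) + self._shift_add_raw(v_raw, b) + c
        dv += self.v_bias
        dv -= self._shift_add_raw(n_raw, self.v_n)
        if self.v_q is not None:
            dv -= self._shift_add_raw(q_raw, self.v_q)
        if self.v_u is not None:
            dv += self._shift_add_raw(u_raw, self.v_u)
        dv += self._shift_add_raw(I_raw, self.v_I)
        v_next = self._clip(v_raw + dv, step)

        if variant is Variant.FOUR_VAR_EXT:
            ei = 0 if u_raw < self.r_u_raw else 1
            a, b, c = self.n_quad_eta[ei][gi]
            dn = self._shift_add_raw(vv_raw, a) + self._shift_add_raw(v_raw, b) + c
            dn -= self._shift_add_raw(n_raw, self.n_n_eta[ei])
        else:
            a, b, c = self.n_quad[gi]
            dn = self._shift_add_raw(vv_raw, a) + self._shift_add_raw(v_raw, b) + c
            dn -= self._shift_add_raw(n_raw, self.n_n)
        n_next = self._clip(n_raw + dn, step)

        out = [v_next, n_next]
        if variant is not Variant.TWO_VAR:
            hi = 0 if v_raw < self.r_h_raw else 1
            a, b, c = self.q_quad[hi]
            dq = self._shift_add_raw(vv_raw, a) + self._shift_add_raw(v_raw, b) + c
            dq -= self._shift_add_raw(q_raw, self.q_q)
            out.append(self._clip(q_raw + dq, step))
        if variant in (Variant.FOUR_VAR, Variant.FOUR_VAR_EXT):
            du = self._shift_add_raw(v_raw, self.u_v) + self.u_c
            du -= self._shift_add_raw(u_raw, self.u_u)
            out.append(self._clip(u_raw + du, step))
        return tuple(out)


# ---------------------------------------------------------------------------
# stepping and simulation

def euler_step(
    s: NeuronState,
    I_stim: float,
    p: PQNParams,
    dt: float,
    backend: Backend = "float",
    qfmt: QFormat | None = None,
    engine: FixedEngine | None = None,
) -> NeuronState:
    """One synchronous Euler update s' = s + dt * derivatives(s, I, p)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if backend == "float":
        der = derivatives(s, I_stim, p)
        vals = [x + dt * d for x, d in zip(s.as_tuple(), der)]
        if p.variant is Variant.TWO_VAR:
            return NeuronState(vals[0], vals[1])
        if p.variant is Variant.THREE_VAR:
            return NeuronState(vals[0], vals[1], vals[2])
        return NeuronState(vals[0], vals[1], vals[2], vals[3])
    if backend == "fixed":
        if engine is None:
            if qfmt is None:
                raise ValueError("fixed backend requires qfmt or a prebuilt engine")
            engine = FixedEngine(p, qfmt, dt)
        if dt == 0:
            return engine.state_from_raw(engine.quantize_state(s))
        raws = engine.quantize_state(s)
        return engine.state_from_raw(engine.step_raw(raws, I_stim))
    raise ValueError(f"unknown backend {backend!r}")


def default_initial_state(p: PQNParams, I_stim: float = 0.0) -> tuple[NeuronState, str]:
    """Resting equilibrium at the given constant stimulus, else zeros."""
    eq = find_equilibrium(p, I_stim)
    if eq is not None:
        return eq, "equilibrium"
    variant = p.variant
    if variant is Variant.TWO_VAR:
        return NeuronState(0.0, 0.0), "zeros"
    if variant is Variant.THREE_VAR:
        return NeuronState(0.0, 0.0, 0.0), "zeros"
    return NeuronState(0.0, 0.0, 0.0, 0.0), "zeros"


def simulate(
    p: PQNParams,
    stim: StimulusProgram | None = None,
    t_max: float = 1.0,
    init: NeuronState | None = None,
    backend: Backend = "float",
    qfmt: QFormat | None = None,
    dt: float | None = None,
    overflow: fx.OverflowPolicy = "wrap",
) -> Trace:
    """Integrate the model on the uniform grid t_j = j * dt up to t_max.

    Deterministic: identical inputs produce identical traces (the fixed
    backend is bit-exact by construction).  The initial state defaults to
    the resting equilibrium at I_stim = 0 when one exists, else zeros; the
    choice is recorded in ``trace.meta['init']``.
    """
    if not p.is_complete:
        raise ValueError("parameters must be completed before simulation")
    dt = p.dt if dt is None else dt
    if dt is None or dt <= 0:
        raise ValueError("a positive dt is required")
    if t_max < dt:
        raise ValueError(f"t_max {t_max} shorter than one step dt {dt}")
    stim = stim if stim is not None else StimulusProgram()
    n_steps = int(round(t_max / dt))
    times = np.arange(n_steps + 1) * dt

    init_label = "given"
    if init is None:
        init, init_label = default_initial_state(p)
    _check_state(init, p)

    stim_vals = stim.sample(times)
    dim = len(init.as_tuple())
    data = np.empty((n_steps + 1, dim))

    meta = {
        "mode": p.mode.value,
        "backend": backend,
        "dt": dt,
        "init": init_label,
        "qformat": None,
        "overflow_count": 0,
    }

    if backend == "float":
        state = list(init.as_tuple())
        data[0] = state
        p_ = p
        for j in range(n_steps):
            s = NeuronState(*state)
            der = derivatives(s, float(stim_vals[j]), p_)
            for i in range(dim):
                state[i] += dt * der[i]
            if not (abs(state[0]) < DIVERGENCE_LIMIT) or state[0] != state[0]:
                raise SimulationError(
                    f"divergence at step {j + 1} (t={times[j + 1]:.6g}): v={state[0]!r}",
                    step=j + 1,
                )
            data[j + 1] = state
    elif backend == "fixed":
        if qfmt is None:
            from .params import default_qformat

            qfmt = default_qformat(p.mode)
        engine = FixedEngine(p, qfmt, dt, overflow=overflow)
        raws = engine.quantize_state(init)
        res = qfmt.resolution
        data[0] = [r * res for r in raws]
        for j in range(n_steps):
            raws = engine.step_raw(raws, float(stim_vals[j]), step=j)
            data[j + 1] = [r * res for r in raws]
        meta["qformat"] = str(qfmt)
        meta["overflow_count"] = engine.overflows.count
    else:
        raise ValueError(f"unknown backend {backend!r}")

    q = data[:, 2] if dim >= 3 else None
    u = data[:, 3] if dim >= 4 else None
    return Trace(
        times=times,
        v=data[:, 0],
        n=data[:, 1],
        q=q,
        u=u,
        stimulus=stim_vals,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# equilibria

def _rest_residual(v: float, p: PQNParams, I_stim: float) -> float:
    """dv/dt at the point of the slow manifold where dn=dq=du=0."""
    fv = eval_piecewise_quadratic(v, p.f_branch(), 0.0)
    gv = eval_piecewise_quadratic(v, p.g_branch(), p.r_g)
    drive = p.I0 + p.k * I_stim
    variant = p.variant
    if variant is Variant.TWO_VAR:
        return fv - gv + drive
    hv = eval_piecewise_quadratic(v, p.h_branch(), p.r_h)
    if variant is Variant.THREE_VAR:
        return fv - gv - hv + drive
    if variant is Variant.FOUR_VAR:
        u = (v + p.v0) / p.alpha_u
        return fv - gv - hv + u + drive
    return fv - gv - hv + drive  # FOUR_VAR_EXT: u does not feed dv


def find_equilibrium(
    p: PQNParams,
    I_stim: float = 0.0,
    bracket: tuple[float, float] = (-10.0, 10.0),
    n_scan: int = 1000,
) -> NeuronState | None:
    """Leftmost rest point in the bracket, or None if no sign change is found.

    Scans the residual f(v) - g(v) [- h(v)] [+ u(v)] + I0 + k*I on a
    uniform grid, then refines the first sign change with Brent's method;
    the remaining state variables follow from their nullclines.
    """
    if not p.is_complete:
        raise ValueError("parameters must be completed first")
    lo, hi = bracket
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"invalid bracket {bracket}")
    vs = np.linspace(lo, hi, n_scan)
    res = np.array([_rest_residual(v, p, I_stim) for v in vs])
    v_star: float | None = None
    for i in range(len(vs) - 1):
        r0, r1 = res[i], res[i + 1]
        if r0 == 0.0:
            v_star = float(vs[i])
            break
        if r0 * r1 < 0:
            v_star = float(
                brentq(_rest_residual, vs[i], vs[i + 1], args=(p, I_stim), xtol=1e-14)
            )
            break
    else:
        if res[-1] == 0.0:
            v_star = float(vs[-1])
    if v_star is None:
        return None
    n_star = eval_piecewise_quadratic(v_star, p.g_branch(), p.r_g)
    variant = p.variant
    if variant is Variant.TWO_VAR:
        return NeuronState(v_star, n_star)
    q_star = eval_piecewise_quadratic(v_star, p.h_branch(), p.r_h)
    if variant is Variant.THREE_VAR:
        return NeuronState(v_star, n_star, q_star)
    u_star = (v_star + p.v0) / p.alpha_u
    return NeuronState(v_star, n_star, q_star, u_star)
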