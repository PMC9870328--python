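"""Hardware-planning arithmetic for the shared-engine FPGA implementation.

The neuron-update engine multiplies state variables by fixed constants
using shifters and adders: each set bit in the binary representation of a
coefficient costs one shifter/adder pair, so the resource footprint of a
parameter set is read directly off its bit patterns.  The one true
multiplier (a DSP slice, 25x18-bit on the target part) computes v**2;
wider state words are tiled across several DSPs.  A single engine serves
many neurons by cycling their state through a FIFO, which fixes the
real-time neuron capacity: at clock rate C and integration step dt there
are round(C*dt) cycles per step, minus the engine pipeline depth and the
FIFO read/write latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal

__all__ = [
    "ShiftAddPlan",
    "CycleBudget",
    "decompose_coefficient",
    "dsp_tiles",
    "cycle_budget",
]


@dataclass(frozen=True)
class ShiftAddPlan:
    """Shifter/adder realization of multiplication by a constant.

    ``shifts`` holds the bit positions p of the quantized magnitude
    (position p contributes 2**-p; p <= 0 are integer-part bits), so the
    plan reconstructs sign * sum(2**-p) exactly.  ``ones_count`` is the
    popcount of the magnitude, the proxy for adder/shifter cost.
    """

    sign: int
    shifts: tuple[int, ...]
    fraction_bits: int

    @property
    def reconstructed_value(self) -> Fraction:
        total = sum(Fraction(1, 2**p) if p > 0 else Fraction(2 ** (-p)) for p in self.shifts)
        return self.sign * total

    @property
    def ones_count(self) -> int:
        return len(self.shifts)


def decompose_coefficient(
    c: float,
    fraction_bits: int,
    rounding: Literal["nearest", "truncate"] = "nearest",
) -> ShiftAddPlan:
    """Quantize |c| to ``fraction_bits`` and list its set-bit positions.

    Plain binary decomposition (not canonical signed digit): the hardware
    cost model counts ones in the ordinary binary representation, so that
    is the representation planned here.  c = 0 yields an empty plan.

    >>> decompose_coefficient(0.037109375, 10).shifts
    (5, 8, 9)
    """
    if not math.isfinite(c):
        raise ValueError(f"coefficient must be finite, got {c}")
    sign = -1 if c < 0 else 1
    scaled = abs(c) * (1 << fraction_bits)
    if rounding == "nearest":
        mag = round(scaled)
    elif rounding == "truncate":
        mag = math.floor(scaled)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    shifts = []
    bit = 0
    while mag >> bit:
        if (mag >> bit) & 1:
            # raw bit `bit` has weight 2**(bit - fraction_bits)
            shifts.append(fraction_bits - bit)
        bit += 1
    shifts.sort()
    return ShiftAddPlan(sign=sign, shifts=tuple(shifts), fraction_bits=fraction_bits)


def dsp_tiles(operand_bits: int, dsp_a: int = 25, dsp_b: int = 18) -> int:
    """DSP slices needed to square an ``operand_bits``-wide word.

    One slice multiplies dsp_a x dsp_b bits (25x18 on the Artix-7); a
    w x w product is tiled ceil(w/25) * ceil(w/18) ways, hence 1 slice for
    18-bit state words and 4 for the 28-bit Class II format.
    """
    if operand_bits <= 0 or dsp_a <= 0 or dsp_b <= 0:
        raise ValueError("bit widths must be positive")
    return math.ceil(operand_bits / dsp_a) * math.ceil(operand_bits / dsp_b)


@dataclass(frozen=True)
class CycleBudget:
    """Real-time cycle accounting for one shared neuron-update engine."""

    clock_hz: float
    dt: float
    cycles_per_step: int
    engine_latency_cycles: int
    fifo_cycles: int

    @property
    def capacity(self) -> int:
        """Neurons one engine updates per step in real time."""
        return self.cycles_per_step - self.engine_latency_cycles - self.fifo_cycles


def cycle_budget(
    clock_hz: float,
    dt: float,
    engine_latency_cycles: int = 4,
    fifo_cycles: int = 3,
) -> CycleBudget:
    """Cycles available per integration step and resulting neuron capacity.

    Defaults match the reference pipeline: the update engine takes 4 cycles
    and FIFO reads/writes take 3.  At 100 MHz with dt = 0.1 ms this gives
    10,000 cycles per step and a capacity of 9,993 neurons.
    """
    if clock_hz <= 0 or dt <= 0:
        raise ValueError("clock_hz and dt must be positive")
    if engine_latency_cycles < 0 or fifo_cycles < 0:
        raise ValueError("latencies must be non-negative")
    cycles = round(clock_hz * dt)
    budget = CycleBudget(
        clock_hz=clock_hz,
        dt=dt,
        cycles_per_step=cycles,
        engine_latency_cycles=engine_latency_cycles,
        fifo_cycles=fifo_cycles,
    )
    if budget.capacity < 0:
        raise ValueError(
            f"cycle budget {cycles} cannot cover latency "
            f"{engine_latency_cycles}+{fifo_cycles}"
        )
    return budget
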