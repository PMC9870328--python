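"""Bit-exact emulation of FPGA fixed-point arithmetic.

State variables on the target hardware live in a two's-complement Q-format
(total bits / integer bits, the integer part including the sign bit): 18/8
for most neuron classes and 28/8 for Class II, whose phase-resetting curve
needs the extra fractional resolution.  This module reproduces that
arithmetic on arbitrary-precision Python integers so that a simulation run
here produces the same raw bit patterns as the circuit: quantization with
truncation or round-half-to-even, a truncating multiplier, and the
shifter/adder network used for constant-coefficient multiplication.

Truncation is everywhere toward minus infinity (arithmetic right shift),
the natural behavior of a two's-complement shifter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "QFormat",
    "FixedValue",
    "OverflowError_",
    "quantize",
    "fx_mul",
    "fx_add",
    "shift_add_mul",
    "parse_qformat",
]

OverflowPolicy = Literal["wrap", "saturate", "error"]
Rounding = Literal["truncate", "nearest"]


class OverflowError_(ArithmeticError):
    """Raised when a result leaves the representable range under policy 'error'."""


@dataclass(frozen=True)
class QFormat:
    """Fixed-point format: ``total_bits`` wide, ``integer_bits`` integer part.

    ``integer_bits`` includes the sign bit, so q18.8 carries 10 fraction
    bits (resolution 2**-10) and spans [-128, 128 - 2**-10].
    """

    total_bits: int
    integer_bits: int

    def __post_init__(self) -> None:
        if not (1 <= self.integer_bits <= self.total_bits):
            raise ValueError(
                f"integer_bits must satisfy 1 <= {self.integer_bits} <= {self.total_bits}"
            )

    @property
    def fraction_bits(self) -> int:
        return self.total_bits - self.integer_bits

    @property
    def resolution(self) -> float:
        return 2.0 ** -self.fraction_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def min_value(self) -> float:
        return self.raw_min * self.resolution

    @property
    def max_value(self) -> float:
        return self.raw_max * self.resolution

    def __str__(self) -> str:
        return f"q{self.total_bits}.{self.integer_bits}"


#: formats the hardware actually uses
Q18_8 = QFormat(18, 8)
Q28_8 = QFormat(28, 8)

_QFMT_RE = re.compile(r"^[qQ](\d+)\.(\d+)$")


def parse_qformat(spec: str) -> QFormat:
    """Parse a format spec string such as ``'q18.8'`` (total.integer)."""
    m = _QFMT_RE.match(spec.strip())
    if m is None:
        raise ValueError(f"bad Q-format spec {spec!r}; expected e.g. 'q18.8'")
    return QFormat(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class FixedValue:
    """A number stored as a raw two's-complement integer in a Q-format."""

    raw: int
    fmt: QFormat

    def __post_init__(self) -> None:
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise OverflowError_(
                f"raw {self.raw} outside {self.fmt} range "
                f"[{self.fmt.raw_min}, {self.fmt.raw_max}]"
            )

    def to_float(self) -> float:
        return self.raw * self.fmt.resolution

    # convenience operators -------------------------------------------------
    def __float__(self) -> float:
        return self.to_float()


def _handle_overflow(raw: int, fmt: QFormat, policy: OverflowPolicy) -> int:
    if fmt.raw_min <= raw <= fmt.raw_max:
        return raw
    if policy == "error":
        raise OverflowError_(f"raw {raw} overflows {fmt}")
    if policy == "saturate":
        return fmt.raw_max if raw > fmt.raw_max else fmt.raw_min
    # wrap: two's complement
    span = 1 << fmt.total_bits
    wrapped = (raw - fmt.raw_min) % span + fmt.raw_min
    return wrapped


def quantize(
    x: float,
    fmt: QFormat,
    rounding: Rounding = "nearest",
    overflow: OverflowPolicy = "error",
) -> FixedValue:
    """Convert a real number to the nearest/truncated representable value.

    ``truncate`` floors toward minus infinity (raw = floor(x * 2**f));
    ``nearest`` rounds half to even on the raw grid.
    """
    import math

    if not math.isfinite(x):
        raise ValueError(f"cannot quantize non-finite value {x}")
    scaled = x * (1 << fmt.fraction_bits)
    if rounding == "truncate":
        raw = math.floor(scaled)
    elif rounding == "nearest":
        # round-half-to-even; scaled may exceed float integer precision only
        # for absurd formats, which the range check catches anyway
        raw = round(scaled)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown rounding {rounding!r}")
    raw = _handle_overflow(raw, fmt, overflow)
    return FixedValue(raw, fmt)


def fx_add(
    a: FixedValue, b: FixedValue, overflow: OverflowPolicy = "wrap"
) -> FixedValue:
    if a.fmt != b.fmt:
        raise ValueError(f"format mismatch: {a.fmt} vs {b.fmt}")
    return FixedValue(_handle_overflow(a.raw + b.raw, a.fmt, overflow), a.fmt)


def fx_mul(
    a: FixedValue, b: FixedValue, overflow: OverflowPolicy = "wrap"
) -> FixedValue:
    """Truncating multiply: full integer product, arithmetic shift right.

    The full-precision product carries 2f fraction bits; shifting right by f
    with sign extension truncates toward minus infinity, exactly what the
    DSP-plus-shifter datapath produces.
    """
    if a.fmt != b.fmt:
        raise ValueError(f"format mismatch: {a.fmt} vs {b.fmt}")
    full = a.raw * b.raw
    raw = full >> a.fmt.fraction_bits  # Python >> is arithmetic (floor)
    return FixedValue(_handle_overflow(raw, a.fmt, overflow), a.fmt)


def shift_add_mul(
    x: FixedValue,
    shifts,
    sign: int = 1,
    overflow: OverflowPolicy = "wrap",
) -> FixedValue:
    """Multiply by a constant through its shifter/adder network.

    ``shifts`` lists the set-bit positions p of the constant (value
    sign * sum 2**-p; p <= 0 addresses integer-part bits, realized as left
    shifts), or is a plan object carrying ``shifts`` and ``sign`` attributes
    (see :class:`pqnsim.hardware.ShiftAddPlan`).  Each right shift truncates
    its own low bits independently — the terms are added only afterwards, as
    in the hardware — so the result can differ from ``fx_mul`` by up to one
    raw unit per term.
    """
    if hasattr(shifts, "shifts"):  # a ShiftAddPlan
        sign = shifts.sign
        shifts = shifts.shifts
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    acc = 0
    for p in shifts:
        if p >= 0:
            acc += x.raw >> p
        else:
            acc += x.raw << (-p)
    raw = _handle_overflow(sign * acc, x.fmt, overflow)
    return FixedValue(raw, x.fmt)


@dataclass
class OverflowCounter:
    """Counts wraps so that silent two's-complement divergence is visible."""

    count: int = 0
    first_step: int | None = None

    def note(self, step: int | None = None) -> None:
        self.count += 1
        if self.first_step is None:
            self.first_step = step
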