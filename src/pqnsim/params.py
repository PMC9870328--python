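"""Parameter data model for the four PQN variants.

A PQN neuron is a two- to four-variable system whose nullclines are built
from two quadratic branches joined at a junction.  Only the negative-side
branch and the positive-side curvature are free parameters: the remaining
positive-branch vertex and offset are *completed* so that each nullcline is
continuous with a continuous first derivative at its junction —

    b_fp = a_fn * b_fn / a_fp
    c_fp = a_fn * b_fn**2 + c_fn - a_fp * b_fp**2

for the fast (f) nullcline joined at v = 0, and analogously for the
recovery (g) nullcline at v = r_g and the slow (h) nullcline at v = r_h.
Completion is a structural invariant: derived values are always recomputed
on load and never trusted from a file.

Eight neuronal modes are bundled, each tied to a variant:

========  =============  =====================================
mode      variant        behavior
========  =============  =====================================
CLASS2    TWO_VAR        Hodgkin Class II: graded response, Type II PRC
RS_EXC    THREE_VAR      regular spiking, spike-frequency adaptation
RS_INH    THREE_VAR      regular spiking, stronger adaptation
FS        THREE_VAR      fast spiking, weak transient adaptation
EB        THREE_VAR      elliptic bursting
PB        FOUR_VAR       parabolic bursting (slow q-u oscillation)
LTS       FOUR_VAR_EXT   low-threshold spiking, rebound bursting
IB        FOUR_VAR_EXT   intrinsic bursting at stimulus onset
========  =============  =====================================

The bundled parameter files are qualitative sets designed with this
package to exhibit each mode's class behavior; they are synthetic, not
fitted against ionic-conductance target models.  Integration uses a 1 ms
Euler step for PB and 0.1 ms for every other mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any

from .fixedpoint import QFormat

__all__ = [
    "Variant",
    "ModeID",
    "PQNParams",
    "Diagnostic",
    "ParameterError",
    "complete_parameters",
    "validate_parameters",
    "load_mode_params",
    "save_params",
    "bundled_modes",
    "default_qformat",
]


class ParameterError(ValueError):
    """A parameter document is malformed, incomplete, or inconsistent."""


class Variant(str, Enum):
    TWO_VAR = "TWO_VAR"
    THREE_VAR = "THREE_VAR"
    FOUR_VAR = "FOUR_VAR"
    FOUR_VAR_EXT = "FOUR_VAR_EXT"


class ModeID(str, Enum):
    CLASS2 = "CLASS2"
    RS_EXC = "RS_EXC"
    RS_INH = "RS_INH"
    FS = "FS"
    LTS = "LTS"
    IB = "IB"
    EB = "EB"
    PB = "PB"
    TOY2VAR = "TOY2VAR"
    TOY3VAR = "TOY3VAR"

    @property
    def variant(self) -> Variant:
        return _MODE_VARIANT[self]


_MODE_VARIANT = {
    ModeID.CLASS2: Variant.TWO_VAR,
    ModeID.RS_EXC: Variant.THREE_VAR,
    ModeID.RS_INH: Variant.THREE_VAR,
    ModeID.FS: Variant.THREE_VAR,
    ModeID.EB: Variant.THREE_VAR,
    ModeID.PB: Variant.FOUR_VAR,
    ModeID.LTS: Variant.FOUR_VAR_EXT,
    ModeID.IB: Variant.FOUR_VAR_EXT,
    ModeID.TOY2VAR: Variant.TWO_VAR,
    ModeID.TOY3VAR: Variant.THREE_VAR,
}

# free (non-derived) fields required by each variant, beyond the common ones
_COMMON_FIELDS = (
    "phi", "tau", "I0", "k",
    "a_fn", "b_fn", "c_fn", "a_fp",
    "a_gn", "b_gn", "c_gn", "a_gp", "r_g",
)
_H_FIELDS = ("eps_q", "a_hn", "b_hn", "c_hn", "a_hp", "r_h")
_U_FIELDS = ("eps_u", "v0", "alpha_u")
_ETA_FIELDS = ("eta0", "eta1", "r_u")

_VARIANT_FIELDS: dict[Variant, tuple[str, ...]] = {
    Variant.TWO_VAR: _COMMON_FIELDS,
    Variant.THREE_VAR: _COMMON_FIELDS + _H_FIELDS,
    Variant.FOUR_VAR: _COMMON_FIELDS + _H_FIELDS + _U_FIELDS,
    Variant.FOUR_VAR_EXT: _COMMON_FIELDS + _H_FIELDS + _U_FIELDS + _ETA_FIELDS,
}

_DERIVED_FIELDS: dict[Variant, tuple[str, ...]] = {
    Variant.TWO_VAR: ("b_fp", "c_fp", "b_gp", "c_gp"),
    Variant.THREE_VAR: ("b_fp", "c_fp", "b_gp", "c_gp", "b_hp", "c_hp"),
    Variant.FOUR_VAR: ("b_fp", "c_fp", "b_gp", "c_gp", "b_hp", "c_hp"),
    Variant.FOUR_VAR_EXT: ("b_fp", "c_fp", "b_gp", "c_gp", "b_hp", "c_hp"),
}

# curvatures that must be nonzero for the variant
_NONZERO = {
    Variant.TWO_VAR: ("a_fn", "a_fp", "a_gn", "a_gp"),
    Variant.THREE_VAR: ("a_fn", "a_fp", "a_gn", "a_gp", "a_hn", "a_hp"),
    Variant.FOUR_VAR: ("a_fn", "a_fp", "a_gn", "a_gp", "a_hn", "a_hp"),
    Variant.FOUR_VAR_EXT: ("a_fn", "a_fp", "a_gn", "a_gp", "a_hn", "a_hp"),
}


@dataclass(frozen=True)
class PQNParams:
    """All constants of one PQN neuron.

    Fields irrelevant to the mode's variant stay ``None``; derived
    positive-branch coefficients are ``None`` until completion.  ``dt`` is
    the Euler step in seconds, stored with the parameters but overridable
    at simulation time.
    """

    mode: ModeID
    phi: float | None = None
    tau: float | None = None
    I0: float | None = None
    k: float | None = None
    # f nullcline, junction at v = 0
    a_fn: float | None = None
    b_fn: float | None = None
    c_fn: float | None = None
    a_fp: float | None = None
    # g nullcline, junction at v = r_g
    a_gn: float | None = None
    b_gn: float | None = None
    c_gn: float | None = None
    a_gp: float | None = None
    r_g: float | None = None
    # h nullcline (three variables and up), junction at v = r_h
    eps_q: float | None = None
    a_hn: float | None = None
    b_hn: float | None = None
    c_hn: float | None = None
    a_hp: float | None = None
    r_h: float | None = None
    # u nullcline (four variables and up)
    eps_u: float | None = None
    v0: float | None = None
    alpha_u: float | None = None
    # eta switch (extended four-variable only)
    eta0: float | None = None
    eta1: float | None = None
    r_u: float | None = None
    # integration step (seconds)
    dt: float | None = None
    # derived, set by complete_parameters
    b_fp: float | None = None
    c_fp: float | None = None
    b_gp: float | None = None
    c_gp: float | None = None
    b_hp: float | None = None
    c_hp: float | None = None

    @property
    def variant(self) -> Variant:
        return self.mode.variant

    @property
    def is_complete(self) -> bool:
        return all(getattr(self, f) is not None for f in _DERIVED_FIELDS[self.variant])

    def f_branch(self) -> tuple[float, float, float, float, float, float]:
        return (self.a_fn, self.b_fn, self.c_fn, self.a_fp, self.b_fp, self.c_fp)

    def g_branch(self) -> tuple[float, float, float, float, float, float]:
        return (self.a_gn, self.b_gn, self.c_gn, self.a_gp, self.b_gp, self.c_gp)

    def h_branch(self) -> tuple[float, float, float, float, float, float]:
        return (self.a_hn, self.b_hn, self.c_hn, self.a_hp, self.b_hp, self.c_hp)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: which field broke which rule."""

    field: str
    rule: str
    observed: Any = None

    def __str__(self) -> str:
        return f"{self.field}: {self.rule} (observed {self.observed!r})"


def default_dt(mode: ModeID) -> float:
    """Euler step in seconds: 1 ms for PB, 0.1 ms for every other mode."""
    return 1e-3 if mode is ModeID.PB else 1e-4


def default_qformat(mode: ModeID) -> QFormat:
    """Hardware word format: 28/8 for Class II, 18/8 otherwise."""
    return QFormat(28, 8) if mode is ModeID.CLASS2 else QFormat(18, 8)


def _complete_branch(a_n: float, b_n: float, c_n: float, a_p: float, r: float):
    """Positive-branch vertex/offset for value+slope continuity at v = r."""
    b_p = r - a_n * (r - b_n) / a_p
    c_p = a_n * (r - b_n) ** 2 + c_n - a_p * (r - b_p) ** 2
    return b_p, c_p


def complete_parameters(p: PQNParams) -> PQNParams:
    """Fill in the smoothness-determined positive-branch coefficients.

    Idempotent; the input object is not mutated.  Raises
    :class:`ParameterError` naming any missing free field or zero
    positive-branch curvature.
    """
    variant = p.variant
    missing = [f for f in _VARIANT_FIELDS[variant] if getattr(p, f) is None]
    if missing:
        raise ParameterError(
            f"mode {p.mode.value} ({variant.value}) missing required field(s): "
            + ", ".join(missing)
        )
    for f in _NONZERO[variant]:
        if getattr(p, f) == 0:
            raise ParameterError(f"curvature {f} must be nonzero")

    updates: dict[str, float] = {}
    updates["b_fp"], updates["c_fp"] = _complete_branch(
        p.a_fn, p.b_fn, p.c_fn, p.a_fp, 0.0
    )
    updates["b_gp"], updates["c_gp"] = _complete_branch(
        p.a_gn, p.b_gn, p.c_gn, p.a_gp, p.r_g
    )
    if variant is not Variant.TWO_VAR:
        updates["b_hp"], updates["c_hp"] = _complete_branch(
            p.a_hn, p.b_hn, p.c_hn, p.a_hp, p.r_h
        )
    if p.dt is None:
        updates["dt"] = default_dt(p.mode)
    return replace(p, **updates)


def validate_parameters(p: PQNParams) -> list[Diagnostic]:
    """Check the type invariants; returns diagnostics rather than raising."""
    out: list[Diagnostic] = []
    variant = p.variant
    for f in _VARIANT_FIELDS[variant]:
        if getattr(p, f) is None:
            out.append(Diagnostic(f, "required for variant " + variant.value))
    for f in _NONZERO[variant]:
        v = getattr(p, f)
        if v == 0:
            out.append(Diagnostic(f, "curvature must be nonzero", v))
    for f in ("phi", "tau"):
        v = getattr(p, f)
        if v is not None and v <= 0:
            out.append(Diagnostic(f, "time-scale constant must be positive", v))
    if variant in (Variant.THREE_VAR, Variant.FOUR_VAR, Variant.FOUR_VAR_EXT):
        if p.eps_q is not None and p.eps_q <= 0:
            out.append(Diagnostic("eps_q", "rate factor must be positive", p.eps_q))
    if variant in (Variant.FOUR_VAR, Variant.FOUR_VAR_EXT):
        if p.eps_u is not None and p.eps_u <= 0:
            out.append(Diagnostic("eps_u", "rate factor must be positive", p.eps_u))
        if p.alpha_u is not None and p.alpha_u == 0:
            out.append(Diagnostic("alpha_u", "must be nonzero", p.alpha_u))
    if p.dt is not None and p.dt <= 0:
        out.append(Diagnostic("dt", "integration step must be positive", p.dt))
    # fields irrelevant to the variant must be absent
    allowed = set(_VARIANT_FIELDS[variant]) | set(_DERIVED_FIELDS[variant]) | {"dt", "mode"}
    for fld in fields(p):
        if fld.name in allowed:
            continue
        if getattr(p, fld.name) is not None:
            out.append(
                Diagnostic(fld.name, "not a field of variant " + variant.value,
                           getattr(p, fld.name))
            )
    # derived coefficients, when present, must satisfy the completion identity
    if p.is_complete and not any(d.rule.startswith("required") for d in out):
        b_fp, c_fp = _complete_branch(p.a_fn, p.b_fn, p.c_fn, p.a_fp, 0.0)
        if abs(p.b_fp - b_fp) > 1e-9 or abs(p.c_fp - c_fp) > 1e-9:
            out.append(Diagnostic("b_fp/c_fp", "inconsistent with smoothness completion",
                                  (p.b_fp, p.c_fp)))
    return out


# ---------------------------------------------------------------------------
# JSON I/O

def params_to_dict(p: PQNParams, include_derived: bool = False) -> dict[str, Any]:
    doc: dict[str, Any] = {"mode": p.mode.value}
    keep = set(_VARIANT_FIELDS[p.variant]) | {"dt"}
    if include_derived:
        keep |= set(_DERIVED_FIELDS[p.variant])
    for fld in fields(p):
        if fld.name in keep and getattr(p, fld.name) is not None:
            doc[fld.name] = getattr(p, fld.name)
    return doc


def params_from_dict(doc: dict[str, Any]) -> PQNParams:
    if not isinstance(doc, dict):
        raise ParameterError(f"parameter document must be an object, got {type(doc).__name__}")
    if "mode" not in doc:
        raise ParameterError("parameter document missing 'mode'")
    try:
        mode = ModeID(doc["mode"])
    except ValueError:
        raise ParameterError(f"unknown mode {doc['mode']!r}") from None
    known = {f.name for f in fields(PQNParams)}
    kwargs: dict[str, Any] = {}
    for key, val in doc.items():
        if key == "mode" or key.startswith("_"):
            continue  # underscore keys are comments
        if key not in known:
            raise ParameterError(f"unknown parameter field {key!r}")
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ParameterError(f"field {key!r} must be numeric, got {val!r}")
        kwargs[key] = float(val)
    # derived coefficients are recomputed, never trusted from the file
    for d in ("b_fp", "c_fp", "b_gp", "c_gp", "b_hp", "c_hp"):
        kwargs.pop(d, None)
    return PQNParams(mode=mode, **kwargs)


def save_params(p: PQNParams, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(params_to_dict(p), indent=2, sort_keys=True) + "\n"
    )


def bundled_modes() -> list[str]:
    """Names of the parameter sets shipped with the package."""
    pkg = resources.files("pqnsim") / "modes"
    return sorted(f.name[:-5] for f in pkg.iterdir() if f.name.endswith(".json"))


def load_mode_params(source: str | Path) -> PQNParams:
    """Load, complete, and validate parameters.

    ``source`` is either a bundled mode name (case-insensitive, e.g. "PB"
    or "toy2var") or a path to a JSON parameter file.
    """
    text: str | None = None
    if isinstance(source, str) and not source.endswith(".json") and "/" not in source:
        candidate = resources.files("pqnsim") / "modes" / f"{source.lower()}.json"
        if candidate.is_file():
            text = candidate.read_text()
        else:
            raise ParameterError(
                f"unknown mode name {source!r}; bundled: {', '.join(bundled_modes())}"
            )
    if text is None:
        path = Path(source)
        if not path.exists():
            raise ParameterError(f"parameter file not found: {path}")
        text = path.read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParameterError(f"malformed parameter JSON: {e}") from e
    p = complete_parameters(params_from_dict(doc))
    diags = validate_parameters(p)
    if diags:
        raise ParameterError(
            "invalid parameters: " + "; ".join(str(d) for d in diags)
        )
    return p
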