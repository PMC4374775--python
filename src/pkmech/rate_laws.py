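"""Closed-form rate laws for a bisubstrate (bi-bi) kinase.

The central model is the rapid-equilibrium random-order rate equation

    v = Vmax * A * B / (Ka*Kb + Ka*B + Kb*A + A*B)

with A the phosphoryl donor (PEP3-) and B the metal-nucleotide complex
(ADP-Mg).  Alongside it: the Hill equation for cooperative saturation, the
linear dead-end inhibition equations (competitive / noncompetitive / mixed /
uncompetitive), simplified ordered and ping-pong laws used as classifier
oracles, and the conversion of a specific activity into kcat and
specificity constants.

Concentrations are mM throughout; velocities are specific activities in
umol.min-1.mg-1 unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np

__all__ = [
    "RandomREParams",
    "HillParams",
    "InhibitionParams",
    "OrderedParams",
    "PingPongParams",
    "rate_random_re",
    "rate_hill",
    "rate_inhibited",
    "rate_ordered",
    "rate_ping_pong",
    "catalytic_constants",
    "INHIBITION_KINDS",
]

INHIBITION_KINDS = ("competitive", "noncompetitive", "mixed", "uncompetitive")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


def _check_conc(name, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


@dataclass(frozen=True)
class RandomREParams:
    """Parameters of the rapid-equilibrium random-order rate law.

    vmax in umol.min-1.mg-1; ka, kb are the Michaelis constants (mM) for the
    varied substrates A (PEP3-) and B (ADP-Mg).
    """

    vmax: float
    ka: float
    kb: float

    def __post_init__(self) -> None:
        _check_positive("vmax", self.vmax)
        _check_positive("ka", self.ka)
        _check_positive("kb", self.kb)


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: vmax, half-saturation K0.5 (mM), exponent n."""

    vmax: float
    k05: float
    n: float

    def __post_init__(self) -> None:
        _check_positive("vmax", self.vmax)
        _check_positive("k05", self.k05)
        _check_positive("n", self.n)


@dataclass(frozen=True)
class InhibitionParams:
    """Parameters of the linear dead-end inhibition rate laws.

    ``kind`` selects the equation; ``alpha`` is the interaction factor of the
    mixed model (alpha = 1 reduces it to noncompetitive, and it is ignored by
    the competitive model).  The uncompetitive form (slope unaffected,
    intercept only) is provided for completeness of the Cleland family.
    """

    v: float
    km: float
    ki: float
    alpha: float = 1.0
    kind: str = "competitive"

    def __post_init__(self) -> None:
        _check_positive("v", self.v)
        _check_positive("km", self.km)
        _check_positive("ki", self.ki)
        _check_positive("alpha", self.alpha)
        if self.kind not in INHIBITION_KINDS:
            raise ValueError(f"unknown inhibition kind {self.kind!r}")
        if self.kind == "noncompetitive" and self.alpha != 1.0:
            raise ValueError("noncompetitive inhibition requires alpha = 1")


@dataclass(frozen=True)
class OrderedParams:
    """Ordered steady-state bi-bi law (A binds first), no products.

    v = Vmax*A*B / (Kia*Kb + Kb*A + Ka*B + A*B).  Kia is the dissociation
    constant of A from the binary complex; Kia != Ka displaces the
    double-reciprocal intersection off the 1/S axis.
    """

    vmax: float
    ka: float
    kb: float
    kia: float

    def __post_init__(self) -> None:
        for name in ("vmax", "ka", "kb", "kia"):
            _check_positive(name, getattr(self, name))


@dataclass(frozen=True)
class PingPongParams:
    """Ping-pong bi-bi law: v = Vmax*A*B / (Ka*B + Kb*A + A*B)."""

    vmax: float
    ka: float
    kb: float

    def __post_init__(self) -> None:
        for name in ("vmax", "ka", "kb"):
            _check_positive(name, getattr(self, name))


def rate_random_re(a, b, p: RandomREParams):
    """Velocity of the rapid-equilibrium random-order mechanism at (A, B)."""
    a = _check_conc("a", a)
    b = _check_conc("b", b)
    num = p.vmax * a * b
    den = p.ka * p.kb + p.ka * b + p.kb * a + a * b
    out = num / den
    return float(out) if out.ndim == 0 else out


def rate_hill(s, p: HillParams):
    """Hill velocity vmax * S^n / (K0.5^n + S^n)."""
    s = _check_conc("s", s)
    sn = np.power(s, p.n)
    out = p.vmax * sn / (p.k05**p.n + sn)
    return float(out) if out.ndim == 0 else out


def rate_inhibited(s, i, p: InhibitionParams):
    """Velocity of the selected linear inhibition law at substrate S, inhibitor I.

    competitive:    v = V*S / (Km*(1 + I/Ki) + S)
    noncompetitive: v = V*S / (Km*(1 + I/Ki) + S*(1 + I/Ki))
    mixed:          v = V*S / (Km*(1 + I/Ki) + S*(1 + I/(alpha*Ki)))
    uncompetitive:  v = V*S / (Km + S*(1 + I/Ki))
    """
    s = _check_conc("s", s)
    i = _check_conc("i", i)
    if p.kind == "competitive":
        den = p.km * (1.0 + i / p.ki) + s
    elif p.kind in ("noncompetitive", "mixed"):
        den = p.km * (1.0 + i / p.ki) + s * (1.0 + i / (p.alpha * p.ki))
    else:  # uncompetitive
        den = p.km + s * (1.0 + i / p.ki)
    out = p.v * s / den
    return float(out) if out.ndim == 0 else out


def rate_ordered(a, b, p: OrderedParams):
    """Velocity of the ordered steady-state bi-bi law at (A, B)."""
    a = _check_conc("a", a)
    b = _check_conc("b", b)
    den = p.kia * p.kb + p.kb * a + p.ka * b + a * b
    out = p.vmax * a * b / den
    return float(out) if out.ndim == 0 else out


def rate_ping_pong(a, b, p: PingPongParams):
    """Velocity of the ping-pong bi-bi law at (A, B)."""
    a = _check_conc("a", a)
    b = _check_conc("b", b)
    den = p.ka * b + p.kb * a + a * b
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, p.vmax * a * b / np.where(den > 0, den, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


#: Monomer mass of the T. pendens pyruvate kinase (Da), tag-free.
TPPK_SUBUNIT_MASS_DA = 51_340.0


def catalytic_constants(
    vmax_specific: float,
    subunit_mass: float = TPPK_SUBUNIT_MASS_DA,
    n_subunits: int = 4,
    km_mM: Dict[str, float] | None = None,
) -> Dict[str, object]:
    """Turnover number and log specificity constants from a specific activity.

    kcat is computed per oligomer: ``vmax_specific`` (umol.min-1.mg-1) times
    the oligomer molar mass (``subunit_mass * n_subunits``, g/mol) gives
    umol product per umol enzyme per minute, divided by 60 for s-1.  The
    enzyme here is a homotetramer, so the default basis is 4 subunits;
    the per-monomer number is obtained with ``n_subunits=1``.

    ``km_mM`` maps substrate name to its Michaelis constant in mM; for each,
    ``log10(kcat / Km)`` is reported with Km converted to molar, i.e. the
    specificity constant in M-1 s-1 on a log scale.

    Returns a dict with keys ``kcat`` (s-1) and ``log_specificity``
    (name -> log10(kcat/Km)).
    """
    if vmax_specific < 0:
        raise ValueError("vmax_specific must be >= 0")
    _check_positive("subunit_mass", subunit_mass)
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    molar_mass = subunit_mass * n_subunits  # g/mol = mg/mmol... (Da)
    # umol.min-1.mg-1 * g/mol = mol product / mol enzyme / min
    kcat = vmax_specific * 1e-6 * molar_mass / 60.0 * 1e3
    # units walk-through: vmax 1e-6 mol.min-1.mg-1 * mass mg/mmol -> 1e-6
    # mol.min-1.mmol-1 = 1e-3 min-1; *1e3 -> min-1; /60 -> s-1.
    log_spec: Dict[str, float] = {}
    for name, km in (km_mM or {}).items():
        _check_positive(f"km[{name}]", km)
        log_spec[name] = math.log10(kcat / (km * 1e-3))
    return {"kcat": kcat, "log_specificity": log_spec}
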