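"""Whole-body layer of the glucose homeostasis model.

Fourteen ordinary differential equations describe the minute-scale dynamics
of glucose masses and hormone concentrations across gut, plasma, liver,
muscle and adipose tissue, plus the two interstitial deviation variables
that couple the whole-body layer to the adipocyte signaling cascade:

==========  =======================================================  ==========
variable    meaning                                                  units
==========  =======================================================  ==========
S           stomach glucose mass                                     mg
L           intestine glucose mass                                   mg
G           plasma glucose concentration                             mg/dL
I           plasma insulin concentration                             uU/mL
W           plasma incretin concentration                            pmol/L
E           plasma glucagon concentration                            pg/mL
C           liver glucose mass ready for secretion                   mg
M           muscle glucose mass                                      mg
A           adipose glucose mass                                     mg
Y           plasma leptin                                            ng/mL
Q           plasma ghrelin                                           pg/mL
H           hunger signal: glucose amount needed by the body         mg
INS_A       interstitial insulin deviation above basal               uU/mL
Gt_A        interstitial glucose deviation above basal               mg/dL
==========  =======================================================  ==========

The loop is closed through hunger: ghrelin (secreted by the empty stomach)
drives H up, leptin and insulin push it down, and intake ``b9*H`` feeds the
stomach, so the model self-sustains recurrent meals without external forcing.

Unit conventions: ``v`` is the glucose distribution volume in dL so that
mass/v is mg/dL; ``f`` is the dimensionless absorbed fraction; insulin
effectiveness ``e`` multiplies insulin action (``e = 1`` in normal glucose
regulation, lower in type 2 diabetes).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WHOLE_BODY_STATE_NAMES",
    "WholeBodyState",
    "WholeBodyParams",
    "heaviside_switch",
    "smoothed_heaviside",
    "glucagon_rate",
    "hunger_rate",
    "interstitial_rates",
    "whole_body_rhs",
]

#: Canonical state ordering used by every array-based interface.
WHOLE_BODY_STATE_NAMES: tuple[str, ...] = (
    "S", "L", "G", "I", "W", "E", "C",
    "M", "A", "Y", "Q", "H", "INS_A", "Gt_A",
)

# Tolerance below which a negative component is treated as integrator noise
# and clipped to zero; anything more negative is a genuine domain error.
NEGATIVE_GUARD = -1e-9


@dataclass(frozen=True)
class WholeBodyState:
    """Named container for the 14 whole-body state variables.

    All fields must be non-negative; units are fixed per field (see module
    docstring) and conversions happen only inside the rate terms via the
    distribution volume ``v`` and absorbed fraction ``f``.
    """

    S: float
    L: float
    G: float
    I: float
    W: float
    E: float
    C: float
    M: float
    A: float
    Y: float
    Q: float
    H: float
    INS_A: float = 0.0
    Gt_A: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in WHOLE_BODY_STATE_NAMES],
                        dtype=float)

    @classmethod
    def from_array(cls, arr) -> "WholeBodyState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(WHOLE_BODY_STATE_NAMES),):
            raise ValueError(
                f"expected {len(WHOLE_BODY_STATE_NAMES)} components, "
                f"got shape {arr.shape}")
        return cls(**dict(zip(WHOLE_BODY_STATE_NAMES, arr.tolist())))

    def replace(self, **kwargs) -> "WholeBodyState":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class WholeBodyParams:
    """Rate constants, thresholds and volumes of the whole-body equations.

    ``b4, b5, b12, b13, b17, b27, c, c3`` are normally not set by hand: the
    parameter workflow derives them from the fasting steady state (see
    :mod:`glucoloop.parameter_workflow`).  ``kgluc`` is shared with the
    cellular layer because adipose glucose mass (A) sits in both.
    """

    # gut / plasma glucose
    b1: float    # insulin-independent plasma glucose elimination (1/min)
    b3: float    # insulin-dependent elimination (mL/uU/min)
    b8: float    # stomach emptying rate (1/min)
    b9: float    # hunger-to-stomach intake rate (1/min)
    b10: float   # intestine-to-plasma transfer rate (1/min)
    f: float     # absorbed fraction (dimensionless, 0 < f <= 1)
    v: float     # glucose distribution volume (dL)
    # insulin / incretin
    b2: float    # insulin elimination rate (1/min)
    b4: float    # glucose-dependent insulin secretion rate
    c: float     # incretin-dependent insulin secretion rate
    b6: float    # incretin secretion rate from intestinal glucose
    b7: float    # incretin elimination rate (1/min)
    s: float     # constant incretin appearance rate (pmol/L/min)
    # glucagon
    c0: float    # basal glucagon secretion (pg/mL/min)
    c1: float    # glucose-gated glucagon secretion scale
    c2: float    # insulin half-suppression offset for glucagon secretion
    c3: float    # glucagon elimination rate (1/min)
    Ge: float    # plasma glucose threshold gating glucagon secretion (mg/dL)
    e: float     # insulin effectiveness (1 in NGR, < 1 in T2DM)
    # liver
    b5: float    # liver-to-plasma glucose transfer rate (1/min)
    b21: float   # glucagon-dependent liver glucose production
    b22: float   # glucose inhibition of liver production
    b23: float   # basal liver glucose production (mg/min)
    b25: float   # insulin inhibition of liver production
    # muscle / adipose
    b27: float   # muscle glucose elimination rate (1/min)
    kgluc: float  # adipose glucose elimination rate (1/min)
    # leptin / ghrelin / hunger
    b11: float   # ghrelin elimination rate (1/min)
    b12: float   # ghrelin secretion rate (pg/mL/min)
    b13: float   # leptin secretion rate
    b14: float   # leptin elimination rate (1/min)
    b17: float   # ghrelin-dependent hunger drive rate
    b18: float   # leptin inhibition scale on hunger (mL/ng)
    b19: float   # glucose-dependent hunger decay (dL/mg/min)
    l: float     # stomach-glucose decay rate of ghrelin secretion (1/mg)
    m: float     # insulin decay rate of ghrelin secretion (mL/uU)
    r: float     # insulin inhibition rate on hunger (mL/uU)
    Fat: float   # average total fat mass (kg)
    # basal levels & interstitial transfer
    Ib: float    # basal plasma insulin (uU/mL)
    Gb: float    # basal plasma glucose (mg/dL)
    p2U: float   # interstitial insulin transfer/degradation rate (1/min)
    q1: float    # interstitial glucose degradation rate (1/min)
    q2: float    # plasma-to-interstitium glucose transfer rate (1/min)

    def replace(self, **kwargs) -> "WholeBodyParams":
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        """Raise ``ValueError`` on an out-of-domain parameter."""
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValueError(f"parameter {name} is not finite: {val}")
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"f must lie in (0, 1], got {self.f}")
        if not 0.0 < self.e <= 1.0:
            raise ValueError(f"e must lie in (0, 1], got {self.e}")
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        for name in self.__dataclass_fields__:
            if name in ("s",):
                continue
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0, "
                                 f"got {getattr(self, name)}")


def heaviside_switch(x: float) -> float:
    """Right-continuous unit step: 1 for x >= 0, 0 for x < 0.

    Gates glucagon secretion on the sign of ``Ge - G``; the step is taken
    closed on the right so that ``u(0) = 1``.
    """
    if not math.isfinite(x):
        raise ValueError(f"heaviside_switch requires a finite argument, got {x}")
    return 1.0 if x >= 0.0 else 0.0


def smoothed_heaviside(steepness: float):
    """Return a tanh approximation of the unit step, for stiff solvers that
    prefer a smooth right-hand side.  ``steepness`` has units 1/(mg/dL)."""
    if steepness <= 0:
        raise ValueError("steepness must be positive")

    def u(x: float) -> float:
        if not math.isfinite(x):
            raise ValueError(f"smoothed heaviside requires finite argument, got {x}")
        return 0.5 * (1.0 + math.tanh(steepness * x))

    return u


def glucagon_rate(G: float, I: float, E: float, p: WholeBodyParams,
                  heaviside=heaviside_switch) -> float:
    """dE/dt: basal secretion, glucose-gated secretion suppressed by
    insulin, and first-order elimination.

    Below the glucose threshold ``Ge`` the secretion term
    ``c1/(c2 + I*e) * (Ge - G)`` switches on; above it only the basal and
    elimination terms remain, giving the fixed point ``E = c0/c3``.
    """
    denom = p.c2 + I * p.e
    if denom == 0.0:
        raise ZeroDivisionError("glucagon_rate: c2 + I*e is zero")
    gate = heaviside(p.Ge - G)
    return p.c0 + (p.c1 / denom) * (p.Ge - G) * gate - p.c3 * E


def hunger_rate(Q: float, Y: float, I: float, G: float, H: float,
                p: WholeBodyParams) -> float:
    """dH/dt: ghrelin-driven appetite, divided down by leptin and
    exponentially suppressed by insulin, minus glucose-dependent decay and
    the transfer of intake into the stomach."""
    drive = p.b17 * Q / (p.b18 * Y + 1.0) * math.exp(-p.r * I)
    return drive - p.b19 * G * H - p.b9 * H


def interstitial_rates(I: float, G: float, INS_A: float, Gt_A: float,
                       p: WholeBodyParams) -> tuple[float, float]:
    """(dINS_A/dt, dGt_A/dt): first-order relaxation toward the
    above-basal plasma excess.

    Only the amount exceeding basal transfers to the interstitium; the
    drive terms are floored at zero so that a plasma dip below basal cannot
    pull the interstitial deviations negative.
    """
    d_ins = -p.p2U * INS_A + p.p2U * max(I - p.Ib, 0.0)
    d_gt = -p.q1 * Gt_A + p.q2 * max(G - p.Gb, 0.0)
    return d_ins, d_gt


def whole_body_rhs(state, uptake_flux: float, p: WholeBodyParams,
                   heaviside=heaviside_switch) -> np.ndarray:
    """Time derivatives of all 14 whole-body variables.

    Parameters
    ----------
    state
        Array of length 14 ordered as :data:`WHOLE_BODY_STATE_NAMES`, or a
        :class:`WholeBodyState`.
    uptake_flux
        GLUT1/GLUT4-mediated adipocyte glucose entry flux (mg/min), the
        first two terms of the adipose mass balance; computed by the
        cellular layer (:func:`glucoloop.adipocyte_signaling.adipose_glucose_uptake`).
    p
        Whole-body parameter set.
    heaviside
        Unit-step implementation used by the glucagon gate (exact by
        default; pass :func:`smoothed_heaviside` output to smooth it).
    """
    if isinstance(state, WholeBodyState):
        state = state.as_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (len(WHOLE_BODY_STATE_NAMES),):
        raise ValueError(f"expected 14 state components, got shape {y.shape}")
    if np.any(y < NEGATIVE_GUARD):
        bad = [n for n, v in zip(WHOLE_BODY_STATE_NAMES, y) if v < NEGATIVE_GUARD]
        raise ValueError(f"negative state components: {bad}")
    if uptake_flux < 0:
        raise ValueError(f"uptake_flux must be >= 0, got {uptake_flux}")
    # Clip integrator noise so rate laws see the physical orthant.
    y = np.clip(y, 0.0, None)
    S, L, G, I, W, E, C, M, A, Y, Q, H, INS_A, Gt_A = y

    dS = p.b9 * H - p.b8 * S
    dL = p.b8 * S - p.b10 * L
    dG = (p.f * p.b10 * L / p.v + p.f * p.b5 * C / p.v
          - p.b1 * G - p.b3 * I * G)
    dI = p.b4 * G + p.c * W * G - p.b2 * I
    dW = p.b6 * L - p.b7 * W + p.s
    dE = glucagon_rate(G, I, E, p, heaviside)
    dC = p.b23 - p.b25 * I * p.e - p.b22 * G + p.b21 * E - p.b5 * C
    dM = 0.1 * p.v * p.f * p.b3 * G * I * p.e - p.b27 * M
    dA = uptake_flux - p.kgluc * A
    dY = p.b13 * A / p.Fat - p.b14 * Y
    dQ = p.b12 * math.exp(-p.l * S) * math.exp(-p.m * I) - p.b11 * Q
    dH = hunger_rate(Q, Y, I, G, H, p)
    dINS_A, dGt_A = interstitial_rates(I, G, INS_A, Gt_A, p)

    return np.array([dS, dL, dG, dI, dW, dE, dC, dM, dA, dY, dQ, dH,
                     dINS_A, dGt_A])
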