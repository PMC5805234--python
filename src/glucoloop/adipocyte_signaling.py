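"""Adipocyte insulin-signaling cascade (cellular layer).

Mass-action kinetics for 27 species, from binding of interstitial insulin
(INS_A) to the free insulin receptor (IR) down to translocation of GLUT4 to
the plasma membrane (GLUT4m), plus the GLUT1/GLUT4-mediated glucose-uptake
flux that feeds adipose glucose mass at the whole-body level.

The cascade consists of ten interconversion cycles, each conserving its
total protein amount:

* receptor 5-cycle: IR, IR_YP, IRins, IRi_YP, IRi
* IRS1 4-cycle: IRS1, IRS1_YP, IRS1_YP_S307P, IRS1_S307P
* feedback protein: X, X_P
* PKB 4-cycle: PKB, PKB_T308P, PKB_S473P, PKB_T308P_S473P
* mTORC1 / mTORC1a, mTORC2 / mTORC2a
* AS160 / AS160_T642P, GLUT4 / GLUT4m
* S6K / S6K_T389P, S6 / S6_S235_S236P

Amounts are in arbitrary units (a.u.); the absolute scale linking GLUT4m to
a glucose flux in mg/min is carried entirely by ``k8``.

Two modules of code evaluate the same dynamics: :func:`cellular_rhs` is a
direct transcription of the rate equations, while
:func:`build_reaction_network` compiles a declarative reaction list into a
stoichiometry-times-flux product.  The two are algebraically identical and
cross-checked in the test suite; the network also supports an SBML export.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CELLULAR_STATE_NAMES",
    "CellularState",
    "CellularParams",
    "Reaction",
    "ReactionNetwork",
    "cellular_rhs",
    "adipose_glucose_uptake",
    "conserved_totals",
    "build_reaction_network",
    "relax_to_steady_state",
    "to_sbml",
]

CELLULAR_STATE_NAMES: tuple[str, ...] = (
    "IR", "IR_YP", "IRins", "IRi_YP", "IRi",
    "IRS1", "IRS1_YP", "IRS1_YP_S307P", "IRS1_S307P",
    "X", "X_P",
    "PKB", "PKB_T308P", "PKB_S473P", "PKB_T308P_S473P",
    "mTORC1", "mTORC1a", "mTORC2", "mTORC2a",
    "AS160", "AS160_T642P",
    "GLUT4", "GLUT4m",
    "S6K", "S6K_T389P",
    "S6", "S6_S235_S236P",
)

#: Conserved protein groups: name -> member species.
CONSERVED_GROUPS: dict[str, tuple[str, ...]] = {
    "receptor": ("IR", "IR_YP", "IRins", "IRi_YP", "IRi"),
    "irs1": ("IRS1", "IRS1_YP", "IRS1_YP_S307P", "IRS1_S307P"),
    "x": ("X", "X_P"),
    "pkb": ("PKB", "PKB_T308P", "PKB_S473P", "PKB_T308P_S473P"),
    "mtorc1": ("mTORC1", "mTORC1a"),
    "mtorc2": ("mTORC2", "mTORC2a"),
    "as160": ("AS160", "AS160_T642P"),
    "glut4": ("GLUT4", "GLUT4m"),
    "s6k": ("S6K", "S6K_T389P"),
    "s6": ("S6", "S6_S235_S236P"),
}

_IDX = {name: i for i, name in enumerate(CELLULAR_STATE_NAMES)}


@dataclass(frozen=True)
class CellularState:
    """Named 27-species state vector (arbitrary units, non-negative)."""

    IR: float
    IR_YP: float
    IRins: float
    IRi_YP: float
    IRi: float
    IRS1: float
    IRS1_YP: float
    IRS1_YP_S307P: float
    IRS1_S307P: float
    X: float
    X_P: float
    PKB: float
    PKB_T308P: float
    PKB_S473P: float
    PKB_T308P_S473P: float
    mTORC1: float
    mTORC1a: float
    mTORC2: float
    mTORC2a: float
    AS160: float
    AS160_T642P: float
    GLUT4: float
    GLUT4m: float
    S6K: float
    S6K_T389P: float
    S6: float
    S6_S235_S236P: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CELLULAR_STATE_NAMES],
                        dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CellularState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(CELLULAR_STATE_NAMES),):
            raise ValueError(
                f"expected {len(CELLULAR_STATE_NAMES)} species, got {arr.shape}")
        return cls(**dict(zip(CELLULAR_STATE_NAMES, arr.tolist())))

    def replace(self, **kwargs) -> "CellularState":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class CellularParams:
    """Mass-action rate constants of the signaling cascade.

    Unimolecular constants are 1/min; constants whose flux includes a
    species modifier or INS_A are 1/min per a.u. (or per uU/mL for k1a).
    ``kfb`` scales the mTORC1a positive-feedback flux on IRS1 serine
    phosphorylation and is one of the three quantities reduced in the T2DM
    preset (together with the receptor and GLUT4 totals).

    ``irs1_printed_variant`` switches the IRS1 tyrosine-phosphorylation
    drive in the unphosphorylated-IRS1 balance from the internalized
    receptor (IRi_YP, the conservation-restoring form used by default) to
    the membrane form (IR_YP) for compatibility with the as-printed
    equation set; the variant breaks IRS1 conservation and exists only for
    comparison.
    """

    # receptor cycle
    k1a: float
    k1basal: float
    k1c: float
    k1d: float
    k1f: float
    k1g: float
    k1r: float
    # IRS1 cycle
    k2a: float
    k2b: float
    k2c: float
    k2d: float
    k2f: float
    k2g: float
    k2basal: float
    kfb: float
    # feedback protein X
    k3a: float
    k3b: float
    # PKB cycle
    k4a: float
    k4b: float
    k4c: float
    k4e: float
    k4f: float
    k4h: float
    # mTOR complexes
    k5a1: float
    k5a2: float
    k5b: float
    k5c: float
    k5d: float
    # AS160
    k6a1: float
    k6a2: float
    k6b: float
    # GLUT4 translocation
    k7a: float
    k7b: float
    # S6K / S6
    k9a: float
    k9b: float
    k9f2: float
    k9b2: float
    # glucose uptake (shared with the whole-body adipose balance)
    GLUT1: float   # constant transporter amount (a.u.)
    k8: float      # GLUT4m flux scale (mg/min per a.u.)
    KmG4: float    # half-saturation of GLUT4-mediated entry (mg/dL)
    KmG1: float    # half-saturation of GLUT1-mediated entry (mg/dL)
    kgluc: float   # adipose glucose elimination rate (1/min)
    irs1_printed_variant: bool = False

    def replace(self, **kwargs) -> "CellularParams":
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            if name == "irs1_printed_variant":
                continue
            val = getattr(self, name)
            if not math.isfinite(val) or val <= 0:
                raise ValueError(f"parameter {name} must be positive and "
                                 f"finite, got {val}")


def cellular_rhs(cstate, INS_A: float, p: CellularParams) -> np.ndarray:
    """Time derivatives of the 27 signaling species.

    Direct term-by-term transcription of the mass-action rate equations.
    Every conserved group's derivatives sum to zero exactly in real
    arithmetic (for the default, conservation-restoring IRS1 wiring).
    """
    if isinstance(cstate, CellularState):
        cstate = cstate.as_array()
    y = np.asarray(cstate, dtype=float)
    if y.shape != (len(CELLULAR_STATE_NAMES),):
        raise ValueError(f"expected 27 species, got shape {y.shape}")
    if np.any(y < -1e-9):
        bad = [n for n, v in zip(CELLULAR_STATE_NAMES, y) if v < -1e-9]
        raise ValueError(f"negative species: {bad}")
    if INS_A < 0:
        raise ValueError(f"INS_A must be >= 0, got {INS_A}")
    y = np.clip(y, 0.0, None)
    (IR, IR_YP, IRins, IRi_YP, IRi,
     IRS1, IRS1_YP, IRS1_YP_S307P, IRS1_S307P,
     X, X_P,
     PKB, PKB_T308P, PKB_S473P, PKB_T308P_S473P,
     mTORC1, mTORC1a, mTORC2, mTORC2a,
     AS160, AS160_T642P,
     GLUT4, GLUT4m,
     S6K, S6K_T389P,
     S6, S6_S235_S236P) = y

    d = np.empty(len(CELLULAR_STATE_NAMES))

    # receptor 5-cycle
    d[_IDX["IR"]] = (-p.k1a * IR * INS_A - p.k1basal * IR
                     + p.k1g * IR_YP + p.k1r * IRi)
    d[_IDX["IR_YP"]] = (p.k1basal * IR + p.k1c * IRins
                        - p.k1d * IR_YP - p.k1g * IR_YP)
    d[_IDX["IRins"]] = p.k1a * IR * INS_A - p.k1c * IRins
    d[_IDX["IRi_YP"]] = p.k1d * IR_YP - p.k1f * IRi_YP * X_P
    d[_IDX["IRi"]] = p.k1f * IRi_YP * X_P - p.k1r * IRi

    # IRS1 4-cycle; the tyrosine-phosphorylation drive is the internalized
    # phosphorylated receptor in both balance equations (restores the IRS1
    # conservation broken by the membrane-receptor variant).
    irs1_driver = IR_YP if p.irs1_printed_variant else IRi_YP
    fb_flux = p.k2c * IRS1_YP * mTORC1a * p.kfb
    d[_IDX["IRS1"]] = (p.k2b * IRS1_YP + p.k2g * IRS1_S307P
                       - p.k2a * IRS1 * irs1_driver - p.k2basal * IRS1)
    d[_IDX["IRS1_YP"]] = (p.k2a * IRS1 * IRi_YP + p.k2d * IRS1_YP_S307P
                          - p.k2b * IRS1_YP - fb_flux)
    d[_IDX["IRS1_YP_S307P"]] = (fb_flux - p.k2d * IRS1_YP_S307P
                                - p.k2f * IRS1_YP_S307P)
    d[_IDX["IRS1_S307P"]] = (p.k2basal * IRS1 + p.k2f * IRS1_YP_S307P
                             - p.k2g * IRS1_S307P)

    # feedback protein X
    d[_IDX["X"]] = p.k3b * X_P - p.k3a * X * IRS1_YP
    d[_IDX["X_P"]] = p.k3a * X * IRS1_YP - p.k3b * X_P

    # PKB 4-cycle
    d[_IDX["PKB"]] = (p.k4b * PKB_T308P + p.k4h * PKB_S473P
                      - p.k4a * PKB * IRS1_YP)
    d[_IDX["PKB_T308P"]] = (p.k4a * PKB * IRS1_YP - p.k4b * PKB_T308P
                            - p.k4c * PKB_T308P * mTORC2a)
    d[_IDX["PKB_S473P"]] = (p.k4f * PKB_T308P_S473P
                            - p.k4e * PKB_S473P * IRS1_YP_S307P
                            - p.k4h * PKB_S473P)
    d[_IDX["PKB_T308P_S473P"]] = (p.k4c * PKB_T308P * mTORC2a
                                  + p.k4e * PKB_S473P * IRS1_YP_S307P
                                  - p.k4f * PKB_T308P_S473P)

    # mTORC1 pair (activation driven by doubly- and singly-phosphorylated PKB)
    act1 = mTORC1 * (p.k5a1 * PKB_T308P_S473P + p.k5a2 * PKB_T308P)
    d[_IDX["mTORC1"]] = p.k5b * mTORC1a - act1
    d[_IDX["mTORC1a"]] = act1 - p.k5b * mTORC1a

    # mTORC2 pair (activated by the internalized phosphorylated receptor)
    d[_IDX["mTORC2"]] = -p.k5c * mTORC2 * IRi_YP + p.k5d * mTORC2a
    d[_IDX["mTORC2a"]] = p.k5c * mTORC2 * IRi_YP - p.k5d * mTORC2a

    # AS160 pair
    act6 = AS160 * (p.k6a1 * PKB_T308P_S473P + p.k6a2 * PKB_S473P)
    d[_IDX["AS160"]] = p.k6b * AS160_T642P - act6
    d[_IDX["AS160_T642P"]] = act6 - p.k6b * AS160_T642P

    # GLUT4 translocation
    transloc = p.k7a * GLUT4 * AS160_T642P
    d[_IDX["GLUT4"]] = -transloc + p.k7b * GLUT4m
    d[_IDX["GLUT4m"]] = transloc - p.k7b * GLUT4m

    # S6K / S6
    d[_IDX["S6K"]] = p.k9b * S6K_T389P - p.k9a * S6K * mTORC1a
    d[_IDX["S6K_T389P"]] = p.k9a * S6K * mTORC1a - p.k9b * S6K_T389P
    d[_IDX["S6"]] = p.k9b2 * S6_S235_S236P - p.k9f2 * S6 * S6K_T389P
    d[_IDX["S6_S235_S236P"]] = p.k9f2 * S6 * S6K_T389P - p.k9b2 * S6_S235_S236P

    return d


def adipose_glucose_uptake(GLUT4m: float, Gt_A: float,
                           p: CellularParams) -> float:
    """Glucose entry flux into adipocytes (mg/min).

    Two saturating Michaelis-Menten routes in interstitial glucose Gt_A:
    insulin-regulated GLUT4 at the membrane and the constitutive, constant
    GLUT1 pool.  Monotone increasing in Gt_A and bounded by
    ``k8*GLUT4m + GLUT1``.
    """
    if GLUT4m < 0 or Gt_A < 0:
        raise ValueError("adipose_glucose_uptake requires non-negative inputs")
    return (p.k8 * GLUT4m * Gt_A / (p.KmG4 + Gt_A)
            + p.GLUT1 * Gt_A / (p.KmG1 + Gt_A))


def conserved_totals(cstate) -> dict[str, float]:
    """Total protein amount of each of the ten interconversion cycles."""
    if isinstance(cstate, CellularState):
        cstate = cstate.as_array()
    y = np.asarray(cstate, dtype=float)
    return {group: float(sum(y[_IDX[s]] for s in members))
            for group, members in CONSERVED_GROUPS.items()}


# ---------------------------------------------------------------------------
# Declarative reaction network (independent oracle + SBML export)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    Flux = rate_constant * prod(reactants) * prod(modifiers)
           * (INS_A if insulin_driven) * (kfb if kfb_scaled).
    Modifiers multiply the rate law without being consumed.
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: str
    modifiers: tuple[str, ...] = ()
    insulin_driven: bool = False
    kfb_scaled: bool = False


@dataclass
class ReactionNetwork:
    """Reaction list compiled to a stoichiometry matrix and flux function."""

    reactions: list[Reaction]
    params: CellularParams
    stoichiometry: np.ndarray = field(init=False)  # (species, reactions)

    def __post_init__(self) -> None:
        n_s, n_r = len(CELLULAR_STATE_NAMES), len(self.reactions)
        N = np.zeros((n_s, n_r))
        for j, rxn in enumerate(self.reactions):
            for sp in rxn.reactants:
                N[_IDX[sp], j] -= 1.0
            for sp in rxn.products:
                N[_IDX[sp], j] += 1.0
        self.stoichiometry = N

    def fluxes(self, cstate, INS_A: float) -> np.ndarray:
        y = np.asarray(cstate, dtype=float)
        v = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            rate = getattr(self.params, rxn.rate_constant)
            for sp in rxn.reactants:
                rate *= y[_IDX[sp]]
            for sp in rxn.modifiers:
                rate *= y[_IDX[sp]]
            if rxn.insulin_driven:
                rate *= INS_A
            if rxn.kfb_scaled:
                rate *= self.params.kfb
            v[j] = rate
        return v

    def rhs(self, cstate, INS_A: float) -> np.ndarray:
        """Stoichiometry-times-flux derivative vector."""
        return self.stoichiometry @ self.fluxes(cstate, INS_A)

    def conservation_vectors(self) -> np.ndarray:
        """Indicator vectors of the ten conserved groups, rows spanning a
        subspace of the left null space of the stoichiometry matrix."""
        vecs = np.zeros((len(CONSERVED_GROUPS), len(CELLULAR_STATE_NAMES)))
        for i, members in enumerate(CONSERVED_GROUPS.values()):
            for sp in members:
                vecs[i, _IDX[sp]] = 1.0
        return vecs


def build_reaction_network(p: CellularParams) -> ReactionNetwork:
    """Declarative reaction list whose compiled RHS is algebraically
    identical to :func:`cellular_rhs` (default wiring)."""
    R = Reaction
    reactions = [
        # receptor cycle
        R("ins_binding", ("IR",), ("IRins",), "k1a", insulin_driven=True),
        R("basal_autophos", ("IR",), ("IR_YP",), "k1basal"),
        R("bound_autophos", ("IRins",), ("IR_YP",), "k1c"),
        R("receptor_dephos", ("IR_YP",), ("IR",), "k1g"),
        R("internalization", ("IR_YP",), ("IRi_YP",), "k1d"),
        R("internal_dephos", ("IRi_YP",), ("IRi",), "k1f", modifiers=("X_P",)),
        R("recycling", ("IRi",), ("IR",), "k1r"),
        # IRS1 cycle
        R("irs1_tyr_phos", ("IRS1",), ("IRS1_YP",), "k2a",
          modifiers=("IRi_YP",)),
        R("irs1_tyr_dephos", ("IRS1_YP",), ("IRS1",), "k2b"),
        R("irs1_ser_phos_fb", ("IRS1_YP",), ("IRS1_YP_S307P",), "k2c",
          modifiers=("mTORC1a",), kfb_scaled=True),
        R("irs1_ser_dephos", ("IRS1_YP_S307P",), ("IRS1_YP",), "k2d"),
        R("irs1_tyr_loss", ("IRS1_YP_S307P",), ("IRS1_S307P",), "k2f"),
        R("irs1_ser_recovery", ("IRS1_S307P",), ("IRS1",), "k2g"),
        R("irs1_basal_ser", ("IRS1",), ("IRS1_S307P",), "k2basal"),
        # feedback protein X
        R("x_activation", ("X",), ("X_P",), "k3a", modifiers=("IRS1_YP",)),
        R("x_deactivation", ("X_P",), ("X",), "k3b"),
        # PKB cycle
        R("pkb_t308_phos", ("PKB",), ("PKB_T308P",), "k4a",
          modifiers=("IRS1_YP",)),
        R("pkb_t308_dephos", ("PKB_T308P",), ("PKB",), "k4b"),
        R("pkb_s473_phos", ("PKB_T308P",), ("PKB_T308P_S473P",), "k4c",
          modifiers=("mTORC2a",)),
        R("pkb_t308_gain", ("PKB_S473P",), ("PKB_T308P_S473P",), "k4e",
          modifiers=("IRS1_YP_S307P",)),
        R("pkb_t308_loss", ("PKB_T308P_S473P",), ("PKB_S473P",), "k4f"),
        R("pkb_s473_dephos", ("PKB_S473P",), ("PKB",), "k4h"),
        # mTOR complexes
        R("mtorc1_act_dual", ("mTORC1",), ("mTORC1a",), "k5a1",
          modifiers=("PKB_T308P_S473P",)),
        R("mtorc1_act_t308", ("mTORC1",), ("mTORC1a",), "k5a2",
          modifiers=("PKB_T308P",)),
        R("mtorc1_deact", ("mTORC1a",), ("mTORC1",), "k5b"),
        R("mtorc2_act", ("mTORC2",), ("mTORC2a",), "k5c",
          modifiers=("IRi_YP",)),
        R("mtorc2_deact", ("mTORC2a",), ("mTORC2",), "k5d"),
        # AS160
        R("as160_phos_dual", ("AS160",), ("AS160_T642P",), "k6a1",
          modifiers=("PKB_T308P_S473P",)),
        R("as160_phos_s473", ("AS160",), ("AS160_T642P",), "k6a2",
          modifiers=("PKB_S473P",)),
        R("as160_dephos", ("AS160_T642P",), ("AS160",), "k6b"),
        # GLUT4 translocation
        R("glut4_translocation", ("GLUT4",), ("GLUT4m",), "k7a",
          modifiers=("AS160_T642P",)),
        R("glut4_retrieval", ("GLUT4m",), ("GLUT4",), "k7b"),
        # S6K / S6
        R("s6k_phos", ("S6K",), ("S6K_T389P",), "k9a", modifiers=("mTORC1a",)),
        R("s6k_dephos", ("S6K_T389P",), ("S6K",), "k9b"),
        R("s6_phos", ("S6",), ("S6_S235_S236P",), "k9f2",
          modifiers=("S6K_T389P",)),
        R("s6_dephos", ("S6_S235_S236P",), ("S6",), "k9b2"),
    ]
    return ReactionNetwork(reactions=reactions, params=p)


def relax_to_steady_state(cstate0, p: CellularParams, INS_A: float = 0.0,
                          t_max: float = 50_000.0,
                          rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """Integrate the cascade at fixed INS_A until it settles.

    Used to compute the fasting (unstimulated, INS_A = 0) initial cellular
    state of a condition preset and the stimulated steady states probed in
    dose-response tests.
    """
    from scipy.integrate import solve_ivp

    y0 = cstate0.as_array() if isinstance(cstate0, CellularState) else \
        np.asarray(cstate0, dtype=float)
    sol = solve_ivp(lambda t, y: cellular_rhs(y, INS_A, p),
                    (0.0, t_max), y0, method="BDF", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"steady-state relaxation failed: {sol.message}")
    return np.clip(sol.y[:, -1], 0.0, None)


# ---------------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------------

def to_sbml(network: ReactionNetwork, model_id: str = "adipocyte_signaling",
            INS_A: float = 0.0) -> str:
    """Serialize the reaction network as an SBML Level 3 Version 2 string.

    Species and rate-constant identifiers match the field's symbols; INS_A
    is exported as a (boundary) parameter so external simulators can drive
    it.  Kinetic laws are plain mass-action products with modifiers.
    """
    p = network.params
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" '
        'level="3" version="2">',
        f'  <model id="{model_id}" timeUnits="minute">',
        '    <listOfCompartments>',
        '      <compartment id="cell" constant="true" size="1"/>',
        '    </listOfCompartments>',
        '    <listOfSpecies>',
    ]
    for sp in CELLULAR_STATE_NAMES:
        lines.append(f'      <species id="{sp}" compartment="cell" '
                     'hasOnlySubstanceUnits="true" boundaryCondition="false" '
                     'constant="false"/>')
    lines.append('    </listOfSpecies>')
    lines.append('    <listOfParameters>')
    seen = set()
    for rxn in network.reactions:
        if rxn.rate_constant not in seen:
            seen.add(rxn.rate_constant)
            lines.append(f'      <parameter id="{rxn.rate_constant}" '
                         f'value="{getattr(p, rxn.rate_constant)!r}" '
                         'constant="true"/>')
    lines.append(f'      <parameter id="kfb" value="{p.kfb!r}" constant="true"/>')
    lines.append(f'      <parameter id="INS_A" value="{INS_A!r}" constant="false"/>')
    lines.append('    </listOfParameters>')
    lines.append('    <listOfReactions>')
    for rxn in network.reactions:
        lines.append(f'      <reaction id="{rxn.name}" reversible="false">')
        lines.append('        <listOfReactants>')
        for sp in rxn.reactants:
            lines.append(f'          <speciesReference species="{sp}" '
                         'stoichiometry="1" constant="true"/>')
        lines.append('        </listOfReactants>')
        lines.append('        <listOfProducts>')
        for sp in rxn.products:
            lines.append(f'          <speciesReference species="{sp}" '
                         'stoichiometry="1" constant="true"/>')
        lines.append('        </listOfProducts>')
        if rxn.modifiers:
            lines.append('        <listOfModifiers>')
            for sp in rxn.modifiers:
                lines.append(f'          <modifierSpeciesReference species="{sp}"/>')
            lines.append('        </listOfModifiers>')
        factors = [rxn.rate_constant, *rxn.reactants, *rxn.modifiers]
        if rxn.insulin_driven:
            factors.append("INS_A")
        if rxn.kfb_scaled:
            factors.append("kfb")
        math_body = "\n".join(
            f'              <ci> {f} </ci>' for f in factors)
        lines.append(
            '        <kineticLaw>\n'
            '          <math xmlns="http://www.w3.org/1998/Math/MathML">\n'
            '            <apply>\n'
            '              <times/>\n'
            f'{math_body}\n'
            '            </apply>\n'
            '          </math>\n'
            '        </kineticLaw>')
        lines.append('      </reaction>')
    lines.append('    </listOfReactions>')
    lines.append('  </model>')
    lines.append('</sbml>')
    return "\n".join(lines)
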