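"""Reduced reaction network of cellular glucose catabolism.

The network lumps glycolysis and mitochondrial metabolism into seven
mass-action-like reactions over eight dynamic species:

====  ============================  =============================================
id    reaction                      net rate law
====  ============================  =============================================
R1    Glu_ex -> Glu                 k_in * Glu_ex * (Capacity_G - Glu)
R2    Glu <-> Pyr                   kf_1 * Glu * f(dose) - kr_1 * Pyr
R3    Pyr <-> Lac                   kf_2 * Pyr - kr_2 * Lac
R4    Lac <-> Lac_ex                kf_3 * Lac - kr_3 * Lac_ex
R5    Pyr <-> TCA                   kf_4 * Pyr * (Capacity_M - TCA) - kr_4 * TCA
R6    TCA -> OxPP                   kf_5 * TCA * (1 - oligo * i2)
R7    TCA -> CellComponents         kf_6 * TCA
====  ============================  =============================================

with the drug-modulation factor ``f = max(0, 1 + oligo*i2 - dg2*i1)`` on the
forward leg of R2 only.  ``Capacity_G`` and ``Capacity_M`` are constant
boundary quantities (transport capacities), not state variables: every
reaction transfers material 1:1, so the total over the eight species is
conserved along any trajectory.

Concentrations are carried in micromolar, time in minutes; rate constants are
kept numerically as model units without dimensional analysis of the composite
capacity terms.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "STOICHIOMETRY",
    "InvalidParameterError",
    "ModulatorDose",
    "ParameterSet",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "initial_state",
    "modulation_factor",
    "preset",
    "reaction_fluxes",
    "rhs",
]

#: Frozen ordering of the dynamic species; every state vector, trajectory
#: column block and serialization uses exactly this order.
SPECIES: tuple[str, ...] = (
    "Glu_ex",
    "Glu",
    "Pyr",
    "Lac",
    "Lac_ex",
    "TCA",
    "OxPP",
    "CellComponents",
)

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

#: 8 species x 7 reactions; entries in {-1, 0, +1}.  Each column sums to zero
#: over the dynamic species (1:1 mass transfer), the basis of conservation.
STOICHIOMETRY = np.array(
    [
        # R1  R2  R3  R4  R5  R6  R7
        [-1,  0,  0,  0,  0,  0,  0],   # Glu_ex
        [+1, -1,  0,  0,  0,  0,  0],   # Glu
        [ 0, +1, -1,  0, -1,  0,  0],   # Pyr
        [ 0,  0, +1, -1,  0,  0,  0],   # Lac
        [ 0,  0,  0, +1,  0,  0,  0],   # Lac_ex
        [ 0,  0,  0,  0, +1, -1, -1],   # TCA
        [ 0,  0,  0,  0,  0, +1,  0],   # OxPP
        [ 0,  0,  0,  0,  0,  0, +1],   # CellComponents
    ],
    dtype=float,
)


class InvalidParameterError(ValueError):
    """A kinetic parameter, capacity or dose violates its invariant."""


class PresetLookupError(KeyError):
    """Unknown cell-line preset name."""


@dataclass(frozen=True)
class ModulatorDose:
    """Dimensionless drug doses applied for a whole run.

    ``oligo`` is the ATP-synthase inhibitor oligomycin, which *inhibits* the
    TCA->OxPP drain (R6) and *stimulates* glycolysis (R2) through the same
    sensitivity parameter ``i2``.  ``dg2`` is the competitive glycolysis
    inhibitor 2-deoxyglucose acting subtractively on R2 via ``i1``.  The
    working dose range of the model is 0-10 units.
    """

    oligo: float = 0.0
    dg2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("oligo", "dg2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"dose {name!r} must be finite and >= 0, got {v!r}")


# Canonical key order used by the flat TOML serialization (table naming).
_TOML_KEYS = (
    "k_in", "kf_1", "kr_1", "kf_2", "kr_2", "kf_3", "kr_3",
    "kf_4", "kr_4", "kf_5", "kf_6", "i1", "i2",
    "Capacity_G", "Capacity_M", "Glu_ex",
)


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants, capacities and the initial extracellular glucose.

    Attributes
    ----------
    k_in : float
        Glucose-uptake rate constant (min^-1 conc^-1), reaction R1.
    kf_1 ... kf_6, kr_1 ... kr_4 : float
        Forward / reverse rate constants of reactions R2-R7.
    i1 : float
        2-deoxyglucose inhibition rate (per dose unit), acting on R2.
    i2 : float
        Oligomycin stimulation/inhibition rate; one shared parameter acting
        at both R2 (stimulation) and R6 (inhibition).
    Capacity_G, Capacity_M : float
        Glycolytic and mitochondrial capacities (conc units); constant
        boundary quantities throttling R1 and R5.
    glu_ex0 : float
        Initial extracellular glucose (uM); every other species starts at 0.
    compartment_volumes : tuple
        (media, cell, mitochondria); fixed at 1 and excluded from the ODEs.
    """

    k_in: float = 0.00012
    kf_1: float = 1.0
    kr_1: float = 0.01
    kf_2: float = 1.0
    kr_2: float = 0.1
    kf_3: float = 1.0
    kr_3: float = 0.1
    kf_4: float = 0.1
    kr_4: float = 1.0
    kf_5: float = 1.0
    kf_6: float = 1.0
    i1: float = 0.1
    i2: float = 0.1
    Capacity_G: float = 500.0
    Capacity_M: float = 50.0
    glu_ex0: float = 20000.0
    compartment_volumes: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _TOML_KEYS:
            v = getattr(self, "glu_ex0" if name == "Glu_ex" else name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"parameter {name!r} must be finite and >= 0, got {v!r}")
        if tuple(self.compartment_volumes) != (1.0, 1.0, 1.0):
            raise InvalidParameterError(
                "compartment_volumes are fixed at (1, 1, 1) in this model, "
                f"got {self.compartment_volumes!r}"
            )

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the named fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- flat key/value (TOML) interchange ---------------------------------

    def to_dict(self) -> dict[str, float]:
        """Flat mapping with the canonical field names (``Glu_ex`` = glu_ex0)."""
        d = {k: getattr(self, k) for k in _TOML_KEYS if k != "Glu_ex"}
        d["Glu_ex"] = self.glu_ex0
        return d

    def to_toml(self) -> str:
        return "".join(f"{k} = {v!r}\n" for k, v in self.to_dict().items())

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        unknown = set(d) - set(_TOML_KEYS)
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        kw = {k: float(v) for k, v in d.items() if k != "Glu_ex"}
        if "Glu_ex" in d:
            kw["glu_ex0"] = float(d["Glu_ex"])
        return cls(**kw)

    @classmethod
    def from_toml(cls, text: str) -> "ParameterSet":
        return cls.from_dict(tomllib.loads(text))


# -- cell-line presets (published optimized values) -------------------------

_A549 = ParameterSet()
PRESETS: dict[str, ParameterSet] = {
    "A549": _A549,
    # monkey kidney line: slower uptake, stronger lactate re-import
    "LLCMK2": _A549.replace(k_in=0.0001, kr_3=0.2),
    # hepatocellular line: lower capacities, oligomycin-insensitive
    "HepG2": _A549.replace(k_in=0.0001, Capacity_G=350.0, Capacity_M=40.0, i2=0.01),
}


def preset(cell_line: str) -> ParameterSet:
    """Optimized parameter set for one of the three characterized cell lines."""
    try:
        return PRESETS[cell_line]
    except KeyError:
        raise PresetLookupError(
            f"unknown cell line {cell_line!r}; valid names: {sorted(PRESETS)}"
        ) from None


def initial_state(params: ParameterSet) -> np.ndarray:
    """Assay initial condition: everything zero except extracellular glucose."""
    y0 = np.zeros(len(SPECIES))
    y0[0] = params.glu_ex0
    return y0


def modulation_factor(params: ParameterSet, dose: ModulatorDose) -> float:
    """Drug factor on the forward leg of R2, clamped at zero from below.

    The printed law ``1 + oligo*i2 - dg2*i1`` turns negative for doses beyond
    the 0-10 working range; a negative factor would reverse the enzyme, so it
    is floored at 0.  Within the published dose range with i1 = 0.1 the clamp
    is inactive.
    """
    return max(0.0, 1.0 + dose.oligo * params.i2 - dose.dg2 * params.i1)


@dataclass(frozen=True)
class Reaction:
    rid: str
    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool
    rate: Callable[[np.ndarray], float] = field(repr=False, compare=False)


@dataclass(frozen=True)
class ReactionNetwork:
    """The seven reactions with rate evaluators closed over a parameter set."""

    reactions: tuple[Reaction, ...]
    stoichiometry: np.ndarray
    params: ParameterSet
    dose: ModulatorDose

    def fluxes(self, state: np.ndarray) -> np.ndarray:
        return np.array([r.rate(state) for r in self.reactions])


def build_network(
    params: ParameterSet, dose: ModulatorDose | None = None
) -> ReactionNetwork:
    """Assemble the 7-reaction network for a parameter set and dose.

    Passing no dose is identical to passing ``ModulatorDose(0, 0)``.
    """
    params.validate()
    d = ModulatorDose() if dose is None else dose
    p = params
    f = modulation_factor(p, d)
    oligo_brake = 1.0 - d.oligo * p.i2

    defs = [
        ("R1", "glucose uptake", ("Glu_ex",), ("Glu",), False,
         lambda y: p.k_in * y[0] * (p.Capacity_G - y[1])),
        ("R2", "glycolysis (Glu <-> Pyr)", ("Glu",), ("Pyr",), True,
         lambda y: p.kf_1 * y[1] * f - p.kr_1 * y[2]),
        ("R3", "lactate production (Pyr <-> Lac)", ("Pyr",), ("Lac",), True,
         lambda y: p.kf_2 * y[2] - p.kr_2 * y[3]),
        ("R4", "lactate export (Lac <-> Lac_ex)", ("Lac",), ("Lac_ex",), True,
         lambda y: p.kf_3 * y[3] - p.kr_3 * y[4]),
        ("R5", "mitochondrial uptake (Pyr <-> TCA)", ("Pyr",), ("TCA",), True,
         lambda y: p.kf_4 * y[2] * (p.Capacity_M - y[5]) - p.kr_4 * y[5]),
        ("R6", "oxidative phosphorylation drain", ("TCA",), ("OxPP",), False,
         lambda y: p.kf_5 * y[5] * oligo_brake),
        ("R7", "biosynthesis drain", ("TCA",), ("CellComponents",), False,
         lambda y: p.kf_6 * y[5]),
    ]
    reactions = tuple(Reaction(*d_) for d_ in defs)
    return ReactionNetwork(reactions, STOICHIOMETRY.copy(), p, d)


def reaction_fluxes(
    state: Sequence[float], params: ParameterSet, dose: ModulatorDose | None = None
) -> np.ndarray:
    """Net (forward - reverse) rate of each reaction, uM/min, order R1..R7."""
    y = np.asarray(state, dtype=float)
    if y.shape != (len(SPECIES),) or not np.all(np.isfinite(y)):
        raise ValueError(f"state must be a finite vector of {len(SPECIES)} species")
    d = ModulatorDose() if dose is None else dose
    p = params
    f = modulation_factor(p, d)
    return np.array([
        p.k_in * y[0] * (p.Capacity_G - y[1]),
        p.kf_1 * y[1] * f - p.kr_1 * y[2],
        p.kf_2 * y[2] - p.kr_2 * y[3],
        p.kf_3 * y[3] - p.kr_3 * y[4],
        p.kf_4 * y[2] * (p.Capacity_M - y[5]) - p.kr_4 * y[5],
        p.kf_5 * y[5] * (1.0 - d.oligo * p.i2),
        p.kf_6 * y[5],
    ])


def rhs(
    t: float,
    state: Sequence[float],
    params: ParameterSet,
    dose: ModulatorDose | None = None,
) -> np.ndarray:
    """ODE right-hand side, d(state)/dt in uM/min.

    Time-autonomous (``t`` is accepted for solver compatibility only).  The
    component form is written out so that the TCA drain is ``R5 - (R6 + R7)``:
    addition commutes bitwise, which keeps the system exactly symmetric under
    exchanging the two terminal sinks when ``kf_5 == kf_6`` and oligo is 0.
    """
    r1, r2, r3, r4, r5, r6, r7 = reaction_fluxes(state, params, dose)
    return np.array([
        -r1,            # Glu_ex
        r1 - r2,        # Glu
        r2 - r3 - r5,   # Pyr
        r3 - r4,        # Lac
        r4,             # Lac_ex
        r5 - (r6 + r7),  # TCA
        r6,             # OxPP
        r7,             # CellComponents
    ])
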