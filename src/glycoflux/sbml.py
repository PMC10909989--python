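"""SBML Level 3 Version 2 export/import of the metabolic model.

The document carries three unit compartments (media, cell, mitochondria),
the eight dynamic species, the two capacities as constant *boundary* species
(they appear in rate laws as flux throttles, never as consumed material),
two constant modulator species, the global kinetic parameters, and the seven
reactions with their rate laws in MathML.  Doses are constant over a run, so
modulation lives inside the kinetic laws rather than as events.

The species id for 2-deoxyglucose is ``DG2`` (SBML ids cannot start with a
digit); its display name is "2DG".
"""

from __future__ import annotations

import libsbml

from .model import (
    ModulatorDose,
    ParameterSet,
    ReactionNetwork,
    build_network,
)

__all__ = ["SBMLSchemaError", "export_sbml", "import_sbml"]


class SBMLSchemaError(ValueError):
    """The document is missing a required model element."""


_PARAMETER_IDS = (
    "k_in", "kf_1", "kr_1", "kf_2", "kr_2", "kf_3", "kr_3",
    "kf_4", "kr_4", "kf_5", "kf_6", "i1", "i2",
)

# species id -> (compartment, initial-amount source)
_SPECIES_LAYOUT = {
    "Glu_ex": "media",
    "Lac_ex": "media",
    "Glu": "cell",
    "Pyr": "cell",
    "Lac": "cell",
    "TCA": "mitochondria",
    "OxPP": "mitochondria",
    "CellComponents": "mitochondria",
}

_REACTIONS = (
    # id, reversible, reactants, products, modifiers, formula
    ("R1", False, ["Glu_ex"], ["Glu"], ["Capacity_G"],
     "k_in * Glu_ex * (Capacity_G - Glu)"),
    ("R2", True, ["Glu"], ["Pyr"], ["Oligomycin", "DG2"],
     "kf_1 * Glu * (1 + Oligomycin * i2 - DG2 * i1) - kr_1 * Pyr"),
    ("R3", True, ["Pyr"], ["Lac"], [],
     "kf_2 * Pyr - kr_2 * Lac"),
    ("R4", True, ["Lac"], ["Lac_ex"], [],
     "kf_3 * Lac - kr_3 * Lac_ex"),
    ("R5", True, ["Pyr"], ["TCA"], ["Capacity_M"],
     "kf_4 * Pyr * (Capacity_M - TCA) - kr_4 * TCA"),
    ("R6", False, ["TCA"], ["OxPP"], ["Oligomycin"],
     "kf_5 * TCA * (1 - Oligomycin * i2)"),
    ("R7", False, ["TCA"], ["CellComponents"], [],
     "kf_6 * TCA"),
)


def _check(obj, what: str):
    if obj is None:
        raise RuntimeError(f"libsbml failed to create {what}")
    return obj


def export_sbml(
    params: ParameterSet,
    dose: ModulatorDose | None = None,
    path: str | None = None,
) -> str:
    """Serialize the model to an SBML L3V2 string (optionally also to a file)."""
    params.validate()
    dose = ModulatorDose() if dose is None else dose

    doc = libsbml.SBMLDocument(3, 2)
    model = _check(doc.createModel(), "model")
    model.setId("glucose_catabolism_eca")
    model.setName("Rate-equation model of glucose catabolism driving extracellular acidification")

    for cid in ("media", "cell", "mitochondria"):
        c = _check(model.createCompartment(), f"compartment {cid}")
        c.setId(cid)
        c.setSize(1.0)
        c.setConstant(True)
        c.setSpatialDimensions(3)

    def add_species(sid, compartment, amount, boundary, constant, name=None):
        s = _check(model.createSpecies(), f"species {sid}")
        s.setId(sid)
        if name:
            s.setName(name)
        s.setCompartment(compartment)
        s.setInitialAmount(float(amount))
        s.setBoundaryCondition(boundary)
        s.setConstant(constant)
        s.setHasOnlySubstanceUnits(True)

    for sid, comp in _SPECIES_LAYOUT.items():
        init = params.glu_ex0 if sid == "Glu_ex" else 0.0
        add_species(sid, comp, init, boundary=False, constant=False)
    # capacities: constant boundary quantities throttling flux
    add_species("Capacity_G", "media", params.Capacity_G, boundary=True, constant=True)
    add_species("Capacity_M", "cell", params.Capacity_M, boundary=True, constant=True)
    # modulators: constant over a run
    add_species("Oligomycin", "media", dose.oligo, boundary=True, constant=True)
    add_species("DG2", "media", dose.dg2, boundary=True, constant=True, name="2DG")

    for pid in _PARAMETER_IDS:
        p = _check(model.createParameter(), f"parameter {pid}")
        p.setId(pid)
        p.setValue(float(getattr(params, pid)))
        p.setConstant(True)

    for rid, reversible, reactants, products, modifiers, formula in _REACTIONS:
        r = _check(model.createReaction(), f"reaction {rid}")
        r.setId(rid)
        r.setReversible(reversible)
        for sid in reactants:
            ref = _check(r.createReactant(), f"{rid} reactant {sid}")
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for sid in products:
            ref = _check(r.createProduct(), f"{rid} product {sid}")
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for sid in modifiers:
            ref = _check(r.createModifier(), f"{rid} modifier {sid}")
            ref.setSpecies(sid)
        law = _check(r.createKineticLaw(), f"{rid} kinetic law")
        math = libsbml.parseL3Formula(formula)
        if math is None:
            raise RuntimeError(f"could not parse rate law for {rid}: {formula}")
        law.setMath(math)

    text = libsbml.writeSBMLToString(doc)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def import_sbml(source: str) -> tuple[ParameterSet, ReactionNetwork, ModulatorDose]:
    """Reconstruct parameters, network and dose from an exported document.

    ``source`` may be a path or the document text.  Unknown extra elements
    are ignored; missing required species, parameters or reactions raise
    :class:`SBMLSchemaError` naming the element.
    """
    if "<sbml" in source:
        doc = libsbml.readSBMLFromString(source)
    else:
        doc = libsbml.readSBMLFromFile(source)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLSchemaError(f"unreadable SBML document: {err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise SBMLSchemaError("document has no model element")

    def species_amount(sid: str) -> float:
        sp = model.getSpecies(sid)
        if sp is None:
            raise SBMLSchemaError(f"missing species {sid!r}")
        return float(sp.getInitialAmount())

    for sid in _SPECIES_LAYOUT:
        if model.getSpecies(sid) is None:
            raise SBMLSchemaError(f"missing species {sid!r}")
    for rid, *_ in _REACTIONS:
        if model.getReaction(rid) is None:
            raise SBMLSchemaError(f"missing reaction {rid!r}")

    values = {}
    for pid in _PARAMETER_IDS:
        p = model.getParameter(pid)
        if p is None:
            raise SBMLSchemaError(f"missing parameter {pid!r}")
        values[pid] = float(p.getValue())

    params = ParameterSet(
        **values,
        Capacity_G=species_amount("Capacity_G"),
        Capacity_M=species_amount("Capacity_M"),
        glu_ex0=species_amount("Glu_ex"),
    )
    dose = ModulatorDose(
        oligo=species_amount("Oligomycin") if model.getSpecies("Oligomycin") else 0.0,
        dg2=species_amount("DG2") if model.getSpecies("DG2") else 0.0,
    )
    return params, build_network(params, dose), dose
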