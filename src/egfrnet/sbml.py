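"""SBML Level 3 export of reaction-network models.

Writes a self-contained SBML L3V2 document: two compartments (membrane,
cytosol), one species entry per model species, one global parameter per
named rate constant, and one reaction per row with its mass-action kinetic
law in MathML (``kf * r1 * r2`` or ``kf * r1 * r2 - kr * p1 * p2`` for
reversible rows).  Import is out of scope.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from collections import Counter

from .network import Law, Model

__all__ = ["export_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(name: str) -> str:
    """Map a species/parameter name to a valid SBML SId."""
    out = []
    for ch in name:
        out.append(ch if ch.isalnum() or ch == "_" else "_")
    sid = "".join(out)
    return sid if sid[0].isalpha() or sid[0] == "_" else "s_" + sid


def _mathml_product(parent: ET.Element, k_sid: str, species: list[str]):
    if not species:
        ET.SubElement(parent, "ci").text = f" {k_sid} "
        return
    apply_ = ET.SubElement(parent, "apply")
    ET.SubElement(apply_, "times")
    ET.SubElement(apply_, "ci").text = f" {k_sid} "
    for s in species:
        ET.SubElement(apply_, "ci").text = f" {_sid(s)} "


def export_sbml(model: Model, model_id: str = "egfrnet_model") -> str:
    """Serialize a model as an SBML Level 3 Version 2 document string."""
    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", level="3", version="2")
    mdl = ET.SubElement(sbml, "model", id=_sid(model_id))

    comps = ET.SubElement(mdl, "listOfCompartments")
    for cid in ("membrane", "cytosol"):
        ET.SubElement(comps, "compartment", id=cid, constant="true",
                      spatialDimensions="3", size="1")

    sp_list = ET.SubElement(mdl, "listOfSpecies")
    for sp in model.species:
        ET.SubElement(
            sp_list, "species", id=_sid(sp.name), name=sp.name,
            compartment=sp.compartment,
            initialConcentration=repr(float(sp.initial_amount)),
            hasOnlySubstanceUnits="false",
            boundaryCondition="true" if "clamped" in sp.role_tags else "false",
            constant="false")

    par_list = ET.SubElement(mdl, "listOfParameters")
    for name, value in sorted(model.parameters.items()):
        ET.SubElement(par_list, "parameter", id=_sid(name), name=name,
                      value=repr(float(value)), constant="true")

    rx_list = ET.SubElement(mdl, "listOfReactions")
    for rxn in model.reactions:
        if rxn.law is Law.ENZYMATIC_TWO_STEP:
            raise ValueError(
                f"reaction {rxn.id}: expand enzymatic rows before export")
        rev = rxn.law is Law.MASS_ACTION_REVERSIBLE
        rx = ET.SubElement(rx_list, "reaction", id=_sid(rxn.id),
                           reversible="true" if rev else "false")
        if rxn.reactants:
            lst = ET.SubElement(rx, "listOfReactants")
            for s, n in Counter(rxn.reactants).items():
                ET.SubElement(lst, "speciesReference", species=_sid(s),
                              stoichiometry=str(n), constant="true")
        if rxn.products:
            lst = ET.SubElement(rx, "listOfProducts")
            for s, n in Counter(rxn.products).items():
                ET.SubElement(lst, "speciesReference", species=_sid(s),
                              stoichiometry=str(n), constant="true")
        kl = ET.SubElement(rx, "kineticLaw")
        math = ET.SubElement(kl, f"{{{_MATHML_NS}}}math")
        if rev:
            minus = ET.SubElement(math, "apply")
            ET.SubElement(minus, "minus")
            _mathml_product(minus, _sid(rxn.constants["kf"].name),
                            list(rxn.reactants))
            _mathml_product(minus, _sid(rxn.constants["kr"].name),
                            list(rxn.products))
        else:
            _mathml_product(math, _sid(rxn.constants["kf"].name),
                            list(rxn.reactants))

    ET.indent(sbml)
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(sbml, encoding="unicode"))
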