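"""SBML Level 2 export of the reaction network.

Writes the 19-reaction, two-compartment model as an SBML L2V4 document
with mass-action kinetic laws (Hill kinetics for transcription) so the
network can be inspected or re-simulated in standard SBML tooling.  A
small reader recovers the kinetic parameters and conserved totals from
files written by this exporter; importing arbitrary third-party SBML
models is out of scope.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .model import PM_PER_NM, ParameterSet, TotalConcentrations
from ._kinetics import STATE_NAMES

__all__ = ["export_sbml", "read_sbml_parameters"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_CYTOPLASM = ("R", "LR", "LRa", "LRaI", "S_c", "pS_c", "C_c", "D_c", "H_c", "m_c", "I")

# reaction id -> (reactants, products, modifiers, rate expression in infix)
_REACTIONS = {
    "r1_ligand_binding": (("L", "R"), ("LR",), (), "k2 * L * R"),
    "r2_ligand_unbinding": (("LR",), ("L", "R"), (), "k1 * LR"),
    "r3_receptor_activation": (("LR",), ("LRa",), (), "k3 * LR"),
    "r4_receptor_deactivation": (("LRa",), ("LR",), (), "k4 * LRa"),
    "r5_ismad_sequestration": (("LRa", "I"), ("LRaI",), (), "k5 * LRa * I"),
    "r6_ismad_release": (("LRaI",), ("LRa", "I"), (), "k6 * LRaI"),
    "r7_rsmad_phosphorylation": (("S_c",), ("pS_c",), ("LRa",), "k7 * LRa * S_c"),
    "r8a_import_S": (("S_c",), ("S_n",), (), "k8 * S_c"),
    "r8b_import_pS": (("pS_c",), ("pS_n",), (), "k8 * pS_c"),
    "r8c_import_C": (("C_c",), ("C_n",), (), "k8 * C_c"),
    "r9a_export_S": (("S_n",), ("S_c",), (), "k9 * S_n"),
    "r9b_export_pS": (("pS_n",), ("pS_c",), (), "k9 * pS_n"),
    "r9c_export_C": (("C_n",), ("C_c",), (), "k9 * C_n"),
    "r10a_homodimer_cyt": (("pS_c", "pS_c"), ("D_c",), (), "k10 * pS_c * pS_c"),
    "r10b_heterodimer_cyt": (("pS_c", "C_c"), ("H_c",), (), "k10 * pS_c * C_c"),
    "r10c_homodimer_nuc": (("pS_n", "pS_n"), ("D_n",), (), "k10 * pS_n * pS_n"),
    "r10d_heterodimer_nuc": (("pS_n", "C_n"), ("H_n",), (), "k10 * pS_n * C_n"),
    "r11a_homodimer_diss_cyt": (("D_c",), ("pS_c", "pS_c"), (), "k11 * D_c"),
    "r11b_heterodimer_diss_cyt": (("H_c",), ("pS_c", "C_c"), (), "k11 * H_c"),
    "r11c_homodimer_diss_nuc": (("D_n",), ("pS_n", "pS_n"), (), "k11 * D_n"),
    "r11d_heterodimer_diss_nuc": (("H_n",), ("pS_n", "C_n"), (), "k11 * H_n"),
    "r12a_dimer_import_D": (("D_c",), ("D_n",), (), "k12 * D_c"),
    "r12b_dimer_import_H": (("H_c",), ("H_n",), (), "k12 * H_c"),
    "r13_nuclear_dephosphorylation": (("pS_n",), ("S_n",), (), "k13 * pS_n"),
    "r14_15_transcription": ((), ("m_n",), ("H_n",), "hill(H_n)"),
    "r16_mrna_export": (("m_n",), ("m_c",), (), "k16 * m_n"),
    "r17_mrna_degradation": (("m_c",), (), (), "k17 * m_c"),
    "r18_translation": ((), ("I",), ("m_c",), "k18 * m_c"),
    "r19_ismad_degradation": (("I",), (), (), "k19 * I"),
}


def _mathml_times(parent, factors):
    apply = ET.SubElement(parent, "apply")
    ET.SubElement(apply, "times")
    for f in factors:
        ci = ET.SubElement(apply, "ci")
        ci.text = f
    return apply


def _mathml_hill(parent):
    # k14 * H_n^h / (k15^h + H_n^h)
    top = ET.SubElement(parent, "apply")
    ET.SubElement(top, "divide")
    num = ET.SubElement(top, "apply")
    ET.SubElement(num, "times")
    ET.SubElement(num, "ci").text = "k14"
    powe = ET.SubElement(num, "apply")
    ET.SubElement(powe, "power")
    ET.SubElement(powe, "ci").text = "H_n"
    ET.SubElement(powe, "ci").text = "h"
    den = ET.SubElement(top, "apply")
    ET.SubElement(den, "plus")
    p1 = ET.SubElement(den, "apply")
    ET.SubElement(p1, "power")
    ET.SubElement(p1, "ci").text = "k15"
    ET.SubElement(p1, "ci").text = "h"
    p2 = ET.SubElement(den, "apply")
    ET.SubElement(p2, "power")
    ET.SubElement(p2, "ci").text = "H_n"
    ET.SubElement(p2, "ci").text = "h"


def export_sbml(path, params: ParameterSet,
                totals: TotalConcentrations = TotalConcentrations(),
                ligand_pM: float = 200.0) -> None:
    """Write the model as an SBML Level 2 Version 4 document.

    Ligand is a constant boundary species.  Initial amounts follow the
    pre-equilibration convention: all receptor free, all Smad/Co-Smad
    cytoplasmic and unphosphorylated, everything else zero.
    """
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "2", "version": "4"})
    model = ET.SubElement(sbml, "model", {"id": "tgfb_smad_feedback",
                                          "name": "TGF-beta/Smad network with I-Smad feedback"})
    lc = ET.SubElement(model, "listOfCompartments")
    ET.SubElement(lc, "compartment", {"id": "cytoplasm", "size": "1"})
    ET.SubElement(lc, "compartment", {"id": "nucleus", "size": "1"})

    init = {"R": totals.R_tot, "S_c": totals.S_tot, "C_c": totals.C_tot}
    ls = ET.SubElement(model, "listOfSpecies")
    ET.SubElement(ls, "species", {
        "id": "L", "compartment": "cytoplasm",
        "initialConcentration": repr(ligand_pM / PM_PER_NM),
        "boundaryCondition": "true", "constant": "true"})
    for name in STATE_NAMES:
        comp = "cytoplasm" if name in _CYTOPLASM else "nucleus"
        ET.SubElement(ls, "species", {
            "id": name, "compartment": comp,
            "initialConcentration": repr(float(init.get(name, 0.0))),
            "boundaryCondition": "false", "constant": "false"})

    lp = ET.SubElement(model, "listOfParameters")
    for name, value in params.to_dict().items():
        ET.SubElement(lp, "parameter", {"id": name, "value": repr(value), "constant": "true"})
    for name, value in totals.to_dict().items():
        ET.SubElement(lp, "parameter", {"id": name, "value": repr(value), "constant": "true"})

    lr = ET.SubElement(model, "listOfReactions")
    for rid, (reactants, products, modifiers, rate) in _REACTIONS.items():
        rxn = ET.SubElement(lr, "reaction", {"id": rid, "reversible": "false"})
        if reactants:
            lre = ET.SubElement(rxn, "listOfReactants")
            seen: dict[str, ET.Element] = {}
            for s in reactants:
                if s in seen:
                    seen[s].set("stoichiometry", "2")
                else:
                    seen[s] = ET.SubElement(lre, "speciesReference",
                                            {"species": s, "stoichiometry": "1"})
        if products:
            lpr = ET.SubElement(rxn, "listOfProducts")
            seen = {}
            for s in products:
                if s in seen:
                    seen[s].set("stoichiometry", "2")
                else:
                    seen[s] = ET.SubElement(lpr, "speciesReference",
                                            {"species": s, "stoichiometry": "1"})
        if modifiers:
            lmo = ET.SubElement(rxn, "listOfModifiers")
            for s in modifiers:
                ET.SubElement(lmo, "modifierSpeciesReference", {"species": s})
        kl = ET.SubElement(rxn, "kineticLaw")
        math_el = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        if rate == "hill(H_n)":
            _mathml_hill(math_el)
        else:
            _mathml_times(math_el, rate.split(" * "))

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_sbml_parameters(path) -> tuple[ParameterSet, TotalConcentrations]:
    """Recover kinetic parameters and conserved totals from an exported file."""
    root = ET.parse(Path(path)).getroot()
    ns = {"s": SBML_NS}
    values = {}
    for p in root.findall(".//s:listOfParameters/s:parameter", ns):
        values[p.get("id")] = float(p.get("value"))
    tot_keys = {"R_tot", "S_tot", "C_tot"}
    totals = TotalConcentrations(**{k: values.pop(k) for k in tot_keys if k in values})
    return ParameterSet.from_dict(values), totals
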