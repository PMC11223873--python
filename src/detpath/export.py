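"""Interchange writers: SBML pathway documents, network JSON, query links.

SBML is Level 3 Version 1; compound roles and structures travel in a small
namespaced annotation element so a round-trip recovers species counts and
canonical keys.  Network JSON uses the common ``elements`` dialect (nodes
and edges with ``data`` payloads) consumed by browser graph viewers.
"""

from __future__ import annotations

import json
import re
from typing import Dict, List, Optional, Union
from urllib.parse import quote

import libsbml

from .chem import Compound
from .pathways import ChassisMetabolome, Pathway, ScopeGraph

__all__ = [
    "ANNOTATION_NS",
    "export_network_json",
    "export_sbml",
    "enzyme_query_links",
    "read_sbml_pathway",
]

ANNOTATION_NS = "urn:detpath:annotation"
_TOOL_VERSION = "detpath-0.1.0"


class UnclassifiedPathwayError(ValueError):
    """SBML export requires a classified pathway."""


def _sid(prefix: str, index: int) -> str:
    return f"{prefix}_{index:04d}"


def _check(value: int, message: str) -> None:
    if value not in (libsbml.LIBSBML_OPERATION_SUCCESS, 0):
        raise RuntimeError(f"libsbml error while {message}: {value}")


def export_sbml(
    pathway: Pathway,
    chassis: Optional[ChassisMetabolome] = None,
    model_id: str = "detectable_pathway",
) -> str:
    """Serialize a classified pathway as an SBML L3V1 document string.

    One species per pathway compound (role + InChI + SMILES in a namespaced
    annotation), one reaction per step with forward reactant/product links.
    Raises :class:`UnclassifiedPathwayError` when roles do not cover every
    compound — classify first.
    """
    if not pathway.is_classified:
        raise UnclassifiedPathwayError(
            "pathway has unclassified compounds; run classify_compounds() "
            "against a chassis metabolome before exporting"
        )
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    _check(model.setId(model_id), "setting model id")
    if chassis is not None:
        model.setName(f"{model_id} ({chassis.display_name})")

    comp = model.createCompartment()
    _check(comp.setId("c"), "setting compartment id")
    comp.setConstant(True)
    comp.setSize(1.0)

    key_to_sid: Dict[str, str] = {}
    for i, (key, compound) in enumerate(sorted(pathway.compounds().items())):
        sp = model.createSpecies()
        sid = _sid("M", i)
        key_to_sid[key] = sid
        _check(sp.setId(sid), "setting species id")
        sp.setName(key)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialAmount(0.0)
        annotation = (
            f'<detpath:compound xmlns:detpath="{ANNOTATION_NS}" '
            f'detpath:role="{pathway.roles[key]}" '
            f'detpath:smiles="{_xml_attr(key)}" '
            f'detpath:inchi="{_xml_attr(compound.inchi)}" '
            f'detpath:inchikey="{compound.inchikey}"/>'
        )
        _check(sp.setAnnotation(annotation), "annotating species")

    for i, step in enumerate(pathway.steps):
        rxn = model.createReaction()
        _check(rxn.setId(_sid("R", i)), "setting reaction id")
        rxn.setName(step.rule_id)
        rxn.setReversible(False)
        rxn.setFast(False)
        for reactant in step.reactants:
            ref = rxn.createReactant()
            ref.setSpecies(key_to_sid[reactant.canonical_key])
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        pref = rxn.createProduct()
        pref.setSpecies(key_to_sid[step.product.canonical_key])
        pref.setStoichiometry(1.0)
        pref.setConstant(True)
        annotation = (
            f'<detpath:reaction xmlns:detpath="{ANNOTATION_NS}" '
            f'detpath:rule_id="{step.rule_id}" '
            f'detpath:penalty_score="{step.penalty_score}" '
            f'detpath:diameter="{step.rule.diameter}"/>'
        )
        _check(rxn.setAnnotation(annotation), "annotating reaction")

    return libsbml.writeSBMLToString(doc)


def _xml_attr(value: str) -> str:
    return (
        value.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


_SMILES_ATTR_RE = re.compile(r'detpath:smiles="([^"]*)"')
_ROLE_ATTR_RE = re.compile(r'detpath:role="([^"]*)"')


def read_sbml_pathway(document: str) -> dict:
    """Parse an exported SBML document back into counts, keys and roles."""
    doc = libsbml.readSBMLFromString(document)
    model = doc.getModel()
    if model is None:
        raise ValueError("not a readable SBML document")
    species = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        text = sp.getAnnotationString() if sp.isSetAnnotation() else ""
        smiles_m = _SMILES_ATTR_RE.search(text)
        role_m = _ROLE_ATTR_RE.search(text)
        key = _xml_unattr(smiles_m.group(1)) if smiles_m else sp.getName()
        species.append(
            {
                "id": sp.getId(),
                "canonical_key": Compound(key).canonical_key,
                "role": role_m.group(1) if role_m else None,
            }
        )
    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        reactions.append(
            {
                "id": rxn.getId(),
                "rule_id": rxn.getName(),
                "n_reactants": rxn.getNumReactants(),
                "n_products": rxn.getNumProducts(),
            }
        )
    return {
        "n_species": model.getNumSpecies(),
        "n_reactions": model.getNumReactions(),
        "species": species,
        "reactions": reactions,
    }


def _xml_unattr(value: str) -> str:
    return (
        value.replace("&quot;", '"')
        .replace("&lt;", "<")
        .replace("&gt;", ">")
        .replace("&amp;", "&")
    )


def validate_sbml(document: str) -> List[str]:
    """Return consistency-check error strings (empty list = valid)."""
    doc = libsbml.readSBMLFromString(document)
    doc.checkConsistency()
    errors = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(err.getMessage())
    return errors


def export_network_json(obj: Union[ScopeGraph, Pathway, List[Pathway]]) -> str:
    """Serialize a scope graph or pathway(s) as elements-style network JSON.

    Compound nodes carry id/label/role, reaction nodes carry rule id and
    penalty score; edges link substrates to reactions and reactions to
    products.  Node count equals the compound + reaction count of the
    input.  Deterministic byte stream for a given input.
    """
    nodes: List[dict] = []
    edges: List[dict] = []

    def emit(compounds: Dict[str, Compound], steps, roles: Dict[str, str]):
        for key in sorted(compounds):
            nodes.append(
                {
                    "data": {
                        "id": key,
                        "label": compounds[key].id,
                        "kind": "compound",
                        "role": roles.get(key),
                    }
                }
            )
        for i, step in enumerate(steps):
            rid = f"rxn_{i:04d}_{step.rule_id}"
            nodes.append(
                {
                    "data": {
                        "id": rid,
                        "label": step.rule_id,
                        "kind": "reaction",
                        "rule_id": step.rule_id,
                        "score": step.penalty_score,
                    }
                }
            )
            for reactant in step.reactants:
                edges.append(
                    {
                        "data": {
                            "source": reactant.canonical_key,
                            "target": rid,
                            "rule_id": step.rule_id,
                        }
                    }
                )
            edges.append(
                {
                    "data": {
                        "source": rid,
                        "target": step.product.canonical_key,
                        "rule_id": step.rule_id,
                    }
                }
            )

    if isinstance(obj, ScopeGraph):
        roles = {
            obj.target.canonical_key: "target",
            obj.source.canonical_key: "effector",
        }
        steps = [obj.reactions[k] for k in sorted(obj.reactions, key=repr)]
        emit(obj.compounds, steps, roles)
    elif isinstance(obj, Pathway):
        emit(obj.compounds(), obj.steps, obj.roles)
    else:  # list of pathways — union of compounds and steps
        compounds: Dict[str, Compound] = {}
        roles: Dict[str, str] = {}
        steps = {}
        for pw in obj:
            for key, compound in pw.compounds().items():
                compounds.setdefault(key, compound)
            for key, role in pw.roles.items():
                roles.setdefault(key, role)
            for step in pw.steps:
                steps.setdefault(
                    (step.rule_id, step.reactant_keys, step.product.canonical_key),
                    step,
                )
        emit(compounds, [steps[k] for k in sorted(steps, key=repr)], roles)

    payload = {
        "format_version": "1.0",
        "generated_by": _TOOL_VERSION,
        "elements": {"nodes": nodes, "edges": edges},
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def enzyme_query_links(pathway: Pathway, base_url: str) -> List[str]:
    """One enzyme-selection query URL per pathway step.

    Each URL embeds the percent-encoded forward reaction string; no network
    call is made.
    """
    if not base_url:
        raise ValueError("base_url must be a non-empty URL prefix")
    links = []
    for step in pathway.steps:
        rsmiles = quote(step.forward_reaction_smiles(), safe="")
        links.append(f"{base_url.rstrip('/')}/?smarts={rsmiles}")
    return links
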