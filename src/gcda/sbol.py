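"""SBOL3-style design documents for genetic networks.

The exporter renders the hierarchical design description of the SBOL3 data
model — components, subcomponents, ordering constraints, interactions and a
model reference — as a plain JSON document with the same structure
(``document = "sbol3-json/1"``), which can be post-processed into RDF by any
SBOL3 tool chain.

Mapping: the network becomes the top-level component; each operator together
with its output gene products becomes a transcriptional-unit component of
type DNA with role ``engineered-region`` whose subcomponents (the operator
part followed by one CDS part per output) are kept in order by ``precedes``
constraints.  Each output gets a ``genetic-production`` interaction from its
unit to the species; each regulator (or supplement) input gets an
``inhibition`` or ``stimulation`` interaction on its target operator, the
type chosen from the operator's parameters.  Exactly one model reference
(source, language, framework) is attached.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from .network import (
    GeneticNetwork,
    NetworkError,
    Supplement,
    input_signs,
    validate_network,
)

__all__ = ["to_sbol", "validate_sbol_doc", "save_sbol"]

DOCUMENT_TAG = "sbol3-json/1"

_SIGN_TO_INTERACTION = {"repression": "inhibition", "activation": "stimulation"}


def to_sbol(net: GeneticNetwork, include_sequences: bool = False) -> dict:
    """Build the SBOL3-style document for a validated network.

    When ``include_sequences`` is set, product/part entries carry their
    nucleotide sequences; otherwise parts are emitted as placeholders to be
    filled in at the DNA-instantiation stage.
    """
    violations = validate_network(net)
    if violations:
        raise NetworkError("invalid network: " + "; ".join(violations))

    species = []
    for p in net.products:
        entry = {
            "id": p.name,
            "type": "Component",
            "types": ["Protein"],
            "role": p.kind,
        }
        if p.kind == "reporter" and p.signal_id:
            entry["signal_id"] = p.signal_id
        species.append(entry)
    for s in net.supplements:
        species.append(
            {"id": s.name, "type": "Component", "types": ["SimpleChemical"],
             "role": "supplement"}
        )

    units = []
    interactions = []
    for op in net.operators:
        sub_ids = [f"{op.name}_operator"]
        subcomponents = [
            {"id": sub_ids[0], "role": "operator", "types": ["DNA"],
             "placeholder": not include_sequences}
        ]
        for out in op.outputs:
            cds_id = f"{out.name}_cds"
            sub_ids.append(cds_id)
            part = {"id": cds_id, "role": "cds", "types": ["DNA"],
                    "placeholder": not (include_sequences and out.sequence)}
            if include_sequences and out.sequence:
                part["sequence"] = out.sequence
            subcomponents.append(part)
        constraints = [
            {"subject": a, "object": b, "restriction": "precedes"}
            for a, b in zip(sub_ids, sub_ids[1:])
        ]
        units.append(
            {
                "id": f"tu_{op.name}",
                "type": "Component",
                "types": ["DNA"],
                "role": "engineered-region",
                "operator_kind": op.kind,
                "subcomponents": subcomponents,
                "constraints": constraints,
            }
        )
        for out in op.outputs:
            interactions.append(
                {
                    "type": "genetic-production",
                    "template": f"tu_{op.name}",
                    "product": out.name,
                }
            )
        for inp, sign in zip(op.inputs, input_signs(op)):
            if sign is None:
                warnings.warn(
                    f"operator {op.name}: regulated and basal rates are equal "
                    f"for input {inp.name}; defaulting to stimulation"
                )
                itype = "stimulation"
            else:
                itype = _SIGN_TO_INTERACTION[sign]
            interactions.append(
                {
                    "type": itype,
                    "regulator": inp.name,
                    "target": f"tu_{op.name}",
                    "species_kind": "supplement" if isinstance(inp, Supplement)
                    else "regulator",
                }
            )

    return {
        "document": DOCUMENT_TAG,
        "network": {
            "id": net.name,
            "type": "Component",
            "types": ["FunctionalEntity"],
            "role": "genetic-network",
            "members": [u["id"] for u in units] + [s["id"] for s in species],
        },
        "species": species,
        "transcriptional_units": units,
        "interactions": interactions,
        "model": {
            "source": f"{net.name}.design.json",
            "language": "python",
            "framework": "continuous-ode",
        },
    }


def validate_sbol_doc(doc: dict) -> list[str]:
    """Structural checks; returns one message per violation (empty = valid)."""
    problems: list[str] = []
    if doc.get("document") != DOCUMENT_TAG:
        problems.append("missing or unknown document tag")
    model = doc.get("model")
    if not model or not all(k in model for k in ("source", "language", "framework")):
        problems.append("model reference must include source, language, framework")

    regulated = {
        i.get("regulator")
        for i in doc.get("interactions", [])
        if i.get("type") in ("inhibition", "stimulation")
    }
    for sp in doc.get("species", []):
        if sp.get("role") == "regulator" and sp["id"] not in regulated:
            problems.append(f"regulator {sp['id']} has no regulatory interaction")

    for unit in doc.get("transcriptional_units", []):
        sub_ids = [s["id"] for s in unit.get("subcomponents", [])]
        cons = unit.get("constraints", [])
        # `precedes` pairs must chain the subcomponents into one total order
        expected = {(a, b) for a, b in zip(sub_ids, sub_ids[1:])}
        got = {(c["subject"], c["object"]) for c in cons
               if c.get("restriction") == "precedes"}
        if expected != got:
            problems.append(f"unit {unit['id']}: part order is not a total order")
    return problems


def save_sbol(net: GeneticNetwork, path: str | Path,
              include_sequences: bool = False) -> None:
    doc = to_sbol(net, include_sequences=include_sequences)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
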