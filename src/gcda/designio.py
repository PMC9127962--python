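"""Load/save of genetic-network design documents (JSON).

The design document is the exchange format for high-level designs::

    {
      "format_version": "1",
      "name": "...",
      "products":  [{"name", "kind", "degradation_rate",
                     "init_concentration", "signal_id", "sequence"}, ...],
      "supplements": ["ahl1", ...],
      "operators": [{"name", "kind", "inputs", "outputs", "params"}, ...]
    }

Operator inputs/outputs are name references resolved against the declared
products (receiver inputs resolve against ``supplements``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .network import (
    GeneProduct,
    GeneticNetwork,
    HillParams1,
    HillParams2,
    NetworkError,
    Operator,
    Regulator,
    Reporter,
    SourceParams,
    Supplement,
)

__all__ = ["save_design", "load_design", "design_to_dict", "design_from_dict",
           "DesignFormatError", "FORMAT_VERSION"]

FORMAT_VERSION = "1"

_PARAM_TYPES = {"source": SourceParams, "hill1": HillParams1,
                "hill2": HillParams2, "receiver": HillParams1}


class DesignFormatError(ValueError):
    pass


def _product_to_dict(p: GeneProduct) -> dict:
    d = {
        "name": p.name,
        "kind": p.kind,
        "degradation_rate": p.degradation_rate,
        "init_concentration": p.init_concentration,
    }
    if p.signal_id is not None:
        d["signal_id"] = p.signal_id
    if p.sequence is not None:
        d["sequence"] = p.sequence
    return d


def design_to_dict(net: GeneticNetwork) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "name": net.name,
        "products": [_product_to_dict(p) for p in net.products],
        "supplements": [s.name for s in net.supplements],
        "operators": [
            {
                "name": op.name,
                "kind": op.kind,
                "inputs": [i.name for i in op.inputs],
                "outputs": [o.name for o in op.outputs],
                "params": dataclasses.asdict(op.params),
            }
            for op in net.operators
        ],
    }


def design_from_dict(doc: dict) -> GeneticNetwork:
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise DesignFormatError(
            f"unsupported design format_version {version!r} "
            f"(this reader supports {FORMAT_VERSION!r})"
        )
    products: list[GeneProduct] = []
    by_name: dict[str, GeneProduct] = {}
    for pd_ in doc.get("products", []):
        kind = pd_.get("kind", "regulator")
        cls = {"regulator": Regulator, "reporter": Reporter}.get(kind)
        if cls is None:
            raise DesignFormatError(f"unknown product kind {kind!r}")
        p = cls(
            name=pd_["name"],
            degradation_rate=pd_.get("degradation_rate", 0.0),
            init_concentration=pd_.get("init_concentration", 0.0),
            signal_id=pd_.get("signal_id"),
            sequence=pd_.get("sequence"),
        )
        products.append(p)
        by_name[p.name] = p
    supplements = {name: Supplement(name) for name in doc.get("supplements", [])}

    operators: list[Operator] = []
    for od in doc.get("operators", []):
        kind = od.get("kind")
        if kind not in _PARAM_TYPES:
            raise DesignFormatError(f"unknown operator kind {kind!r}")
        inputs = []
        for name in od.get("inputs", []):
            if kind == "receiver":
                inputs.append(supplements.setdefault(name, Supplement(name)))
            elif name in by_name:
                inputs.append(by_name[name])
            else:
                raise DesignFormatError(
                    f"operator {od.get('name')!r}: unresolved input {name!r}"
                )
        outputs = []
        for name in od.get("outputs", []):
            if name not in by_name:
                raise DesignFormatError(
                    f"operator {od.get('name')!r}: unresolved output {name!r}"
                )
            outputs.append(by_name[name])
        params = _PARAM_TYPES[kind](**od.get("params", {}))
        operators.append(
            Operator(name=od["name"], kind=kind, inputs=inputs,
                     outputs=outputs, params=params)
        )
    return GeneticNetwork(name=doc.get("name", "design"),
                          products=products, operators=operators)


def save_design(net: GeneticNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design_to_dict(net), indent=2) + "\n")


def load_design(path: str | Path) -> GeneticNetwork:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DesignFormatError(
            f"malformed design JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    return design_from_dict(doc)
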