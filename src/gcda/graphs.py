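"""Graph representations of genetic networks (networkx / GraphML / DOT).

Two views are provided: the full bipartite view with both operator and
product nodes (production edges operator->product, regulation edges
regulator->operator), and a compact operators-only view in which an edge
A->B means "a regulator produced by operator A is an input of operator B".
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .network import (
    GeneticNetwork,
    NetworkError,
    Supplement,
    classify_logic,
    input_signs,
    validate_network,
)

__all__ = ["to_graph", "write_graphml", "write_dot"]


def _logic_label(op) -> str:
    if op.kind in ("hill1", "hill2"):
        return classify_logic(op)
    return op.kind.upper()


def to_graph(net: GeneticNetwork, operators_only: bool = False) -> nx.DiGraph:
    """Directed regulation graph of a validated network.

    Nodes are added in declaration order (products first, then operators, then
    supplements) so serializations are deterministic.  Edge attribute
    ``edge_type`` is ``production`` or ``regulation``; regulation edges carry
    a ``sign`` attribute (``activation``/``repression``).
    """
    violations = validate_network(net)
    if violations:
        raise NetworkError("invalid network: " + "; ".join(violations))

    if operators_only:
        g = nx.DiGraph(name=net.name)
        for op in net.operators:
            g.add_node(op.name, node_type="operator", kind=op.kind,
                       logic=_logic_label(op))
        producer = {}
        for op in net.operators:
            for out in op.outputs:
                producer.setdefault(out.name, []).append(op.name)
        for op in net.operators:
            for inp, sign in zip(op.inputs, input_signs(op)):
                if isinstance(inp, Supplement):
                    continue
                for src in producer.get(inp.name, []):
                    g.add_edge(src, op.name, edge_type="regulation",
                               regulator=inp.name, sign=sign or "none")
        return g

    g = nx.DiGraph(name=net.name)
    for p in net.products:
        g.add_node(p.name, node_type="product", kind=p.kind)
    for op in net.operators:
        g.add_node(op.name, node_type="operator", kind=op.kind,
                   logic=_logic_label(op))
    for s in net.supplements:
        g.add_node(s.name, node_type="supplement", kind="supplement")
    for op in net.operators:
        for inp, sign in zip(op.inputs, input_signs(op)):
            g.add_edge(inp.name, op.name, edge_type="regulation",
                       sign=sign or "none")
        for out in op.outputs:
            g.add_edge(op.name, out.name, edge_type="production")
    return g


def write_graphml(g: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_dot(g: nx.DiGraph, path: str | Path) -> None:
    """Serialize to Graphviz DOT (written directly; no pydot dependency)."""
    lines = [f'digraph "{g.name or "network"}" {{']
    for node, attrs in g.nodes(data=True):
        shape = {"operator": "box", "product": "ellipse",
                 "supplement": "diamond"}.get(attrs.get("node_type"), "ellipse")
        label = attrs.get("logic", attrs.get("kind", ""))
        lines.append(
            f'  "{node}" [shape={shape}, label="{node}\\n{label}"];'
        )
    for u, v, attrs in g.edges(data=True):
        if attrs.get("edge_type") == "regulation":
            arrow = "tee" if attrs.get("sign") == "repression" else "vee"
            style = "dashed"
        else:
            arrow, style = "normal", "solid"
        lines.append(f'  "{u}" -> "{v}" [arrowhead={arrow}, style={style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
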