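"""Core abstraction for genetic networks.

A genetic network is a wired collection of *operators* and *gene products*.
An operator is a transfer function mapping input regulator concentrations to
output gene-product synthesis rates; the network-level synthesis operator is
the sum of the individual operator contributions.  Gene products decay with a
first-order degradation rate and are additionally diluted by cell growth, so
the deterministic dynamics are

    dp_i/dt = sum_k Phi_k,i(r) - (gamma_i + mu(t)) p_i

where ``Phi_k,i`` is operator *k*'s synthesis rate for product *i*, ``r`` the
vector of regulator concentrations, ``gamma_i`` the degradation rate and
``mu(t)`` the instantaneous growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "GeneProduct",
    "Regulator",
    "Reporter",
    "Supplement",
    "SourceParams",
    "HillParams1",
    "HillParams2",
    "Operator",
    "GeneticNetwork",
    "hill1_rate",
    "hill2_rate",
    "classify_logic",
    "input_signs",
    "operator_rate",
    "network_rhs",
    "validate_network",
    "NetworkError",
]


class NetworkError(ValueError):
    """Raised for invalid network structure or invalid operator evaluation."""


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------


@dataclass
class GeneProduct:
    """A molecular species expressed by the network.

    Parameters
    ----------
    name
        Unique identifier within a network.
    degradation_rate
        First-order degradation rate ``gamma`` (per hour, >= 0).
    init_concentration
        Initial concentration in molecules-per-cell equivalents (>= 0).
    signal_id
        Optional identifier linking a reporter to a measured signal; only
        valid for reporters.
    sequence
        Optional nucleotide sequence, carried through to design export.
    """

    name: str
    degradation_rate: float = 0.0
    init_concentration: float = 0.0
    signal_id: str | None = None
    sequence: str | None = None

    kind = "regulator"

    def __post_init__(self) -> None:
        if self.degradation_rate < 0:
            raise NetworkError(f"{self.name}: degradation_rate must be >= 0")
        if self.init_concentration < 0:
            raise NetworkError(f"{self.name}: init_concentration must be >= 0")
        if self.signal_id is not None and self.kind != "reporter":
            raise NetworkError(f"{self.name}: signal_id is only valid for reporters")


@dataclass
class Regulator(GeneProduct):
    """A gene product that feeds one or more operators."""

    kind = "regulator"


@dataclass
class Reporter(GeneProduct):
    """A measurable gene product (fluorescent-protein-like signal)."""

    kind = "reporter"

    def __post_init__(self) -> None:
        if self.signal_id is None:
            self.signal_id = self.name
        super().__post_init__()


@dataclass(frozen=True)
class Supplement:
    """An external chemical inducer held at a fixed, per-sample concentration.

    Supplements are assay conditions, not state variables: they are neither
    diluted nor consumed, and they enter the network only as inputs to
    receiver operators.
    """

    name: str


# ---------------------------------------------------------------------------
# operator parameter sets
# ---------------------------------------------------------------------------


@dataclass
class SourceParams:
    """Constitutive synthesis rate ``alpha`` (units/hour)."""

    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise NetworkError("source alpha must be >= 0")


@dataclass
class HillParams1:
    """One-input Hill transfer function parameters.

    ``alpha0``/``alpha1`` are the nonregulated and fully regulated synthesis
    rates, ``K`` the switching concentration, and ``n`` the cooperativity.
    ``alpha0 > alpha1`` gives NOT logic, ``alpha0 < alpha1`` a buffer.
    """

    alpha0: float
    alpha1: float
    K: float
    n: float

    def __post_init__(self) -> None:
        if self.alpha0 < 0 or self.alpha1 < 0:
            raise NetworkError("hill1 synthesis rates must be >= 0")
        if self.K <= 0:
            raise NetworkError("hill1 K must be > 0")
        if self.n <= 0:
            raise NetworkError("hill1 n must be > 0")


@dataclass
class HillParams2:
    """Two-input Hill transfer function parameters (two promoters in tandem).

    ``alpha0`` is the nonregulated rate, ``alpha1``/``alpha2`` the rates under
    regulation by input 1 / input 2 alone, and ``alpha3`` the jointly
    regulated rate.  ``K1``, ``K2``, ``n1``, ``n2`` are per-input switching
    concentrations and cooperativities.
    """

    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: float
    K1: float
    K2: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if min(self.alpha0, self.alpha1, self.alpha2, self.alpha3) < 0:
            raise NetworkError("hill2 synthesis rates must be >= 0")
        if self.K1 <= 0 or self.K2 <= 0:
            raise NetworkError("hill2 K1, K2 must be > 0")
        if self.n1 <= 0 or self.n2 <= 0:
            raise NetworkError("hill2 n1, n2 must be > 0")


OperatorParams = Union[SourceParams, HillParams1, HillParams2]

#: expected (arity, params class, input species class) per operator kind
_OPERATOR_KINDS: dict[str, tuple[int, type, type | None]] = {
    "source": (0, SourceParams, None),
    "hill1": (1, HillParams1, Regulator),
    "hill2": (2, HillParams2, Regulator),
    "receiver": (1, HillParams1, Supplement),
}


@dataclass
class Operator:
    """A transfer function from input species to output synthesis rates.

    An operator abstracts the DNA implementation (promoters plus upstream
    elements and RBSs) of a regulated expression unit.  All outputs of one
    operator are synthesized at the same rate.  Kinds:

    - ``source``: zero inputs, constitutive rate ``alpha``;
    - ``hill1``: one regulator input, one-input Hill function;
    - ``hill2``: two regulator inputs, two-input Hill function;
    - ``receiver``: one *supplement* input, one-input Hill function of the
      external inducer concentration.
    """

    name: str
    kind: str
    inputs: list[Regulator | Supplement]
    outputs: list[GeneProduct]
    params: OperatorParams

    def __post_init__(self) -> None:
        if self.kind not in _OPERATOR_KINDS:
            raise NetworkError(f"{self.name}: unknown operator kind {self.kind!r}")
        arity, params_cls, input_cls = _OPERATOR_KINDS[self.kind]
        if len(self.inputs) > 2:
            raise NetworkError(
                f"{self.name}: operators support at most two inputs "
                f"(got {len(self.inputs)})"
            )
        if len(self.inputs) != arity:
            raise NetworkError(
                f"{self.name}: {self.kind} operator requires {arity} input(s), "
                f"got {len(self.inputs)}"
            )
        if not self.outputs:
            raise NetworkError(f"{self.name}: operator requires >= 1 output")
        if not isinstance(self.params, params_cls):
            raise NetworkError(
                f"{self.name}: {self.kind} operator requires {params_cls.__name__}"
            )
        if input_cls is not None:
            for inp in self.inputs:
                if not isinstance(inp, input_cls):
                    raise NetworkError(
                        f"{self.name}: {self.kind} input must be a "
                        f"{input_cls.__name__}, got {type(inp).__name__}"
                    )


# ---------------------------------------------------------------------------
# transfer function mathematics
# ---------------------------------------------------------------------------


def hill1_rate(r: float, params: HillParams1) -> float:
    """One-input Hill synthesis rate.

    ``(alpha0 + alpha1 (r/K)^n) / (1 + (r/K)^n)`` — equals ``alpha0`` at zero
    input, the midpoint ``(alpha0 + alpha1)/2`` at ``r = K``, and saturates at
    ``alpha1``.
    """
    if np.any(np.asarray(r) < 0):
        raise NetworkError("hill1_rate: input concentration must be >= 0")
    x = (r / params.K) ** params.n
    return (params.alpha0 + params.alpha1 * x) / (1.0 + x)


def hill2_rate(r1: float, r2: float, params: HillParams2) -> float:
    """Two-input Hill synthesis rate for two promoters in tandem.

    With ``x_i = (r_i/K_i)^n_i``:
    ``(alpha0 + alpha1 x1 + alpha2 x2 + alpha3 x1 x2) / (1 + x1 + x2 + x1 x2)``.
    The denominator factorizes as ``(1 + x1)(1 + x2)``, i.e. the two promoter
    occupancies are independent and couple only through the joint rate
    ``alpha3``.
    """
    if np.any(np.asarray(r1) < 0) or np.any(np.asarray(r2) < 0):
        raise NetworkError("hill2_rate: input concentrations must be >= 0")
    x1 = (r1 / params.K1) ** params.n1
    x2 = (r2 / params.K2) ** params.n2
    num = params.alpha0 + params.alpha1 * x1 + params.alpha2 * x2 + params.alpha3 * x1 * x2
    return num / (1.0 + x1 + x2 + x1 * x2)


def operator_rate(op: Operator, input_values: Sequence[float]) -> float:
    """Evaluate an operator's synthesis rate at the given input concentrations."""
    if op.kind == "source":
        return op.params.alpha
    if op.kind in ("hill1", "receiver"):
        return hill1_rate(input_values[0], op.params)
    return hill2_rate(input_values[0], input_values[1], op.params)


def classify_logic(op: Operator) -> str:
    """Discrete logic label induced by the parameter ordering.

    One-input: NOT if ``alpha0 > alpha1``, BUFFER if ``alpha0 < alpha1``,
    OTHER on a tie.  Two-input: NOR if ``alpha0`` strictly exceeds every
    regulated rate, else OTHER.
    """
    if op.kind == "hill1":
        p = op.params
        if p.alpha0 > p.alpha1:
            return "NOT"
        if p.alpha0 < p.alpha1:
            return "BUFFER"
        return "OTHER"
    if op.kind == "hill2":
        p = op.params
        if p.alpha0 > max(p.alpha1, p.alpha2, p.alpha3):
            return "NOR"
        return "OTHER"
    raise NetworkError(f"classify_logic: unsupported operator kind {op.kind!r}")


def input_signs(op: Operator) -> list[str | None]:
    """Regulatory sign of each input: 'activation', 'repression', or None (tie).

    For one input the sign compares the saturated rate ``alpha1`` with the
    basal rate ``alpha0``; for two inputs each promoter's singly regulated
    rate is compared with ``alpha0``.
    """
    if op.kind == "source":
        return []
    p = op.params
    if op.kind in ("hill1", "receiver"):
        pairs = [(p.alpha1, p.alpha0)]
    else:
        pairs = [(p.alpha1, p.alpha0), (p.alpha2, p.alpha0)]
    signs: list[str | None] = []
    for hi, lo in pairs:
        if hi > lo:
            signs.append("activation")
        elif hi < lo:
            signs.append("repression")
        else:
            signs.append(None)
    return signs


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass
class GeneticNetwork:
    """A named, wired collection of operators and gene products."""

    name: str
    products: list[GeneProduct] = field(default_factory=list)
    operators: list[Operator] = field(default_factory=list)

    # -- structure accessors -------------------------------------------------

    @property
    def regulators(self) -> list[Regulator]:
        return [p for p in self.products if p.kind == "regulator"]

    @property
    def reporters(self) -> list[Reporter]:
        return [p for p in self.products if p.kind == "reporter"]

    @property
    def supplements(self) -> list[Supplement]:
        seen: dict[str, Supplement] = {}
        for op in self.operators:
            for inp in op.inputs:
                if isinstance(inp, Supplement):
                    seen.setdefault(inp.name, inp)
        return list(seen.values())

    def product_index(self) -> dict[str, int]:
        return {p.name: i for i, p in enumerate(self.products)}

    def add_product(self, product: GeneProduct) -> GeneProduct:
        self.products.append(product)
        return product

    def add_operator(self, op: Operator) -> Operator:
        self.operators.append(op)
        return op

    @property
    def n_products(self) -> int:
        return len(self.products)

    def degradation_rates(self) -> np.ndarray:
        return np.array([p.degradation_rate for p in self.products], float)

    def initial_state(self) -> np.ndarray:
        return np.array([p.init_concentration for p in self.products], float)


def validate_network(net: GeneticNetwork) -> list[str]:
    """Check all structural invariants; return one message per violation.

    An empty list means the network is valid.  Checked: unique product and
    operator names, every operator input/output resolving to a declared
    product (or a supplement placeholder), per-kind input arity and types,
    and the two-input limit.
    """
    violations: list[str] = []
    names = [p.name for p in net.products]
    for name in sorted({n for n in names if names.count(n) > 1}):
        violations.append(f"duplicate product name: {name}")
    op_names = [o.name for o in net.operators]
    for name in sorted({n for n in op_names if op_names.count(n) > 1}):
        violations.append(f"duplicate operator name: {name}")

    declared = set(names)
    for op in net.operators:
        if len(op.inputs) > 2:
            violations.append(f"operator {op.name}: more than two inputs")
        arity = _OPERATOR_KINDS.get(op.kind, (None,))[0]
        if arity is not None and len(op.inputs) != arity:
            violations.append(
                f"operator {op.name}: {op.kind} requires {arity} input(s)"
            )
        for inp in op.inputs:
            if isinstance(inp, Supplement):
                continue
            if inp.name not in declared:
                violations.append(
                    f"operator {op.name}: unresolved input reference {inp.name!r}"
                )
        for out in op.outputs:
            if out.name not in declared:
                violations.append(
                    f"operator {op.name}: unresolved output reference {out.name!r}"
                )
    return violations


def compile_rates(net: GeneticNetwork, supplements: Mapping[str, float] | None = None):
    """Build a fast callable mapping a state vector to per-product synthesis rates.

    Supplement inputs are frozen at the given concentrations (absent entries
    default to 0).  Returns ``synth(p) -> ndarray`` of length ``n_products``.
    """
    supplements = dict(supplements or {})
    idx = net.product_index()
    n = net.n_products
    plan: list[tuple[Operator, list[tuple[bool, float | int]], list[int]]] = []
    for op in net.operators:
        inspec: list[tuple[bool, float | int]] = []
        for inp in op.inputs:
            if isinstance(inp, Supplement):
                inspec.append((False, float(supplements.get(inp.name, 0.0))))
            else:
                inspec.append((True, idx[inp.name]))
        out_idx = [idx[o.name] for o in op.outputs]
        plan.append((op, inspec, out_idx))

    def synth(p) -> np.ndarray:
        rates = np.zeros(n)
        for op, inspec, out_idx in plan:
            vals = [p[ref] if is_state else ref for is_state, ref in inspec]
            rate = operator_rate(op, vals)
            for j in out_idx:
                rates[j] += rate
        return rates

    return synth


def network_rhs(
    net: GeneticNetwork,
    p: Sequence[float],
    mu: float,
    supplements: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Right-hand side of the network ODE: ``Psi(r) - (gamma_i + mu) p_i``."""
    p = np.asarray(p, float)
    if p.shape != (net.n_products,):
        raise NetworkError(
            f"state vector has shape {p.shape}, expected ({net.n_products},)"
        )
    if mu < 0:
        raise NetworkError("growth rate mu must be >= 0")
    synth = compile_rates(net, supplements)
    gamma = net.degradation_rates()
    return synth(p) - (gamma + mu) * p
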