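"""Programmatic builders for the example networks and assays.

Everything the tests and the acceptance checks consume is generated here, in
code: a constitutive source/reporter pair, receiver devices driven by
external inducers (acyl-homoserine-lactone-like supplements), one- and
two-input cascades for the staged characterization workflow, and the
positive-plus-delayed-negative-feedback oscillator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .growth import ConstantGrowth, GrowthProfile
from .network import (
    GeneticNetwork,
    HillParams1,
    HillParams2,
    Operator,
    Regulator,
    Reporter,
    SourceParams,
    Supplement,
)
from .simulation import Assay, Sample

__all__ = [
    "source_reporter_network",
    "receiver_network",
    "hill1_cascade_network",
    "hill2_network",
    "oscillator_network",
    "dose_response_assay",
    "RECEIVER1_PARAMS",
    "RECEIVER2_PARAMS",
    "NOR_PARAMS",
]

#: receiver devices used across the characterization examples
RECEIVER1_PARAMS = HillParams1(alpha0=0.1, alpha1=10.0, K=1.0, n=2.0)
RECEIVER2_PARAMS = HillParams1(alpha0=0.05, alpha1=8.0, K=2.0, n=1.5)
#: two-input NOR device composed downstream of the two receivers
NOR_PARAMS = HillParams2(alpha0=10.0, alpha1=0.3, alpha2=0.3, alpha3=0.3,
                         K1=1.0, K2=1.0, n1=2.0, n2=2.0)


def source_reporter_network(
    alpha: float = 10.0,
    gamma: float = 1.0,
    init: float = 0.0,
    name: str = "source_reporter",
) -> GeneticNetwork:
    """Constitutive source driving a single reporter."""
    rep = Reporter("GFP", degradation_rate=gamma, init_concentration=init)
    op = Operator("src", "source", [], [rep], SourceParams(alpha))
    return GeneticNetwork(name, products=[rep], operators=[op])


def receiver_network(
    supplement_name: str = "ahl1",
    params: HillParams1 = RECEIVER1_PARAMS,
    gamma_reporter: float = 1.0,
    signal: str = "YFP",
    name: str | None = None,
) -> GeneticNetwork:
    """Auxiliary network 1: inducer -> receiver -> reporter."""
    rep = Reporter(signal, degradation_rate=gamma_reporter)
    op = Operator(f"rec_{supplement_name}", "receiver",
                  [Supplement(supplement_name)], [rep], params)
    return GeneticNetwork(name or f"receiver_{supplement_name}",
                          products=[rep], operators=[op])


def hill1_cascade_network(
    hill1_params: HillParams1,
    receiver_params: HillParams1 = RECEIVER1_PARAMS,
    supplement_name: str = "ahl1",
    gamma_regulator: float = 1.0,
    gamma_reporter: float = 1.0,
    name: str = "hill1_cascade",
) -> GeneticNetwork:
    """Cascade: inducer -> receiver -> regulator -> one-input operator -> reporter."""
    reg = Regulator("regA", degradation_rate=gamma_regulator)
    rep = Reporter("RFP", degradation_rate=gamma_reporter)
    rec = Operator("rec", "receiver", [Supplement(supplement_name)], [reg],
                   receiver_params)
    op = Operator("gate", "hill1", [reg], [rep], hill1_params)
    return GeneticNetwork(name, products=[reg, rep], operators=[rec, op])


def hill2_network(
    hill2_params: HillParams2 = NOR_PARAMS,
    receiver1_params: HillParams1 = RECEIVER1_PARAMS,
    receiver2_params: HillParams1 = RECEIVER2_PARAMS,
    supplement_names: tuple[str, str] = ("ahl1", "ahl2"),
    gamma_regulators: tuple[float, float] = (1.0, 1.0),
    gamma_reporter: float = 1.0,
    name: str = "hill2_cascade",
) -> GeneticNetwork:
    """Auxiliary network 3: two receivers drive the two-input operator."""
    regA = Regulator("regA", degradation_rate=gamma_regulators[0])
    regB = Regulator("regB", degradation_rate=gamma_regulators[1])
    rep = Reporter("CFP", degradation_rate=gamma_reporter)
    rec1 = Operator("rec1", "receiver", [Supplement(supplement_names[0])],
                    [regA], receiver1_params)
    rec2 = Operator("rec2", "receiver", [Supplement(supplement_names[1])],
                    [regB], receiver2_params)
    gate = Operator("gate2", "hill2", [regA, regB], [rep], hill2_params)
    return GeneticNetwork(name, products=[regA, regB, rep],
                          operators=[rec1, rec2, gate])


def oscillator_network(name: str = "oscillator") -> GeneticNetwork:
    """Relaxation oscillator with positive and delayed negative feedback.

    Three operators: a two-input operator that is activated by regulator A
    (positive self-feedback, since the operator synthesizes A) and repressed
    by regulator C; and two activated one-input operators forming the delay
    line A -> B -> C that closes the negative loop.  Each operator also
    outputs its own fluorescent reporter (RFP, YFP, CFP).

    Parameters (chosen for robust sustained oscillation; arbitrary
    molecules-per-cell units): strong cooperative self-activation of A
    (n1 = 4) gated off by C (n2 = 4), with A degraded faster than the delay
    line so the positive loop switches quickly and the negative loop
    resets it.
    """
    A = Regulator("actA", degradation_rate=1.0, init_concentration=20.0)
    B = Regulator("relayB", degradation_rate=0.3)
    C = Regulator("repC", degradation_rate=0.3)
    rfp = Reporter("RFP", degradation_rate=1.0)
    yfp = Reporter("YFP", degradation_rate=1.0)
    cfp = Reporter("CFP", degradation_rate=1.0)

    op_ac = Operator(
        "op_AC", "hill2", [A, C], [A, rfp],
        HillParams2(alpha0=5.0, alpha1=60.0, alpha2=0.0, alpha3=0.0,
                    K1=12.0, K2=6.0, n1=4.0, n2=4.0),
    )
    op_b = Operator(
        "op_B", "hill1", [A], [B, yfp],
        HillParams1(alpha0=0.05, alpha1=4.0, K=12.0, n=2.0),
    )
    op_c = Operator(
        "op_C", "hill1", [B], [C, cfp],
        HillParams1(alpha0=0.05, alpha1=4.0, K=8.0, n=2.0),
    )
    return GeneticNetwork(
        name,
        products=[A, B, C, rfp, yfp, cfp],
        operators=[op_ac, op_b, op_c],
    )


def dose_response_assay(
    network: GeneticNetwork,
    doses: Sequence[dict[str, float]],
    duration: float = 10.0,
    interval: float = 0.5,
    growth: GrowthProfile | None = None,
    method: str = "ode",
    seed: int = 0,
    name: str = "dose_response",
) -> Assay:
    """One sample per dose combination, all sharing the network and growth."""
    growth = growth or ConstantGrowth(mu0=0.5)
    samples = [
        Sample(network, growth, dict(dose), name=f"{name}_s{i}")
        for i, dose in enumerate(doses)
    ]
    return Assay(samples, duration, interval, method=method, seed=seed, name=name)


def log_dose_series(lo: float = 0.01, hi: float = 100.0, n: int = 7,
                    include_zero: bool = True) -> list[float]:
    """Log-spaced inducer concentrations, optionally prepended with zero."""
    series = list(np.logspace(np.log10(lo), np.log10(hi), n))
    return ([0.0] + series) if include_zero else series
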