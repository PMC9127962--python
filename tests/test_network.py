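"""Transfer-function math, logic classification, RHS assembly, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcda.network import (
    GeneticNetwork,
    HillParams1,
    HillParams2,
    NetworkError,
    Operator,
    Regulator,
    Reporter,
    SourceParams,
    Supplement,
    classify_logic,
    hill1_rate,
    hill2_rate,
    input_signs,
    network_rhs,
    validate_network,
)

rates = st.floats(0.0, 100.0)
conc = st.floats(0.0, 1e4)
Ks = st.floats(1e-3, 1e3)
ns = st.floats(0.1, 8.0)


# ---------------------------------------------------------------------------
# hill transfer functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r, params, expected",
    [
        (0.0, HillParams1(1.0, 0.0, 1.0, 2.0), 1.0),  # zero input -> alpha0
        (2.0, HillParams1(0.0, 10.0, 2.0, 4.0), 5.0),  # half-maximal at r=K
        (10.0, HillParams1(2.0, 8.0, 1.0, 1.0), 82.0 / 11.0),
    ],
)
def test_hill1_rate_values(r, params, expected):
    assert hill1_rate(r, params) == pytest.approx(expected, rel=1e-12)


def test_hill1_rejects_negative_input():
    with pytest.raises(NetworkError):
        hill1_rate(-0.1, HillParams1(1.0, 2.0, 1.0, 2.0))


def test_hill2_zero_inputs_give_alpha0():
    p = HillParams2(3.0, 1.0, 2.0, 7.0, 1.0, 2.0, 2.0, 3.0)
    assert hill2_rate(0.0, 0.0, p) == pytest.approx(3.0)


def test_hill2_joint_saturation_limit():
    p = HillParams2(1.0, 2.0, 3.0, 7.0, 1.0, 1.0, 2.0, 2.0)
    r = 1e6
    assert hill2_rate(r, r, p) == pytest.approx(7.0, rel=1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rates, rates, rates, rates, Ks, Ks, ns, ns, conc)
def test_hill2_reduces_to_hill1_when_second_input_zero(
    a0, a1, a2, a3, K1, K2, n1, n2, r1
):
    p2 = HillParams2(a0, a1, a2, a3, K1, K2, n1, n2)
    p1 = HillParams1(a0, a1, K1, n1)
    assert hill2_rate(r1, 0.0, p2) == pytest.approx(hill1_rate(r1, p1), rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rates, rates, Ks, ns, st.lists(conc, min_size=2, max_size=8))
def test_hill1_monotone_and_bounded(a0, a1, K, n, rs):
    p = HillParams1(a0, a1, K, n)
    vals = [hill1_rate(r, p) for r in sorted(rs)]
    lo, hi = min(a0, a1), max(a0, a1)
    assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in vals)
    diffs = np.diff(vals)
    if a1 >= a0:
        assert np.all(diffs >= -1e-9)
    else:
        assert np.all(diffs <= 1e-9)


# ---------------------------------------------------------------------------
# logic classification
# ---------------------------------------------------------------------------


def _op1(a0, a1, K=1.0, n=2.0):
    reg = Regulator("r")
    out = Reporter("s")
    return Operator("o", "hill1", [reg], [out], HillParams1(a0, a1, K, n))


def _op2(a0, a1, a2, a3):
    r1, r2 = Regulator("r1"), Regulator("r2")
    out = Reporter("s")
    return Operator("o", "hill2", [r1, r2], [out],
                    HillParams2(a0, a1, a2, a3, 1.0, 1.0, 2.0, 2.0))


@pytest.mark.parametrize(
    "op, label",
    [
        (_op1(10.0, 1.0), "NOT"),
        (_op1(1.0, 10.0), "BUFFER"),
        (_op1(5.0, 5.0), "OTHER"),
        (_op2(10.0, 0.5, 0.5, 0.5), "NOR"),
        (_op2(1.0, 5.0, 0.5, 0.5), "OTHER"),
    ],
)
def test_classify_logic(op, label):
    assert classify_logic(op) == label


def test_classify_logic_rejects_source():
    src = Operator("s", "source", [], [Reporter("x")], SourceParams(1.0))
    with pytest.raises(NetworkError):
        classify_logic(src)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.01, 50), st.floats(0.01, 50), st.floats(0.1, 100))
def test_classify_invariant_to_common_alpha_scaling(a0, a1, factor):
    assert classify_logic(_op1(a0, a1)) == classify_logic(_op1(a0 * factor, a1 * factor))


def test_input_signs_mixed_two_input():
    op = _op2(5.0, 60.0, 0.0, 0.0)
    assert input_signs(op) == ["activation", "repression"]


# ---------------------------------------------------------------------------
# rhs assembly and validation
# ---------------------------------------------------------------------------


def test_rhs_steady_state_zero():
    rep = Reporter("s", degradation_rate=1.0)
    src = Operator("src", "source", [], [rep], SourceParams(10.0))
    net = GeneticNetwork("n", [rep], [src])
    assert network_rhs(net, [5.0], mu=1.0) == pytest.approx([0.0])


def test_rhs_origin_absorbing_when_sources_off():
    rep = Reporter("s", degradation_rate=1.0)
    src = Operator("src", "source", [], [rep], SourceParams(0.0))
    net = GeneticNetwork("n", [rep], [src])
    assert network_rhs(net, [0.0], mu=0.3) == pytest.approx([0.0])


def test_rhs_not_gate_at_switching_concentration():
    reg = Regulator("r", degradation_rate=0.0, init_concentration=2.0)
    rep = Reporter("s", degradation_rate=1.0)
    gate = Operator("g", "hill1", [reg], [rep], HillParams1(8.0, 2.0, 2.0, 3.0))
    net = GeneticNetwork("n", [reg, rep], [gate])
    p = np.array([2.0, 1.5])  # regulator pinned at K
    rhs = network_rhs(net, p, mu=0.5)
    assert rhs[1] == pytest.approx((8.0 + 2.0) / 2 - (1.0 + 0.5) * 1.5)


def test_rhs_shape_mismatch():
    net = GeneticNetwork("n", [Reporter("s")], [])
    with pytest.raises(NetworkError):
        network_rhs(net, [1.0, 2.0], mu=0.0)


def test_rhs_affine_in_state_for_fixed_inputs():
    """With operator inputs held external, rhs is affine in p (dilution term)."""
    rep1, rep2 = Reporter("s1", degradation_rate=0.7), Reporter("s2", degradation_rate=0.2)
    rec = Operator("rec", "receiver", [Supplement("ahl")], [rep1],
                   HillParams1(1.0, 9.0, 1.0, 2.0))
    src = Operator("src", "source", [], [rep2], SourceParams(4.0))
    net = GeneticNetwork("n", [rep1, rep2], [rec, src])
    sup = {"ahl": 2.0}
    p = np.array([3.0, 1.0])
    f0 = network_rhs(net, np.zeros(2), 0.4, sup)
    f1 = network_rhs(net, p, 0.4, sup)
    f2 = network_rhs(net, 2 * p, 0.4, sup)
    assert f2 - f0 == pytest.approx(2 * (f1 - f0))


def test_validate_oscillator_fixture_clean(oscillator):
    assert validate_network(oscillator) == []


def test_validate_reports_unresolved_reference():
    reg = Regulator("r")
    ghost = Reporter("X")
    op = Operator("o", "hill1", [reg], [ghost], HillParams1(1, 2, 1, 2))
    net = GeneticNetwork("n", [reg], [op])
    violations = validate_network(net)
    assert len(violations) == 1 and "X" in violations[0]


def test_three_input_operator_rejected():
    regs = [Regulator(f"r{i}") for i in range(3)]
    with pytest.raises(NetworkError, match="two inputs"):
        Operator("o", "hill2", regs, [Reporter("s")],
                 HillParams2(1, 1, 1, 1, 1, 1, 1, 1))


def test_operator_arity_enforced():
    with pytest.raises(NetworkError):
        Operator("o", "hill1", [], [Reporter("s")], HillParams1(1, 2, 1, 2))


def test_receiver_requires_supplement_input():
    with pytest.raises(NetworkError):
        Operator("o", "receiver", [Regulator("r")], [Reporter("s")],
                 HillParams1(1, 2, 1, 2))


def test_param_invariants():
    with pytest.raises(NetworkError):
        HillParams1(1.0, 1.0, 0.0, 2.0)  # K must be positive
    with pytest.raises(NetworkError):
        HillParams1(-1.0, 1.0, 1.0, 2.0)
    with pytest.raises(NetworkError):
        HillParams2(1, 1, 1, 1, 1.0, 1.0, 0.0, 1.0)
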