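"""Operator parameter recovery from self-generated kinetic data."""

import numpy as np
import pytest

from gcda.characterization import (
    DoseResponseDataset,
    InsufficientDesignError,
    NoDataError,
    assemble_dataset,
    characterize,
    fit_growth_profile,
    fit_hill1,
    fit_hill2,
    fit_receiver,
    fit_source,
    receiver_sse,
)
from gcda.datastore import DataStore
from gcda.examples import (
    NOR_PARAMS,
    RECEIVER1_PARAMS,
    RECEIVER2_PARAMS,
    dose_response_assay,
    hill1_cascade_network,
    hill2_network,
    log_dose_series,
    receiver_network,
)
from gcda.growth import ConstantGrowth, LogisticGrowth
from gcda.network import HillParams1
from gcda.simulation import run_assay


def _rel_errs(true, fitted, names):
    return {n: abs(getattr(fitted, n) - getattr(true, n)) / abs(getattr(true, n))
            for n in names}


def _dataset_from_assay(table, doses, signal, prefix):
    mapping = {}
    for i, d in enumerate(doses):
        mapping[f"{prefix}_s{i}"] = tuple(d[k] for k in sorted(d))
    return assemble_dataset(table, mapping, signal)


# ---------------------------------------------------------------------------
# source
# ---------------------------------------------------------------------------


def test_fit_source_recovers_alpha_noiseless(growth):
    times = np.linspace(0, 8, 17)
    g = 1.0 + 0.5
    obs = 10.0 / g * (1 - np.exp(-g * times))
    fit = fit_source(times, obs, gamma=1.0, growth=growth)
    assert fit.params.alpha == pytest.approx(10.0, rel=0.01)


def test_fit_source_zero_series(growth):
    fit = fit_source(np.linspace(0, 5, 11), np.zeros(11), 1.0, growth)
    assert fit.params.alpha == 0.0
    assert fit.identifiability_flags == {"alpha": False}


def test_fit_source_with_multiplicative_noise(growth):
    rng = np.random.default_rng(3)
    times = np.linspace(0, 8, 17)
    g = 1.5
    obs = 10.0 / g * (1 - np.exp(-g * times))
    noisy = obs * (1 + 0.05 * rng.standard_normal(len(obs)))
    fit = fit_source(times, noisy, gamma=1.0, growth=growth)
    assert fit.params.alpha == pytest.approx(10.0, rel=0.10)


# ---------------------------------------------------------------------------
# receiver
# ---------------------------------------------------------------------------


def test_fit_receiver_recovers_all_parameters(growth, receiver1_table,
                                              receiver1_doses):
    doses = [{"ahl1": c} for c in receiver1_doses]
    ds = _dataset_from_assay(receiver1_table, doses, "YFP", "rec1")
    fit = fit_receiver(ds, gamma=1.0, growth=growth)
    errs = _rel_errs(RECEIVER1_PARAMS, fit.params, ("alpha0", "alpha1", "K", "n"))
    assert max(errs.values()) < 0.05
    assert all(fit.identifiability_flags.values())
    assert fit.residual_sse <= 1e-6 * float(np.sum(ds.values**2))


def test_fit_receiver_flat_response_flags_K_n(growth):
    flat = HillParams1(5.0, 5.0, 1.0, 2.0)
    net = receiver_network("ahl1", flat, signal="YFP")
    doses = [{"ahl1": c} for c in [0.0, 0.1, 1.0, 10.0, 100.0]]
    table = run_assay(dose_response_assay(net, doses, duration=6.0,
                                          interval=0.5, growth=growth,
                                          name="flat"))
    ds = _dataset_from_assay(table, doses, "YFP", "flat")
    fit = fit_receiver(ds, gamma=1.0, growth=growth)
    assert fit.params.alpha0 == pytest.approx(5.0, rel=0.05)
    assert fit.params.alpha1 == pytest.approx(5.0, rel=0.05)
    assert not fit.identifiability_flags["K"]
    assert not fit.identifiability_flags["n"]


def test_fit_receiver_decreasing_response_is_not_type(growth):
    inv = HillParams1(10.0, 0.5, 1.0, 2.0)
    net = receiver_network("ahl1", inv, signal="YFP")
    doses = [{"ahl1": c} for c in [0.0, 0.03, 0.3, 1.0, 3.0, 30.0]]
    table = run_assay(dose_response_assay(net, doses, duration=8.0,
                                          interval=0.5, growth=growth,
                                          name="inv"))
    ds = _dataset_from_assay(table, doses, "YFP", "inv")
    fit = fit_receiver(ds, gamma=1.0, growth=growth)
    assert fit.params.alpha0 > fit.params.alpha1


def test_fit_receiver_requires_enough_concentrations(growth):
    ds = DoseResponseDataset(
        times=np.linspace(0, 5, 11),
        doses=[(0.0,), (1.0,), (2.0,)],
        values=np.ones((3, 11)),
        series_dose=[0, 1, 2],
    )
    with pytest.raises(InsufficientDesignError):
        fit_receiver(ds, 1.0, growth)


# ---------------------------------------------------------------------------
# one-input cascade
# ---------------------------------------------------------------------------


def test_fit_hill1_recovers_not_gate(growth):
    true = HillParams1(8.0, 0.2, 2.0, 2.0)
    net = hill1_cascade_network(true)
    doses = [{"ahl1": c} for c in log_dose_series(0.01, 100.0, 7)]
    table = run_assay(dose_response_assay(net, doses, duration=10.0,
                                          interval=0.5, growth=growth,
                                          name="cas"))
    ds = _dataset_from_assay(table, doses, "RFP", "cas")
    fit = fit_hill1(ds, RECEIVER1_PARAMS, 1.0, 1.0, growth)
    errs = _rel_errs(true, fit.params, ("alpha0", "alpha1", "K", "n"))
    assert max(errs.values()) < 0.10
    assert fit.params.alpha0 > fit.params.alpha1  # NOT-type stays NOT-type


def test_fit_hill1_buffer_sign(growth):
    true = HillParams1(0.2, 9.0, 1.5, 2.0)
    net = hill1_cascade_network(true)
    doses = [{"ahl1": c} for c in log_dose_series(0.01, 100.0, 6)]
    table = run_assay(dose_response_assay(net, doses, duration=10.0,
                                          interval=0.5, growth=growth,
                                          name="buf"))
    ds = _dataset_from_assay(table, doses, "RFP", "buf")
    fit = fit_hill1(ds, RECEIVER1_PARAMS, 1.0, 1.0, growth)
    assert fit.params.alpha1 > fit.params.alpha0


def test_fit_hill1_unreached_K_flagged(growth):
    """When the regulator never approaches K the switch point is unidentifiable."""
    true = HillParams1(8.0, 0.2, 2.0, 2.0)
    weak_receiver = HillParams1(0.001, 10.0, 1.0, 2.0)
    net = hill1_cascade_network(true, receiver_params=weak_receiver)
    doses = [{"ahl1": c} for c in [0.0, 0.001, 0.002, 0.005, 0.01]]
    table = run_assay(dose_response_assay(net, doses, duration=8.0,
                                          interval=0.5, growth=growth,
                                          name="weak"))
    ds = _dataset_from_assay(table, doses, "RFP", "weak")
    fit = fit_hill1(ds, weak_receiver, 1.0, 1.0, growth)
    assert not fit.identifiability_flags["K"]


# ---------------------------------------------------------------------------
# two-input cascade
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def nor_dataset(nor_grid_table):
    table, doses = nor_grid_table
    mapping = {f"nor_s{i}": (d["ahl1"], d["ahl2"]) for i, d in enumerate(doses)}
    return assemble_dataset(table, mapping, "CFP")


def test_fit_hill2_recovers_nor(growth, nor_dataset):
    fit = fit_hill2(nor_dataset, RECEIVER1_PARAMS, RECEIVER2_PARAMS,
                    1.0, 1.0, 1.0, growth)
    names = ("alpha0", "alpha1", "alpha2", "alpha3", "K1", "K2", "n1", "n2")
    errs = _rel_errs(NOR_PARAMS, fit.params, names)
    assert max(errs.values()) < 0.10


def test_fit_hill2_input_swap_symmetry(growth, nor_grid_table):
    table, doses = nor_grid_table
    mapping = {f"nor_s{i}": (d["ahl1"], d["ahl2"]) for i, d in enumerate(doses)}
    swapped = {k: (v[1], v[0]) for k, v in mapping.items()}
    ds = assemble_dataset(table, mapping, "CFP")
    ds_swapped = assemble_dataset(table, swapped, "CFP")
    fit = fit_hill2(ds, RECEIVER1_PARAMS, RECEIVER2_PARAMS, 1.0, 1.0, 1.0, growth)
    fit_sw = fit_hill2(ds_swapped, RECEIVER2_PARAMS, RECEIVER1_PARAMS,
                       1.0, 1.0, 1.0, growth)
    assert fit_sw.params.alpha1 == pytest.approx(fit.params.alpha2, rel=0.02)
    assert fit_sw.params.alpha2 == pytest.approx(fit.params.alpha1, rel=0.02)
    assert fit_sw.params.K1 == pytest.approx(fit.params.K2, rel=0.02)
    assert fit_sw.params.n1 == pytest.approx(fit.params.n2, rel=0.02)


def test_fit_hill2_requires_receivers(growth, nor_dataset):
    from gcda.characterization import WorkflowOrderError

    with pytest.raises(WorkflowOrderError):
        fit_hill2(nor_dataset, None, RECEIVER2_PARAMS, 1.0, 1.0, 1.0, growth)


# ---------------------------------------------------------------------------
# growth reconstruction & store-driven characterization
# ---------------------------------------------------------------------------


def test_fit_growth_profile_constant():
    times = np.linspace(0, 6, 13)
    prof = fit_growth_profile(times, 0.2 * np.exp(0.4 * times))
    assert prof.mu(1.0) == pytest.approx(0.4, rel=1e-3)


def test_fit_growth_profile_logistic():
    true = LogisticGrowth(b0=0.02, Bmax=1.0, mu_max=0.9)
    times = np.linspace(0, 12, 25)
    prof = fit_growth_profile(times, [true.biomass(t) for t in times])
    assert isinstance(prof, LogisticGrowth)
    for t in (1.0, 4.0, 8.0):
        assert prof.mu(t) == pytest.approx(true.mu(t), abs=0.02)


def _store_with_receiver(tmp_path, growth, table, doses, vector="V_rec1"):
    store = DataStore(tmp_path / "store")
    store.register_signal("YFP")
    meta = {
        f"rec1_s{i}": {"vector": vector, "strain": "e.coli", "media": "M9",
                       "supplements": dict(d)}
        for i, d in enumerate(doses)
    }
    store.upload_assay("rec1", table, meta)
    return store


def test_characterize_receiver_from_store(tmp_path, growth, receiver1_table,
                                          receiver1_doses):
    doses = [{"ahl1": c} for c in receiver1_doses]
    store = _store_with_receiver(tmp_path, growth, receiver1_table, doses)
    fit = characterize("receiver", store, {"vector": "V_rec1"},
                       signal="YFP", gamma_reporter=1.0, growth=growth)
    errs = _rel_errs(RECEIVER1_PARAMS, fit.params, ("alpha0", "alpha1", "K", "n"))
    assert max(errs.values()) < 0.05
    # dispatch equivalence: the store route reproduces the direct fit exactly
    ds = _dataset_from_assay(receiver1_table, doses, "YFP", "rec1")
    direct = fit_receiver(ds, gamma=1.0, growth=growth)
    assert fit.params == direct.params


def test_characterize_no_data_error(tmp_path, growth, receiver1_table,
                                    receiver1_doses):
    doses = [{"ahl1": c} for c in receiver1_doses]
    store = _store_with_receiver(tmp_path, growth, receiver1_table, doses)
    with pytest.raises(NoDataError, match="no_such_vector"):
        characterize("receiver", store, {"vector": "no_such_vector"},
                     signal="YFP", gamma_reporter=1.0, growth=growth)


def test_characterize_combines_replicates_additively(tmp_path, growth,
                                                     receiver1_doses):
    """SSE of the joint fit decomposes as the sum over replicate assays."""
    rng = np.random.default_rng(5)
    net = receiver_network("ahl1", RECEIVER1_PARAMS, signal="YFP")
    doses = [{"ahl1": c} for c in receiver1_doses]
    store = DataStore(tmp_path / "store")
    store.register_signal("YFP")
    tables = []
    for rep in range(2):
        assay = dose_response_assay(net, doses, duration=10.0, interval=0.5,
                                    growth=growth, name=f"rep{rep}")
        table = run_assay(assay)
        mask = table["signal"] == "YFP"
        table.loc[mask, "value"] *= 1 + 0.03 * rng.standard_normal(mask.sum())
        meta = {f"rep{rep}_s{i}": {"vector": "V", "supplements": dict(d)}
                for i, d in enumerate(doses)}
        store.upload_assay(f"rep{rep}", table, meta)
        tables.append(table)
    fit = characterize("receiver", store, {"vector": "V"}, signal="YFP",
                       gamma_reporter=1.0, growth=growth,
                       check_identifiability=False)
    per_assay = []
    for rep, table in enumerate(tables):
        mapping = {f"rep{rep}_s{i}": (d["ahl1"],) for i, d in enumerate(doses)}
        ds = assemble_dataset(table, mapping, "YFP")
        per_assay.append(receiver_sse(ds, fit.params, 1.0, growth))
    assert fit.residual_sse == pytest.approx(sum(per_assay), rel=1e-9)
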