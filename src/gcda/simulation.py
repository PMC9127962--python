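"""Deterministic (ODE) and stochastic (Gillespie) simulation of samples.

A :class:`Sample` couples a genetic network to a growth profile and a set of
supplement concentrations; an :class:`Assay` simulates many samples on a
shared measurement grid and emits a tidy measurement table with one row per
(sample, signal, time).

The stochastic path treats each gene product as a birth-death species:
production reactions ``* -> p_i`` with propensity ``a_i`` equal to the summed
operator synthesis rates, and extinction reactions ``p_i -> *`` with
propensity ``b_i = (gamma_i + mu(t)) p_i``.  The direct-method simulation
freezes propensities between events and re-evaluates mu(t) at the current
time after every event (quasi-static growth approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .growth import ConstantGrowth, GrowthProfile
from .network import (
    GeneticNetwork,
    NetworkError,
    Supplement,
    compile_rates,
    operator_rate,
    validate_network,
)

__all__ = [
    "Sample",
    "Assay",
    "Trajectory",
    "PropensityVector",
    "SSAResult",
    "MEASUREMENT_COLUMNS",
    "simulate_ode",
    "propensities",
    "simulate_ssa",
    "ssa_ensemble",
    "run_assay",
    "measurement_grid",
]

MEASUREMENT_COLUMNS = ["assay", "sample", "signal", "time", "value"]

BIOMASS_SIGNAL = "biomass"


@dataclass
class Sample:
    """One simulated culture: a network in a growth context with supplements."""

    network: GeneticNetwork
    growth: GrowthProfile = field(default_factory=ConstantGrowth)
    supplements: dict[str, float] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        for conc in self.supplements.values():
            if conc < 0:
                raise ValueError("supplement concentrations must be >= 0")


@dataclass
class Assay:
    """A batch of samples simulated on a common measurement grid."""

    samples: list[Sample]
    duration: float
    measurement_interval: float
    method: str = "ode"
    seed: int = 0
    name: str = "assay"

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("assay requires at least one sample")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0 < self.measurement_interval <= self.duration:
            raise ValueError("measurement_interval must be in (0, duration]")
        if self.method not in ("ode", "ssa"):
            raise ValueError(f"unknown simulation method {self.method!r}")


def measurement_grid(duration: float, interval: float) -> np.ndarray:
    """Uniform grid 0, dt, 2dt, ... with floor(duration/interval)+1 points."""
    n = int(math.floor(duration / interval + 1e-9)) + 1
    return np.arange(n) * interval


@dataclass
class Trajectory:
    """Time-resolved product concentrations from one simulation."""

    times: np.ndarray
    values: np.ndarray  # (n_times, n_products)
    product_names: list[str]

    def series(self, product: str) -> np.ndarray:
        return self.values[:, self.product_names.index(product)]


@dataclass
class PropensityVector:
    """Per-product synthesis (a) and extinction (b) propensities."""

    a: np.ndarray
    b: np.ndarray


@dataclass
class SSAResult:
    """One stochastic realization: the event list plus a grid-sampled path."""

    event_times: np.ndarray
    events: list[tuple[int, int]]  # (product index, +1 or -1)
    trajectory: Trajectory


class SimulationError(RuntimeError):
    pass


def _require_valid(net: GeneticNetwork) -> None:
    violations = validate_network(net)
    if violations:
        raise NetworkError("invalid network: " + "; ".join(violations))


# ---------------------------------------------------------------------------
# deterministic simulation
# ---------------------------------------------------------------------------


def simulate_ode(
    sample: Sample,
    duration: float,
    timepoints: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate dp/dt = Psi(r) - (gamma + mu(t)) p from the initial state.

    ``timepoints`` defaults to 201 uniform points on [0, duration].  Small
    integrator undershoots below zero (magnitude < 1e-12) are clipped to
    exactly 0.
    """
    _require_valid(sample.network)
    net = sample.network
    if timepoints is None:
        timepoints = np.linspace(0.0, duration, 201)
    timepoints = np.asarray(timepoints, float)
    if timepoints.min() < 0 or timepoints.max() > duration + 1e-9:
        raise ValueError("timepoints must lie within [0, duration]")

    synth = compile_rates(net, sample.supplements)
    gamma = net.degradation_rates()
    mu = sample.growth.mu

    def rhs(t: float, p: np.ndarray) -> np.ndarray:
        return synth(np.clip(p, 0.0, None)) - (gamma + mu(t)) * p

    sol = solve_ivp(
        rhs,
        (0.0, duration),
        net.initial_state(),
        t_eval=timepoints,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    values = sol.y.T.copy()
    values[(values < 0) & (values > -1e-12)] = 0.0
    return Trajectory(timepoints, values, [p.name for p in net.products])


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------


def propensities(
    net: GeneticNetwork,
    p: Sequence[float],
    mu: float,
    supplements: Mapping[str, float] | None = None,
) -> PropensityVector:
    """Birth-death propensities at integer copy-number state ``p``."""
    p = np.asarray(p, float)
    if np.any(p < 0) or np.any(p != np.round(p)):
        raise NetworkError("propensities: copy numbers must be integers >= 0")
    synth = compile_rates(net, supplements)
    a = synth(p)
    b = (net.degradation_rates() + mu) * p
    return PropensityVector(a, b)


def _ssa_plan(net: GeneticNetwork, supplements: Mapping[str, float]):
    """Precompile per-operator rate closures for the inner Gillespie loop."""
    idx = net.product_index()
    plan = []
    for op in net.operators:
        inspec = []
        for inp in op.inputs:
            if isinstance(inp, Supplement):
                inspec.append((False, float(supplements.get(inp.name, 0.0))))
            else:
                inspec.append((True, idx[inp.name]))
        outs = [idx[o.name] for o in op.outputs]
        plan.append((op, inspec, outs))
    return plan


def simulate_ssa(
    sample: Sample,
    duration: float,
    seed: int,
    timepoints: Sequence[float] | None = None,
    record_events: bool = True,
) -> SSAResult:
    """Gillespie direct-method realization of the birth-death network.

    A fixed seed yields a bit-identical event list.  The grid-sampled
    trajectory holds the copy-number state immediately before each grid time.
    """
    _require_valid(sample.network)
    net = sample.network
    state0 = net.initial_state()
    if np.any(state0 != np.round(state0)):
        raise NetworkError("SSA requires integer-valued initial concentrations")
    if timepoints is None:
        timepoints = np.linspace(0.0, duration, 101)
    grid = np.asarray(timepoints, float)

    plan = _ssa_plan(net, sample.supplements)
    gamma = net.degradation_rates().tolist()
    n = net.n_products
    growth = sample.growth
    constant_mu = growth.mu(0.0) if isinstance(growth, ConstantGrowth) else None

    rng = np.random.default_rng(seed)
    # uniforms are drawn in blocks to amortize generator overhead
    block = rng.random(4096)
    bpos = 0

    def draw() -> float:
        nonlocal block, bpos
        if bpos == len(block):
            block = rng.random(4096)
            bpos = 0
        u = block[bpos]
        bpos += 1
        return u

    p = [int(x) for x in state0]
    t = 0.0
    event_times: list[float] = []
    events: list[tuple[int, int]] = []
    samples_out = np.empty((len(grid), n), dtype=np.int64)
    gpos = 0

    while True:
        mu = constant_mu if constant_mu is not None else growth.mu(min(t, duration))
        a = [0.0] * n
        for op, inspec, outs in plan:
            vals = [p[ref] if is_state else ref for is_state, ref in inspec]
            rate = operator_rate(op, vals)
            for j in outs:
                a[j] += rate
        b = [(gamma[i] + mu) * p[i] for i in range(n)]
        total = sum(a) + sum(b)
        if total <= 0.0:
            break
        t_next = t + (-math.log(draw()) / total)
        if t_next > duration:
            break
        # sample grid points passed before this event fires
        while gpos < len(grid) and grid[gpos] < t_next:
            samples_out[gpos] = p
            gpos += 1
        t = t_next
        target = draw() * total
        acc = 0.0
        fired = None
        for i in range(n):
            acc += a[i]
            if target < acc:
                fired = (i, 1)
                break
        if fired is None:
            for i in range(n):
                acc += b[i]
                if target < acc:
                    fired = (i, -1)
                    break
        if fired is None:  # numerical edge: assign to last nonzero channel
            fired = (n - 1, -1 if b[n - 1] > 0 else 1)
        p[fired[0]] += fired[1]
        if record_events:
            event_times.append(t)
            events.append(fired)

    while gpos < len(grid):
        samples_out[gpos] = p
        gpos += 1

    traj = Trajectory(grid, samples_out.astype(float), [pr.name for pr in net.products])
    return SSAResult(np.asarray(event_times), events, traj)


def ssa_ensemble(
    sample: Sample,
    duration: float,
    timepoints: Sequence[float],
    n_runs: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble mean and standard deviation over ``n_runs`` realizations.

    Per-run seeds are spawned deterministically from ``seed``.  Returns
    arrays of shape (n_times, n_products).
    """
    grid = np.asarray(timepoints, float)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    acc = np.zeros((len(grid), sample.network.n_products))
    acc2 = np.zeros_like(acc)
    for s in run_seeds:
        res = simulate_ssa(sample, duration, int(s), grid, record_events=False)
        acc += res.trajectory.values
        acc2 += res.trajectory.values**2
    mean = acc / n_runs
    var = np.clip(acc2 / n_runs - mean**2, 0.0, None)
    return mean, np.sqrt(var)


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------


def run_assay(assay: Assay) -> pd.DataFrame:
    """Simulate every sample and emit the tidy measurement table.

    One row per reporter signal per grid time plus one ``biomass`` row per
    grid time and sample; columns ``assay, sample, signal, time, value``.
    """
    grid = measurement_grid(assay.duration, assay.measurement_interval)
    rows: list[pd.DataFrame] = []
    seed_seq = np.random.SeedSequence(assay.seed).generate_state(len(assay.samples))
    for i, sample in enumerate(assay.samples):
        sample_id = sample.name or f"{assay.name}_s{i}"
        try:
            if assay.method == "ode":
                traj = simulate_ode(sample, assay.duration, grid)
            else:
                traj = simulate_ssa(
                    sample,
                    assay.duration,
                    int(seed_seq[i] % (2**31)),
                    grid,
                    record_events=False,
                ).trajectory
        except SimulationError as exc:
            raise SimulationError(f"sample {sample_id!r}: {exc}") from exc
        for product in sample.network.reporters:
            rows.append(
                pd.DataFrame(
                    {
                        "assay": assay.name,
                        "sample": sample_id,
                        "signal": product.signal_id,
                        "time": grid,
                        "value": traj.series(product.name),
                    }
                )
            )
        biomass = np.array([sample.growth.biomass(t) for t in grid])
        rows.append(
            pd.DataFrame(
                {
                    "assay": assay.name,
                    "sample": sample_id,
                    "signal": BIOMASS_SIGNAL,
                    "time": grid,
                    "value": biomass,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[MEASUREMENT_COLUMNS]
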