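"""Operator parametrization from kinetic dose-response measurements.

The workflow mirrors how composed devices are characterized in practice:

1. each *receiver* (inducer -> reporter) is fitted on its own auxiliary
   network from single-supplement dose-response kinetics;
2. downstream one- or two-input operators are then fitted on cascade data
   with the receiver parameters held fixed, so the regulator concentrations
   driving the operator are reconstructed from the known receiver models.

Fits are trajectory-level nonlinear least squares against the full ODE
solution of the measured cascade (not steady-state shortcuts): the model
trajectory for each dose is integrated with an exponential-trapezoidal rule
that is exact for piecewise-constant synthesis under constant growth, and
the summed squared residual over every series and timepoint is minimized
with bounded multi-start optimization (log10-parametrized rates and
switching concentrations, cooperativities linear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .growth import ConstantGrowth, GrowthProfile, LogisticGrowth
from .network import HillParams1, HillParams2, SourceParams

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "InsufficientDesignError",
    "NoDataError",
    "fit_source",
    "fit_receiver",
    "fit_hill1",
    "fit_hill2",
    "fit_growth_profile",
    "assemble_dataset",
    "characterize",
]

DEFAULT_SEED = 42
DEFAULT_RESTARTS = 10
#: maximum integrator substep (hours) when refining the measurement grid
DT_MAX = 0.05


class InsufficientDesignError(ValueError):
    pass


class NoDataError(ValueError):
    pass


class WorkflowOrderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseDataset:
    """Grouped kinetic series over a grid of input concentrations.

    ``values[s]`` is the reporter time series of series ``s`` on the shared
    measurement grid ``times``; ``series_dose[s]`` indexes into ``doses``
    (several series may share a dose — replicates).  Doses are 1-tuples for
    single-input designs and 2-tuples for two-input grids.
    """

    times: np.ndarray
    doses: list[tuple[float, ...]]
    values: np.ndarray
    series_dose: np.ndarray
    biomass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        self.series_dose = np.asarray(self.series_dose, int)

    @property
    def n_axes(self) -> int:
        return len(self.doses[0]) if self.doses else 0

    def axis_levels(self, axis: int) -> np.ndarray:
        return np.unique([d[axis] for d in self.doses])

    def validate(self, min_levels: int = 4, min_timepoints: int = 5) -> None:
        if len(self.times) < min_timepoints:
            raise InsufficientDesignError(
                f"need >= {min_timepoints} timepoints, got {len(self.times)}"
            )
        for d in self.doses:
            if min(d) < 0:
                raise InsufficientDesignError("concentrations must be >= 0")
        for axis in range(self.n_axes):
            levels = self.axis_levels(axis)
            if len(levels) < min_levels:
                raise InsufficientDesignError(
                    f"need >= {min_levels} distinct concentrations on axis "
                    f"{axis}, got {len(levels)}"
                )


@dataclass
class FitResult:
    """Outcome of one operator fit."""

    params: SourceParams | HillParams1 | HillParams2
    residual_sse: float
    identifiability_flags: dict[str, bool]
    n_restarts_used: int

    def to_dict(self) -> dict:
        import dataclasses

        return {
            "kind": type(self.params).__name__,
            "params": dataclasses.asdict(self.params),
            "residual_sse": self.residual_sse,
            "flags": self.identifiability_flags,
            "restarts": self.n_restarts_used,
        }


# ---------------------------------------------------------------------------
# trajectory model engine
# ---------------------------------------------------------------------------


def _refine_grid(times: np.ndarray, dt_max: float = DT_MAX) -> tuple[np.ndarray, np.ndarray]:
    """Insert substeps so every interval is <= dt_max.

    Returns (fine grid, indices of the original points in the fine grid).
    """
    fine = [times[0]]
    index = [0]
    for t0, t1 in zip(times, times[1:]):
        nsub = max(1, int(math.ceil((t1 - t0) / dt_max - 1e-9)))
        for j in range(1, nsub + 1):
            fine.append(t0 + (t1 - t0) * j / nsub)
        index.append(len(fine) - 1)
    return np.asarray(fine), np.asarray(index, int)


def _integrate_linear(
    f: np.ndarray, g: np.ndarray, tgrid: np.ndarray, s0: float | np.ndarray = 0.0
) -> np.ndarray:
    """Solve s' = f(t) - g(t) s columnwise on ``tgrid``.

    ``f`` has shape (T, J) (synthesis rate per condition), ``g`` shape (T,)
    (degradation + dilution).  Each step uses the exact solution for
    piecewise-constant f and g (exponential-trapezoidal rule), so the scheme
    is exact for constant sources under constant growth and second-order
    accurate otherwise.
    """
    T, J = f.shape
    out = np.empty((T, J))
    s = np.full(J, s0, float) if np.isscalar(s0) else np.asarray(s0, float).copy()
    out[0] = s
    for k in range(T - 1):
        dt = tgrid[k + 1] - tgrid[k]
        G = 0.5 * (g[k] + g[k + 1]) * dt
        fbar = 0.5 * (f[k] + f[k + 1])
        if G > 1e-12:
            E = math.exp(-G)
            s = E * s + fbar * dt * (-math.expm1(-G) / G)
        else:
            s = s + fbar * dt
        out[k + 1] = s
    return out


def _mu_on_grid(growth: GrowthProfile, tgrid: np.ndarray) -> np.ndarray:
    return np.array([growth.mu(t) for t in tgrid])


def _hill1_np(c: np.ndarray, alpha0: float, alpha1: float, K: float, n: float) -> np.ndarray:
    x = (c / K) ** n
    return (alpha0 + alpha1 * x) / (1.0 + x)


def _hill2_np(r1, r2, alpha0, alpha1, alpha2, alpha3, K1, K2, n1, n2):
    x1 = (r1 / K1) ** n1
    x2 = (r2 / K2) ** n2
    return (alpha0 + alpha1 * x1 + alpha2 * x2 + alpha3 * x1 * x2) / (
        (1.0 + x1) * (1.0 + x2)
    )


# ---------------------------------------------------------------------------
# multi-start bounded least squares
# ---------------------------------------------------------------------------


@dataclass
class _ParamSpec:
    name: str
    scale: str  # 'log' or 'lin'
    lo: float
    hi: float

    def to_internal(self, v: float) -> float:
        if self.scale == "log":
            return math.log10(max(v, 10.0 ** self.lo))
        return v

    def from_internal(self, x: float) -> float:
        return 10.0**x if self.scale == "log" else x


def _multistart(
    residual_fn,
    specs: list[_ParamSpec],
    starts: list[list[float]],
    xtol: float = 1e-10,
) -> tuple[np.ndarray, float, int]:
    lo = np.array([s.lo for s in specs])
    hi = np.array([s.hi for s in specs])

    def wrapped(x):
        return residual_fn([s.from_internal(xi) for s, xi in zip(specs, x)])

    best_x, best_sse = None, np.inf
    used = 0
    for start in starts:
        x0 = np.clip([s.to_internal(v) for s, v in zip(specs, start)], lo, hi)
        try:
            res = least_squares(wrapped, x0, bounds=(lo, hi), xtol=xtol, ftol=1e-12)
        except Exception:
            continue
        used += 1
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            best_sse, best_x = sse, res.x
    if best_x is None:
        raise RuntimeError("all optimization restarts failed")
    values = np.array([s.from_internal(xi) for s, xi in zip(specs, best_x)])
    return values, best_sse, used


def _refit_with_fixed(residual_fn, specs, values, fixed_idx, fixed_value) -> float:
    """SSE after re-optimizing the other parameters with one held fixed."""
    free = [i for i in range(len(specs)) if i != fixed_idx]
    lo = np.array([specs[i].lo for i in free])
    hi = np.array([specs[i].hi for i in free])

    def wrapped(xfree):
        full = list(values)
        for j, i in enumerate(free):
            full[i] = specs[i].from_internal(xfree[j])
        full[fixed_idx] = fixed_value
        return residual_fn(full)

    x0 = np.clip(
        [specs[i].to_internal(values[i]) for i in free], lo, hi
    )
    try:
        res = least_squares(wrapped, x0, bounds=(lo, hi), xtol=1e-9, ftol=1e-10,
                            max_nfev=200)
        return float(np.sum(res.fun**2))
    except Exception:
        return np.inf


def _identifiability(
    residual_fn, specs, values, best_sse, data_scale, check: Sequence[str]
) -> dict[str, bool]:
    """Profile-style probe: a parameter is non-identifiable when fixing it at
    0.5x / 1.5x of the fitted value and refitting the rest recovers the data
    essentially as well as the full fit."""
    threshold = max(4.0 * best_sse, 1e-6 * data_scale)
    flags: dict[str, bool] = {}
    for i, spec in enumerate(specs):
        if spec.name not in check:
            flags[spec.name] = True
            continue
        identifiable = False
        for factor in (0.5, 1.5):
            sse = _refit_with_fixed(residual_fn, specs, values, i, values[i] * factor)
            if sse > threshold:
                identifiable = True
                break
        flags[spec.name] = identifiable
    return flags


def _response_spread_small(dataset: DoseResponseDataset) -> bool:
    """True when the endpoint response barely varies across doses (<5% of mean)."""
    end = dataset.values[:, -1]
    mean = float(np.mean(np.abs(end)))
    if mean == 0:
        return True
    return float(end.max() - end.min()) < 0.05 * mean


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


# ---------------------------------------------------------------------------
# operator fits
# ---------------------------------------------------------------------------


def fit_source(
    times: Sequence[float],
    values: Sequence[float],
    gamma: float,
    growth: GrowthProfile,
) -> FitResult:
    """Fit the constitutive rate alpha of a source from one kinetic series.

    The model dp/dt = alpha - (gamma + mu(t)) p is linear in alpha, so the
    least-squares solution is closed-form (clipped at alpha >= 0).
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) < 5:
        raise InsufficientDesignError("need >= 5 timepoints")
    if np.all(values == 0):
        return FitResult(SourceParams(0.0), 0.0, {"alpha": False}, 0)
    fine, idx = _refine_grid(times)
    mu = _mu_on_grid(growth, fine)
    g = gamma + mu
    # unit response: solution for alpha = 1
    h = _integrate_linear(np.ones((len(fine), 1)), g, fine)[idx, 0]
    denom = float(h @ h)
    alpha = max(float(h @ values) / denom, 0.0) if denom > 0 else 0.0
    resid = alpha * h - values
    return FitResult(SourceParams(alpha), float(resid @ resid), {"alpha": True}, 1)


def _prepare(dataset: DoseResponseDataset, growth: GrowthProfile):
    fine, idx = _refine_grid(dataset.times)
    mu = _mu_on_grid(growth, fine)
    return fine, idx, mu


def _reporter_residual_factory(dataset, fine, idx, g_reporter, synth_fn):
    """Residual closure: params -> flattened residual over all series/times.

    ``synth_fn(params) -> (T_fine, n_doses)`` synthesis-rate matrix.
    """
    obs = dataset.values
    sd = dataset.series_dose

    def residual(params):
        f = synth_fn(params)
        model = _integrate_linear(f, g_reporter, fine)[idx]  # (T, J)
        return (model[:, sd].T - obs).ravel()

    return residual


def _alpha_rate_estimates(dataset: DoseResponseDataset, gamma: float,
                          growth: GrowthProfile) -> np.ndarray:
    """Rough per-dose synthesis-rate scale from the endpoint response."""
    g_end = gamma + growth.mu(dataset.times[-1])
    end = np.zeros(len(dataset.doses))
    for j in range(len(dataset.doses)):
        sel = dataset.series_dose == j
        end[j] = float(np.mean(dataset.values[sel, -1]))
    return np.clip(end * max(g_end, 1e-6), 0.0, None)


def fit_receiver(
    dataset: DoseResponseDataset,
    gamma: float,
    growth: GrowthProfile,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    check_identifiability: bool = True,
) -> FitResult:
    """Fit a receiver's Hill parameters from single-supplement kinetics.

    The receiver synthesizes the measured reporter directly, so for each
    supplement concentration c the model is dp/dt = hill1(c) - (gamma+mu)p,
    jointly fitted over all concentrations with multi-start least squares.
    """
    dataset.validate()
    if dataset.n_axes != 1:
        raise InsufficientDesignError("receiver fit expects a single dose axis")
    fine, idx, mu = _prepare(dataset, growth)
    g = gamma + mu
    doses = np.array([d[0] for d in dataset.doses])

    def synth(params):
        a0, a1, K, n = params
        rates = _hill1_np(doses, a0, a1, K, n)
        return np.broadcast_to(rates, (len(fine), len(doses)))

    residual = _reporter_residual_factory(dataset, fine, idx, g, synth)

    rate_est = _alpha_rate_estimates(dataset, gamma, growth)
    a_hi = max(rate_est.max(), 1e-3)
    pos = doses[doses > 0]
    c_lo, c_hi = (pos.min(), pos.max()) if len(pos) else (1e-3, 1e3)
    specs = [
        _ParamSpec("alpha0", "log", math.log10(a_hi) - 8, math.log10(a_hi) + 3),
        _ParamSpec("alpha1", "log", math.log10(a_hi) - 8, math.log10(a_hi) + 3),
        _ParamSpec("K", "log", math.log10(c_lo) - 2, math.log10(c_hi) + 2),
        _ParamSpec("n", "lin", 0.2, 10.0),
    ]
    rng = np.random.default_rng(seed)
    a_at_min = max(rate_est[np.argmin(doses)], a_hi * 1e-6)
    a_at_max = max(rate_est[np.argmax(doses)], a_hi * 1e-6)
    starts = [[a_at_min, a_at_max, math.sqrt(c_lo * c_hi), 2.0]]
    for _ in range(n_restarts - 1):
        starts.append(
            [
                a_at_min * _loguniform(rng, 0.3, 3),
                a_at_max * _loguniform(rng, 0.3, 3),
                _loguniform(rng, c_lo, c_hi),
                rng.uniform(1.0, 4.0),
            ]
        )
    values, sse, used = _multistart(residual, specs, starts)

    flags = {s.name: True for s in specs}
    if _response_spread_small(dataset):
        flags["K"] = flags["n"] = False
    elif check_identifiability:
        flags = _identifiability(
            residual, specs, values, sse, float(np.sum(dataset.values**2)),
            check=("K", "n"),
        )
    params = HillParams1(*values)
    return FitResult(params, sse, flags, used)


def _regulator_trajectories(
    doses: np.ndarray, receiver: HillParams1, gamma_regulator: float,
    fine: np.ndarray, mu: np.ndarray,
) -> np.ndarray:
    """Regulator concentration r(t) per dose under a fixed receiver model."""
    rates = _hill1_np(doses, receiver.alpha0, receiver.alpha1, receiver.K, receiver.n)
    f = np.broadcast_to(rates, (len(fine), len(doses)))
    return _integrate_linear(f, gamma_regulator + mu, fine)


def fit_hill1(
    dataset: DoseResponseDataset,
    receiver: HillParams1,
    gamma_regulator: float,
    gamma_reporter: float,
    growth: GrowthProfile,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    check_identifiability: bool = True,
) -> FitResult:
    """Fit a one-input operator downstream of a characterized receiver.

    The cascade supplement -> receiver -> regulator -> operator -> reporter
    is simulated with the receiver parameters held fixed; only the
    operator's Hill parameters are free.
    """
    dataset.validate()
    if dataset.n_axes != 1:
        raise InsufficientDesignError("hill1 fit expects a single dose axis")
    if receiver is None:
        raise WorkflowOrderError("receiver parameters must be fitted first")
    fine, idx, mu = _prepare(dataset, growth)
    doses = np.array([d[0] for d in dataset.doses])
    r_traj = _regulator_trajectories(doses, receiver, gamma_regulator, fine, mu)

    def synth(params):
        a0, a1, K, n = params
        return _hill1_np(r_traj, a0, a1, K, n)

    residual = _reporter_residual_factory(
        dataset, fine, idx, gamma_reporter + mu, synth
    )

    rate_est = _alpha_rate_estimates(dataset, gamma_reporter, growth)
    a_hi = max(rate_est.max(), 1e-3)
    r_pos = r_traj[r_traj > 0]
    r_lo = float(np.quantile(r_pos, 0.05)) if len(r_pos) else 1e-3
    r_hi = float(r_traj.max()) if r_traj.max() > 0 else 1.0
    specs = [
        _ParamSpec("alpha0", "log", math.log10(a_hi) - 8, math.log10(a_hi) + 3),
        _ParamSpec("alpha1", "log", math.log10(a_hi) - 8, math.log10(a_hi) + 3),
        _ParamSpec("K", "log", math.log10(max(r_lo, 1e-9)) - 2, math.log10(r_hi) + 2),
        _ParamSpec("n", "lin", 0.2, 10.0),
    ]
    rng = np.random.default_rng(seed)
    a_at_min = max(rate_est[np.argmin(doses)], a_hi * 1e-6)
    a_at_max = max(rate_est[np.argmax(doses)], a_hi * 1e-6)
    starts = [[a_at_min, a_at_max, math.sqrt(r_lo * r_hi), 2.0]]
    for _ in range(n_restarts - 1):
        starts.append(
            [
                a_at_min * _loguniform(rng, 0.3, 3),
                a_at_max * _loguniform(rng, 0.3, 3),
                _loguniform(rng, max(r_lo, 1e-9), r_hi),
                rng.uniform(1.0, 4.0),
            ]
        )
    values, sse, used = _multistart(residual, specs, starts)
    flags = {s.name: True for s in specs}
    if _response_spread_small(dataset):
        flags["K"] = flags["n"] = False
    elif check_identifiability:
        flags = _identifiability(
            residual, specs, values, sse, float(np.sum(dataset.values**2)),
            check=("K", "n"),
        )
    return FitResult(HillParams1(*values), sse, flags, used)


def fit_hill2(
    dataset: DoseResponseDataset,
    receiver1: HillParams1,
    receiver2: HillParams1,
    gamma_regulator1: float,
    gamma_regulator2: float,
    gamma_reporter: float,
    growth: GrowthProfile,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    check_identifiability: bool = False,
) -> FitResult:
    """Fit a two-input operator from a 2-D supplement grid.

    Both receivers must be characterized first (the staged workflow uses
    three auxiliary networks: one per receiver plus the composed cascade);
    their parameters are held fixed while the eight two-input Hill
    parameters are fitted.
    """
    if receiver1 is None or receiver2 is None:
        raise WorkflowOrderError("both receivers must be fitted before the "
                                 "two-input operator")
    dataset.validate()
    if dataset.n_axes != 2:
        raise InsufficientDesignError("hill2 fit expects a 2-D dose grid")
    fine, idx, mu = _prepare(dataset, growth)
    d1 = np.array([d[0] for d in dataset.doses])
    d2 = np.array([d[1] for d in dataset.doses])
    r1 = _regulator_trajectories(d1, receiver1, gamma_regulator1, fine, mu)
    r2 = _regulator_trajectories(d2, receiver2, gamma_regulator2, fine, mu)

    def synth(params):
        return _hill2_np(r1, r2, *params)

    residual = _reporter_residual_factory(
        dataset, fine, idx, gamma_reporter + mu, synth
    )

    rate_est = _alpha_rate_estimates(dataset, gamma_reporter, growth)
    a_hi = max(rate_est.max(), 1e-3)

    def corner(sel1, sel2):
        mask = sel1(d1) & sel2(d2)
        est = rate_est[mask]
        return max(float(np.mean(est)) if len(est) else a_hi * 0.1, a_hi * 1e-6)

    lo1, hi1 = d1.min(), d1.max()
    lo2, hi2 = d2.min(), d2.max()
    a00 = corner(lambda x: x == lo1, lambda y: y == lo2)
    a10 = corner(lambda x: x == hi1, lambda y: y == lo2)
    a01 = corner(lambda x: x == lo1, lambda y: y == hi2)
    a11 = corner(lambda x: x == hi1, lambda y: y == hi2)

    def r_range(r):
        pos = r[r > 0]
        lo = float(np.quantile(pos, 0.05)) if len(pos) else 1e-3
        hi = float(r.max()) if r.max() > 0 else 1.0
        return max(lo, 1e-9), hi

    r1_lo, r1_hi = r_range(r1)
    r2_lo, r2_hi = r_range(r2)
    alo, ahi = math.log10(a_hi) - 8, math.log10(a_hi) + 3
    specs = [
        _ParamSpec("alpha0", "log", alo, ahi),
        _ParamSpec("alpha1", "log", alo, ahi),
        _ParamSpec("alpha2", "log", alo, ahi),
        _ParamSpec("alpha3", "log", alo, ahi),
        _ParamSpec("K1", "log", math.log10(r1_lo) - 2, math.log10(r1_hi) + 2),
        _ParamSpec("K2", "log", math.log10(r2_lo) - 2, math.log10(r2_hi) + 2),
        _ParamSpec("n1", "lin", 0.2, 10.0),
        _ParamSpec("n2", "lin", 0.2, 10.0),
    ]
    rng = np.random.default_rng(seed)
    starts = [[a00, a10, a01, a11,
               math.sqrt(r1_lo * r1_hi), math.sqrt(r2_lo * r2_hi), 2.0, 2.0]]
    for _ in range(n_restarts - 1):
        starts.append(
            [
                a00 * _loguniform(rng, 0.3, 3),
                a10 * _loguniform(rng, 0.3, 3),
                a01 * _loguniform(rng, 0.3, 3),
                a11 * _loguniform(rng, 0.3, 3),
                _loguniform(rng, r1_lo, r1_hi),
                _loguniform(rng, r2_lo, r2_hi),
                rng.uniform(1.0, 4.0),
                rng.uniform(1.0, 4.0),
            ]
        )
    values, sse, used = _multistart(residual, specs, starts)
    flags = {s.name: True for s in specs}
    if _response_spread_small(dataset):
        for name in ("K1", "K2", "n1", "n2"):
            flags[name] = False
    elif check_identifiability:
        flags = _identifiability(
            residual, specs, values, sse, float(np.sum(dataset.values**2)),
            check=("K1", "K2", "n1", "n2"),
        )
    return FitResult(HillParams2(*values), sse, flags, used)


def receiver_sse(
    dataset: DoseResponseDataset,
    params: HillParams1,
    gamma: float,
    growth: GrowthProfile,
) -> float:
    """Summed squared residual of a receiver model against a dataset.

    Useful for comparing one parameter set across datasets (e.g. checking
    that the combined-fit residual decomposes additively over replicate
    assays).
    """
    fine, idx, mu = _prepare(dataset, growth)
    doses = np.array([d[0] for d in dataset.doses])

    def synth(p):
        a0, a1, K, n = p
        return np.broadcast_to(_hill1_np(doses, a0, a1, K, n),
                               (len(fine), len(doses)))

    residual = _reporter_residual_factory(dataset, fine, idx, gamma + mu, synth)
    r = residual([params.alpha0, params.alpha1, params.K, params.n])
    return float(r @ r)


# ---------------------------------------------------------------------------
# growth reconstruction
# ---------------------------------------------------------------------------


def fit_growth_profile(times: Sequence[float], biomass: Sequence[float]) -> GrowthProfile:
    """Reconstruct a growth profile from a measured biomass curve.

    A logistic profile is fitted on log-biomass; when the curve is consistent
    with pure exponential growth (or no growth) a constant-rate profile is
    returned instead.
    """
    times = np.asarray(times, float)
    b = np.asarray(biomass, float)
    if np.any(b <= 0):
        raise ValueError("biomass must be positive")
    logb = np.log(b)
    slope, intercept = np.polyfit(times, logb, 1)
    lin_resid = float(np.sum((logb - (slope * times + intercept)) ** 2))
    if lin_resid < 1e-8 * max(float(np.sum(logb**2)), 1.0) or len(times) < 4:
        return ConstantGrowth(mu0=max(slope, 0.0), b0=float(np.exp(intercept)))

    def resid(x):
        log_b0, log_dB, log_mu = x
        b0 = math.exp(log_b0)
        Bmax = b0 + math.exp(log_dB)
        prof = LogisticGrowth(b0=b0, Bmax=Bmax, mu_max=math.exp(log_mu))
        model = np.array([prof.biomass(t) for t in times])
        return np.log(model) - logb

    x0 = [math.log(b[0]), math.log(max(b[-1] - b[0], b[0])), math.log(max(slope, 0.1))]
    res = least_squares(resid, x0)
    b0 = math.exp(res.x[0])
    return LogisticGrowth(b0=b0, Bmax=b0 + math.exp(res.x[1]),
                          mu_max=math.exp(res.x[2]))


# ---------------------------------------------------------------------------
# store-driven characterization
# ---------------------------------------------------------------------------


def assemble_dataset(
    table,
    doses_by_sample: dict[str, tuple[float, ...]],
    signal: str,
) -> DoseResponseDataset:
    """Pivot a tidy measurement table into a :class:`DoseResponseDataset`.

    All samples must share one measurement grid.  Replicate samples at the
    same dose become separate series mapped to a common dose entry; the
    biomass channel, when present, is averaged across samples.
    """
    rows = table[table["signal"] == signal]
    if rows.empty:
        raise NoDataError(f"no rows for signal {signal!r}")
    times = None
    doses: list[tuple[float, ...]] = []
    series, series_dose = [], []
    for sample_id, grp in rows.groupby("sample", sort=True):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy()
        if times is None:
            times = t
        elif len(t) != len(times) or not np.allclose(t, times):
            raise NoDataError("samples do not share a measurement grid")
        dose = tuple(doses_by_sample[sample_id])
        if dose not in doses:
            doses.append(dose)
        series.append(grp["value"].to_numpy())
        series_dose.append(doses.index(dose))
    biomass_rows = table[table["signal"] == "biomass"]
    biomass = None
    if not biomass_rows.empty:
        biomass = (
            biomass_rows.groupby("time", sort=True)["value"].mean().to_numpy()
        )
    return DoseResponseDataset(times, doses, np.array(series),
                               np.array(series_dose), biomass)


def characterize(
    operator_kind: str,
    store,
    selectors: dict,
    *,
    signal: str,
    gamma_reporter: float,
    gamma_regulator: float | None = None,
    gamma_regulator2: float | None = None,
    receiver: HillParams1 | None = None,
    receiver2: HillParams1 | None = None,
    growth: GrowthProfile | None = None,
    supplement_names: Sequence[str] | None = None,
    **fit_kwargs,
) -> FitResult:
    """Single-call parametrization from a datastore.

    Queries the store with ``selectors``, assembles the dose-response dataset
    from the matching assays (combining every available replicate), and
    dispatches to the fit routine for ``operator_kind`` (``source``,
    ``receiver``, ``hill1`` or ``hill2``).  When no growth profile is given
    it is reconstructed from the stored biomass channel.
    """
    # the reporter signal is selected locally so the biomass channel stays
    # available for growth reconstruction
    selectors = {k: v for k, v in selectors.items() if k != "signal"}
    table = store.query(**selectors)
    if table.empty:
        raise NoDataError(f"no measurements match selectors {selectors!r}")

    sample_meta = {
        sid: store.sample_metadata(sid) for sid in table["sample"].unique()
    }
    if supplement_names is None:
        names = sorted({n for m in sample_meta.values()
                        for n in m.get("supplements", {})})
    else:
        names = list(supplement_names)

    if growth is None:
        biomass_rows = table[table["signal"] == "biomass"]
        if biomass_rows.empty:
            raise NoDataError("no growth profile given and no biomass channel "
                              "in the queried data")
        bseries = biomass_rows.groupby("time", sort=True)["value"].mean()
        growth = fit_growth_profile(bseries.index.to_numpy(), bseries.to_numpy())

    if operator_kind == "source":
        rows = table[table["signal"] == signal].sort_values(["sample", "time"])
        if rows.empty:
            raise NoDataError(f"no rows for signal {signal!r}")
        grp = rows.groupby("time", sort=True)["value"].mean()
        return fit_source(grp.index.to_numpy(), grp.to_numpy(),
                          gamma_reporter, growth)

    doses_by_sample = {
        sid: tuple(meta.get("supplements", {}).get(n, 0.0) for n in names)
        for sid, meta in sample_meta.items()
    }
    dataset = assemble_dataset(table, doses_by_sample, signal)

    if operator_kind == "receiver":
        return fit_receiver(dataset, gamma_reporter, growth, **fit_kwargs)
    if operator_kind == "hill1":
        if receiver is None:
            raise WorkflowOrderError("hill1 characterization requires fitted "
                                     "receiver parameters")
        return fit_hill1(dataset, receiver, gamma_regulator, gamma_reporter,
                         growth, **fit_kwargs)
    if operator_kind == "hill2":
        if receiver is None or receiver2 is None:
            raise WorkflowOrderError("hill2 characterization requires both "
                                     "fitted receivers")
        return fit_hill2(dataset, receiver, receiver2, gamma_regulator,
                         gamma_regulator2, gamma_reporter, growth, **fit_kwargs)
    raise ValueError(f"unknown operator kind {operator_kind!r}")
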