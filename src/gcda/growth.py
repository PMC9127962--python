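"""Growth (metabolism) profiles supplying biomass(t) and dilution rate mu(t).

The instantaneous growth rate ``mu(t) = d ln(biomass)/dt`` dilutes every gene
product additively with its degradation rate.  Three batch-culture-style
profiles are provided; mu is derived from the biomass curve analytically so
that ODE right-hand sides stay smooth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthProfile",
    "ConstantGrowth",
    "LogisticGrowth",
    "GompertzGrowth",
    "biomass_at",
    "growth_rate_at",
    "growth_from_dict",
    "growth_to_dict",
]


@dataclass
class GrowthProfile:
    """Base class: subclasses implement ``biomass(t)`` and ``mu(t)``.

    ``duration`` bounds the valid time range [0, duration] (hours); the
    default is unbounded.
    """

    duration: float = math.inf

    def _check_time(self, t: float) -> None:
        if t < 0 or t > self.duration:
            raise ValueError(f"time {t} outside [0, {self.duration}]")

    def biomass(self, t: float) -> float:
        raise NotImplementedError

    def mu(self, t: float) -> float:
        raise NotImplementedError


@dataclass
class ConstantGrowth(GrowthProfile):
    """Exponential growth at fixed rate: biomass = b0 * exp(mu0 * t)."""

    mu0: float = 0.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        if self.mu0 < 0:
            raise ValueError("mu0 must be >= 0")
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")

    def biomass(self, t: float) -> float:
        self._check_time(t)
        return self.b0 * math.exp(self.mu0 * t)

    def mu(self, t: float) -> float:
        self._check_time(t)
        return self.mu0


@dataclass
class LogisticGrowth(GrowthProfile):
    """Logistic batch growth from b0 toward carrying capacity Bmax.

    biomass(t) = Bmax / (1 + (Bmax/b0 - 1) exp(-mu_max t)),
    mu(t) = mu_max (1 - biomass/Bmax).
    """

    b0: float = 0.01
    Bmax: float = 1.0
    mu_max: float = 1.0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")
        if self.Bmax <= self.b0:
            raise ValueError("Bmax must exceed b0")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")

    def biomass(self, t: float) -> float:
        self._check_time(t)
        return self.Bmax / (1.0 + (self.Bmax / self.b0 - 1.0) * math.exp(-self.mu_max * t))

    def mu(self, t: float) -> float:
        self._check_time(t)
        return self.mu_max * (1.0 - self.biomass(t) / self.Bmax)


@dataclass
class GompertzGrowth(GrowthProfile):
    """Gompertz batch growth with an explicit lag phase (Zwietering form).

    ln(biomass/b0) = A exp(-exp(mu_max e (lag - t)/A + 1)) with
    A = ln(Bmax/b0); mu_max is the maximum of mu(t) and ``lag`` the lag time
    in hours.
    """

    b0: float = 0.01
    Bmax: float = 1.0
    mu_max: float = 1.0
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")
        if self.Bmax <= self.b0:
            raise ValueError("Bmax must exceed b0")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    def _u(self, t: float) -> float:
        A = math.log(self.Bmax / self.b0)
        return math.exp(self.mu_max * math.e * (self.lag - t) / A + 1.0)

    def biomass(self, t: float) -> float:
        self._check_time(t)
        A = math.log(self.Bmax / self.b0)
        return self.b0 * math.exp(A * math.exp(-self._u(t)))

    def mu(self, t: float) -> float:
        self._check_time(t)
        u = self._u(t)
        return self.mu_max * math.e * u * math.exp(-u)


def biomass_at(profile: GrowthProfile, t: float) -> float:
    """Closed-form biomass at time ``t`` (OD-like arbitrary units)."""
    return profile.biomass(t)


def growth_rate_at(profile: GrowthProfile, t: float) -> float:
    """Analytic instantaneous growth rate mu(t) = d ln(biomass)/dt."""
    return profile.mu(t)


_KINDS = {"constant": ConstantGrowth, "logistic": LogisticGrowth, "gompertz": GompertzGrowth}
_KIND_OF = {v: k for k, v in _KINDS.items()}


def growth_to_dict(profile: GrowthProfile) -> dict:
    """Serialize a profile to the JSON block {"kind": ..., "params": {...}}."""
    params = {
        k: v
        for k, v in profile.__dict__.items()
        if k != "duration" or math.isfinite(v)
    }
    return {"kind": _KIND_OF[type(profile)], "params": params}


def growth_from_dict(d: dict) -> GrowthProfile:
    kind = d.get("kind")
    if kind not in _KINDS:
        raise ValueError(f"unknown growth profile kind {kind!r}")
    return _KINDS[kind](**d.get("params", {}))
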