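"""Age-structured model of the memory CD8+ T cell compartment.

The compartment obeys logistic-with-source dynamics

    dz/dt = lambda + s * z * (1 - z/k) - mu * z,

where lambda is the influx of new memory cells, s the division rate,
k the carrying capacity and mu the death rate.  Cell *age* is the time
since the cell (or its ancestor) entered the memory compartment —
division does not reset age.  At the steady state z̄ the age density
w(a) satisfies a transport equation with constant effective removal
rate D = mu - s(1 - z̄/k) = lambda/z̄, so the equilibrium age
distribution is Exponential(D) and the mean age is 1/D.  Because
dD/dmu > 0 for all positive parameters, longer cell lifetimes (1/mu)
imply older compartments — though D is a difference of similar terms,
so the correlation can be weak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgeModelParams",
    "AgeDistribution",
    "steady_state",
    "mean_age",
    "dD_dmu",
    "simulate_age_distribution",
]


@dataclass(frozen=True)
class AgeModelParams:
    """Parameters of the memory-compartment model (all per day / cells)."""

    lam: float   # influx into the memory compartment (cells/day)
    s: float     # division rate (/day)
    k: float     # carrying capacity (cells)
    mu: float    # death rate (/day)

    def __post_init__(self):
        for name in ("lam", "s", "k", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class AgeDistribution:
    """Discretised age density w(a) on a uniform grid."""

    ages: np.ndarray      # days
    density: np.ndarray   # cells per day of age
    mean_age: float       # days

    def total(self) -> float:
        """Integral of the density (should equal z̄ at steady state)."""
        return float(np.trapezoid(self.density, self.ages))


def steady_state(params: AgeModelParams) -> tuple[float, float]:
    """Steady-state compartment size z̄ and effective removal rate D.

    z̄ is the stable (larger) positive root of
    lambda + s*z(1 - z/k) - mu*z = 0 and D = mu - s(1 - z̄/k), which by
    the equilibrium condition equals lambda/z̄.
    """
    lam, s, k, mu = params.lam, params.s, params.k, params.mu
    # (s/k) z^2 - (s - mu) z - lam = 0
    a, b, c = s / k, -(s - mu), -lam
    disc = b * b - 4 * a * c
    if disc <= 0:
        raise ValueError("no positive steady state for these parameters")
    # numerically stable larger root: avoids cancellation when s -> 0
    q = -(b + math.copysign(math.sqrt(disc), b)) / 2.0
    zbar = max(q / a, c / q)
    if zbar <= 0:
        raise ValueError("no positive steady state for these parameters")
    # one Newton step tightens the root to machine precision
    g = lam + s * zbar * (1 - zbar / k) - mu * zbar
    gp = s * (1 - 2 * zbar / k) - mu
    if gp != 0.0:
        zbar -= g / gp
    # stability: d/dz [lam + s z(1-z/k) - mu z] < 0 at zbar
    slope = s * (1 - 2 * zbar / k) - mu
    if slope >= 0:
        raise ValueError("selected root is not stable")
    # equilibrium gives D = mu - s(1 - zbar/k) = lam/zbar; the latter is
    # exact in floating point given the polished root
    D = lam / zbar
    return zbar, D


def mean_age(params: AgeModelParams) -> float:
    """Mean age 1/D of the equilibrium (exponential) age distribution."""
    _, D = steady_state(params)
    if D <= 0:
        raise ValueError("effective removal rate must be positive")
    return 1.0 / D


def dD_dmu(params: AgeModelParams) -> float:
    """Derivative of D with respect to mu at fixed (lambda, s, k).

    Via implicit differentiation of the equilibrium condition:
    dz̄/dmu = z̄ / (s(1 - 2z̄/k) - mu) < 0 and D = lambda/z̄, so
    dD/dmu = -lambda * dz̄/dmu / z̄^2 > 0 always.
    """
    lam, s, k, mu = params.lam, params.s, params.k, params.mu
    zbar, _ = steady_state(params)
    dz = zbar / (s * (1 - 2 * zbar / k) - mu)
    return -lam * dz / zbar**2


def simulate_age_distribution(params: AgeModelParams,
                              horizon: float | None = None,
                              da: float = 0.5,
                              a_max: float | None = None,
                              w0: np.ndarray | None = None,
                              z0: float | None = None) -> AgeDistribution:
    """Transport the age density numerically to (near) steady state.

    Uses the method of characteristics with equal age and time steps:
    each step, the density shifts by one age bin and decays by the
    current per-capita removal rate mu - s(1 - z/k); the youngest bin is
    refilled from the boundary condition w(0, t) = lambda.  The total
    population z(t) is the integral of the density, so compartment and
    age dynamics stay consistent.

    Defaults: ``horizon`` = 12 mean ages, ``a_max`` = 12 mean ages.
    A grid too coarse to resolve the removal rate (D*da > 0.2) raises.
    """
    zbar, D = steady_state(params)
    if D * da > 0.2:
        raise ValueError("age grid too coarse for this removal rate; "
                         "decrease da")
    if a_max is None:
        a_max = 12.0 / D
    if horizon is None:
        horizon = 12.0 / D
    ages = np.arange(0.0, a_max + da / 2, da)
    if w0 is None:
        w = np.zeros_like(ages)
        z = params.lam / params.mu if z0 is None else z0
    else:
        w = np.array(w0, dtype=float)
        if w.shape != ages.shape:
            raise ValueError("w0 must match the age grid")
        z = float(np.trapezoid(w, ages)) if z0 is None else z0
    n_steps = int(round(horizon / da))
    for _ in range(n_steps):
        d_now = params.mu - params.s * (1 - z / params.k)
        decay = math.exp(-d_now * da)
        w[1:] = w[:-1] * decay
        w[0] = params.lam
        z = float(np.trapezoid(w, ages))
    mean = float(np.trapezoid(ages * w, ages) / np.trapezoid(w, ages))
    return AgeDistribution(ages=ages, density=w, mean_age=mean)
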