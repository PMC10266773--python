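"""Forward models of deuterated-water label enrichment.

The labeling study administers heavy water in three phases (full dose,
reduced dose, washout).  Label availability in body water is measured in
saliva and described by a three-part empirical curve S(t); blood
monocytes act as a rapidly turning-over reference population whose DNA
enrichment identifies the amplification factor b_w; and the enrichment
of each sorted T cell subset follows simple proliferation/disappearance
kinetics observed with a trafficking delay.

All enrichments are fractions in [0, 1].  Rates are per day, times in
days.  Every model exposes an exact closed-form solution (built on
:mod:`ikirspan._pwexp`) plus a numerical ODE oracle used in testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._pwexp import PiecewiseExponential

__all__ = [
    "LabelingProtocol",
    "BodyWaterModel",
    "MonocyteModel",
    "TcellKinetics",
    "saliva_enrichment",
    "monocyte_enrichment",
    "monocyte_enrichment_numeric",
    "tcell_enrichment",
    "tcell_enrichment_numeric",
    "lifespan_from_rate",
    "half_life_from_rate",
]


@dataclass(frozen=True)
class LabelingProtocol:
    """Three-phase heavy-water dosing schedule.

    Full dose until ``t_full_dose``, a reduced maintenance dose (fraction
    ``dose_fraction_phase2`` of the full dose) until ``t_end_label``,
    then washout.  Defaults mirror the study protocol: full dose for 7
    days, 2/3 dose for 42 days, observation up to 112 days.
    """

    t_full_dose: float = 7.0
    t_end_label: float = 49.0
    dose_fraction_phase2: float = 2.0 / 3.0
    observation_horizon: float = 112.0

    def __post_init__(self):
        if not 0 < self.t_full_dose < self.t_end_label <= self.observation_horizon:
            raise ValueError(
                "require 0 < t_full_dose < t_end_label <= observation_horizon")
        if not 0 < self.dose_fraction_phase2 <= 1:
            raise ValueError("dose_fraction_phase2 must be in (0, 1]")


@dataclass(frozen=True)
class BodyWaterModel:
    """Per-individual body-water label availability S(t).

    ``f`` is the maximal body-water enrichment the individual would
    attain asymptotically on the full dose; ``delta`` is the body-water
    turnover rate per day (shared across individuals when fitting).
    """

    f: float
    delta: float
    protocol: LabelingProtocol = field(default_factory=LabelingProtocol)

    def __post_init__(self):
        if not 0 < self.f < 1:
            raise ValueError("f must be in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def signal(self) -> PiecewiseExponential:
        """S(t) as an exact piecewise-exponential signal.

        Phase 1 rises toward ``f``, phase 2 relaxes toward
        ``dose_fraction_phase2 * f``, phase 3 decays to zero; all three
        phases share the single turnover rate delta, so the curve is
        continuous at the phase boundaries.
        """
        p, f, d = self.protocol, self.f, self.delta
        t1, t2 = p.t_full_dose, p.t_end_label
        f2 = p.dose_fraction_phase2 * f
        s1 = f * (1.0 - math.exp(-d * t1))            # S at end of phase 1
        s2 = f2 + (s1 - f2) * math.exp(-d * (t2 - t1))  # S at end of phase 2
        return PiecewiseExponential(
            breaks=(0.0, t1, t2),
            segments=(
                ((f, 0.0, 0), (-f, d, 0)),
                ((f2, 0.0, 0), (s1 - f2, d, 0)),
                ((s2, d, 0),),
            ),
        )

    def plateau(self) -> float:
        """Asymptote of the maintenance phase (the working plateau)."""
        return self.protocol.dose_fraction_phase2 * self.f


@dataclass(frozen=True)
class MonocyteModel:
    """Bone-marrow/blood monocyte labeling model.

    Precursors in the marrow mitotic pool incorporate label at division
    with amplification ``b_w``; cells transit a post-mitotic marrow pool
    for ``delta_post`` days and are then lost from blood at rate ``r_2``.
    Equilibrium of cell numbers fixes the precursor proliferation rate at
    p_m = r_2 / (M/B) and the mitotic-pool exit rate at r_1 = p_m, so
    only ``b_w`` and ``r_2`` remain free.  The blood plateau during
    prolonged labeling is b_w times the body-water plateau, independent
    of ``M_over_B`` and ``delta_post`` — this is what identifies b_w.
    """

    b_w: float
    r_2: float
    M_over_B: float = 2.6
    delta_post: float = 1.6

    def __post_init__(self):
        if not 0 <= self.b_w <= 7:
            raise ValueError("b_w must be in [0, 7]")
        if not 0 <= self.r_2 <= 10:
            raise ValueError("r_2 must be in [0, 10]")
        if self.M_over_B <= 0:
            raise ValueError("M_over_B must be positive")
        if self.delta_post < 0:
            raise ValueError("delta_post must be non-negative")

    @property
    def p_m(self) -> float:
        return self.r_2 / self.M_over_B

    def blood_signal(self, water: BodyWaterModel) -> PiecewiseExponential:
        """Closed-form blood-monocyte enrichment L_B(t)."""
        s = water.signal()
        pm = self.p_m
        if self.r_2 == 0 or pm == 0:
            return PiecewiseExponential((0.0,), (((0.0, 0.0, 0),),))
        marrow = s.filter(gain=pm * self.b_w, rate=pm)
        return marrow.shift(self.delta_post).filter(gain=self.r_2, rate=self.r_2)


@dataclass(frozen=True)
class TcellKinetics:
    """Per-subset T cell kinetic parameters.

    ``p`` is the proliferation rate, ``d_star`` the disappearance rate of
    labeled cells (kinetic heterogeneity allows d* != p), and ``delay``
    the lag for a cell to traffic from the site of division to blood.
    The reported lifespan is 1/p (half-life ln(2)/p).
    """

    p: float
    d_star: float
    delay: float = 0.0

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("p must be non-negative")
        if self.d_star <= 0:
            raise ValueError("d_star must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    @property
    def lifespan(self) -> float:
        return lifespan_from_rate(self.p)

    @property
    def half_life(self) -> float:
        return half_life_from_rate(self.p)

    def observed_signal(self, b_w: float, water: BodyWaterModel
                        ) -> PiecewiseExponential:
        """Closed-form observed enrichment O(t) = L(t - delay)."""
        s = water.signal()
        lab = s.filter(gain=self.p * b_w, rate=self.d_star)
        return lab.shift(self.delay)


# --------------------------------------------------------------------------
# functional front-ends


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def saliva_enrichment(t, model: BodyWaterModel):
    """Body-water (saliva) enrichment S(t) at time(s) ``t`` in days."""
    return model.signal()(_check_time(t))


def monocyte_enrichment(t, model: MonocyteModel, water: BodyWaterModel):
    """Blood-monocyte DNA enrichment L_B(t) (closed form)."""
    return model.blood_signal(water)(_check_time(t))


def tcell_enrichment(t, kin: TcellKinetics, b_w: float,
                     water: BodyWaterModel):
    """Observed T cell DNA enrichment O(t) (closed form)."""
    if b_w < 0:
        raise ValueError("b_w must be non-negative")
    return kin.observed_signal(b_w, water)(_check_time(t))


def lifespan_from_rate(p: float) -> float:
    """Mean cell lifespan 1/p in days."""
    if p <= 0:
        raise ValueError("proliferation rate must be positive")
    return 1.0 / p


def half_life_from_rate(p: float) -> float:
    """Half-life ln(2)/p in days."""
    return math.log(2.0) * lifespan_from_rate(p)


# --------------------------------------------------------------------------
# numeric ODE oracles (reference implementations for testing)


def _segment_integrate(rhs, y0, breaks, t_eval):
    """Integrate a smooth-by-segment ODE, stopping at each breakpoint."""
    t_eval = np.asarray(t_eval, dtype=float)
    t_end = max(float(t_eval.max()), breaks[-1] + 1.0) if t_eval.size else breaks[-1]
    knots = sorted({0.0, *[b for b in breaks if 0.0 < b < t_end], t_end})
    ts, ys = [], []
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    for a, b in zip(knots, knots[1:]):
        inside = t_eval[(t_eval > a) & (t_eval <= b)]
        pts = np.unique(np.concatenate([inside, [b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=pts, rtol=1e-10, atol=1e-12,
                        method="LSODA")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1]
    ts = np.concatenate(ts)
    ys = np.concatenate(ys, axis=1)
    out = np.empty((ys.shape[0], t_eval.size))
    for j, tv in enumerate(t_eval):
        if tv <= 0:
            out[:, j] = np.atleast_1d(np.asarray(y0, dtype=float)) * 0.0
        else:
            out[:, j] = ys[:, np.argmin(np.abs(ts - tv))]
    return out


def tcell_enrichment_numeric(t, kin: TcellKinetics, b_w: float,
                             water: BodyWaterModel):
    """ODE-oracle version of :func:`tcell_enrichment`.

    Integrates dL/dt = p*b_w*S(t) - d*.L numerically and applies the
    trafficking delay to the observable.
    """
    t = _check_time(np.atleast_1d(t))
    s = water.signal()
    proto = water.protocol

    def rhs(tt, y):
        return [kin.p * b_w * s(tt) - kin.d_star * y[0]]

    shifted = np.clip(t - kin.delay, 0.0, None)
    breaks = (proto.t_full_dose, proto.t_end_label)
    vals = _segment_integrate(rhs, [0.0], breaks, shifted)[0]
    vals[t < kin.delay] = 0.0
    return vals


def monocyte_enrichment_numeric(t, model: MonocyteModel,
                                water: BodyWaterModel):
    """ODE-oracle version of :func:`monocyte_enrichment`.

    The marrow pool is integrated first; its (delayed) output then
    drives the blood compartment.  Used to validate the closed form.
    """
    t = _check_time(np.atleast_1d(t))
    s = water.signal()
    proto = water.protocol
    pm = model.p_m
    if pm == 0 or model.r_2 == 0:
        return np.zeros_like(t)

    # marrow enrichment on a fine grid, then blood driven by its delay
    horizon = float(max(t.max(), proto.observation_horizon)) + 1.0
    grid = np.linspace(0.0, horizon, 4001)

    def rhs_m(tt, y):
        return [pm * (model.b_w * s(tt) - y[0])]

    lm = _segment_integrate(rhs_m, [0.0], (proto.t_full_dose, proto.t_end_label),
                            grid)[0]

    def lm_delayed(tt):
        tau = tt - model.delta_post
        if tau <= 0:
            return 0.0
        return float(np.interp(tau, grid, lm))

    def rhs_b(tt, y):
        return [model.r_2 * (lm_delayed(tt) - y[0])]

    breaks = (proto.t_full_dose + model.delta_post,
              proto.t_end_label + model.delta_post, model.delta_post)
    return _segment_integrate(rhs_b, [0.0], tuple(sorted(b for b in breaks if b > 0)),
                              t)[0]
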