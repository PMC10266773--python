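"""Piecewise polynomial-exponential signals and first-order linear filters.

All forward models of label enrichment in this package are cascades of
first-order linear compartments driven by the three-phase body-water
curve, which is itself a sum of constants and exponentials on each dosing
phase.  The closed-form solutions therefore stay within the class

    x(t) = sum_i  c_i * (t - t_j)^k_i * exp(-r_i * (t - t_j))

on each segment [t_j, t_{j+1}).  This module implements that class plus
the two operations the models need: filtering through dy/dt = g*u - a*y
and a pure time delay.  Keeping the algebra exact is what makes the
"analytic solution == numeric ODE" contract cheap to honour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# Rates closer than this are treated as resonant (exact t*exp form); the
# snap error and the cancellation error on either side of the threshold
# are both far below the package's 1e-6 analytic-vs-ODE tolerance.
_RESONANCE_TOL = 1e-9

# term: (coef, rate, power) meaning coef * tau**power * exp(-rate*tau),
# tau measured from the segment's left breakpoint.


@dataclass(frozen=True)
class PiecewiseExponential:
    """A signal that is polynomial-exponential on each segment.

    ``breaks`` is an increasing array starting at 0; segment ``i`` covers
    ``[breaks[i], breaks[i+1])`` (the last segment extends to infinity).
    ``segments[i]`` is a tuple of ``(coef, rate, power)`` terms.  The
    signal is defined as 0 for t < 0.
    """

    breaks: tuple[float, ...]
    segments: tuple[tuple[tuple[float, float, int], ...], ...]

    def __post_init__(self):
        if len(self.breaks) != len(self.segments):
            raise ValueError("one term list per segment required")
        if self.breaks[0] != 0.0:
            raise ValueError("signals start at t=0")
        if any(b1 <= b0 for b0, b1 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    # ------------------------------------------------------------------ eval
    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        breaks = np.asarray(self.breaks)
        idx = np.searchsorted(breaks, t, side="right") - 1
        valid = t >= 0.0
        for i, terms in enumerate(self.segments):
            mask = valid & (idx == i)
            if not mask.any():
                continue
            tau = t[mask] - breaks[i]
            acc = np.zeros_like(tau)
            for c, r, k in terms:
                acc += c * tau**k * np.exp(-r * tau)
            out[mask] = acc
        return out[0] if scalar else out

    # ----------------------------------------------------------------- shift
    def shift(self, delay: float) -> "PiecewiseExponential":
        """Delay the signal by ``delay`` days (zero history before it)."""
        if delay < 0:
            raise ValueError("delay must be non-negative")
        if delay == 0:
            return self
        breaks = (0.0,) + tuple(b + delay for b in self.breaks)
        segments = ((),) + self.segments
        return PiecewiseExponential(breaks, segments)

    # ---------------------------------------------------------------- filter
    def filter(self, gain: float, rate: float, y0: float = 0.0
               ) -> "PiecewiseExponential":
        """Solve dy/dt = gain * u(t) - rate * y with y(0) = y0.

        ``u`` is this signal; the result is again piecewise
        polynomial-exponential with the same breakpoints.
        """
        if rate <= 0:
            raise ValueError("filter rate must be positive")
        out_segments = []
        y_left = y0
        for i, terms in enumerate(self.segments):
            seg_terms: list[tuple[float, float, int]] = []
            # particular solution per input term
            for c, r, k in terms:
                seg_terms.extend(_particular(gain * c, r, k, rate))
            # homogeneous part matches the left-side initial condition
            p0 = sum(c for c, r, k in seg_terms if k == 0)
            seg_terms.append((y_left - p0, rate, 0))
            seg_terms = _merge(seg_terms)
            out_segments.append(tuple(seg_terms))
            # propagate the state to the next breakpoint
            if i + 1 < len(self.breaks):
                tau = self.breaks[i + 1] - self.breaks[i]
                y_left = sum(c * tau**k * math.exp(-r * tau)
                             for c, r, k in seg_terms)
        return PiecewiseExponential(self.breaks, tuple(out_segments))


def _particular(c: float, r: float, k: int, a: float
                ) -> list[tuple[float, float, int]]:
    """Particular solution of y' + a*y = c * tau^k * exp(-r*tau)."""
    if abs(a - r) < _RESONANCE_TOL:
        # exact resonance: y_p = c * tau^(k+1)/(k+1) * exp(-a*tau)
        return [(c / (k + 1), a, k + 1)]
    b = a - r
    # y_p = P(tau) exp(-r tau) with P' + b P = c tau^k
    terms = []
    coef = c
    for j in range(k, -1, -1):
        coef_j = coef / b
        terms.append((coef_j, r, j))
        coef = -coef_j * j
    return terms


def _merge(terms: list[tuple[float, float, int]]
           ) -> list[tuple[float, float, int]]:
    """Combine terms with (nearly) identical rate and power."""
    merged: list[tuple[float, float, int]] = []
    for c, r, k in terms:
        for idx, (c2, r2, k2) in enumerate(merged):
            if k == k2 and abs(r - r2) < _RESONANCE_TOL:
                merged[idx] = (c + c2, r2, k2)
                break
        else:
            merged.append((c, r, k))
    return [t for t in merged if t[0] != 0.0] or [(0.0, 0.0, 0)]
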