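"""Fitting the labeling model to saliva, monocyte and T cell enrichment.

Two backends share one forward model and one prior specification:

* :func:`fit_point` — staged bounded least squares (body water, then
  monocytes per individual, then each T cell series), with an optional
  joint polish.  Deterministic and fast; the workhorse for simulation
  studies and parameter-recovery checks.
* :func:`fit_hierarchical` — a full joint posterior via the affine-
  invariant ensemble sampler (emcee), with the study's hierarchical
  structure: per-series kinetic parameters (p, d*, delay) drawn from
  lognormal population distributions whose hyperparameters are fitted,
  a single body-water turnover rate delta shared by all individuals,
  and per-individual f, b_w, r_2.  The hyperparameter mu_p is shared by
  all lymphocyte populations regardless of subset, genotype or
  infection status, so no between-population structure is imposed on p.

Observation noise is additive Gaussian on enrichment fractions with a
per-compartment standard deviation; replicates are i.i.d.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import validate_enrichment
from .labeling import (BodyWaterModel, LabelingProtocol, MonocyteModel,
                       TcellKinetics)

__all__ = [
    "HierarchicalPriors",
    "FitResult",
    "fit_body_water",
    "fit_point",
    "fit_hierarchical",
    "recovery_report",
]

_LOG_FLOOR = math.log(1e-6)  # proper-prior floor for the mu hyperparameters


@dataclass(frozen=True)
class HierarchicalPriors:
    """Prior supports for the joint model.

    The population means mu_p, mu_d*, mu_delay are uniform up to
    log(0.05), log(1) and log(21) respectively (with a log(1e-6) floor
    to keep them proper); the population scales are uniform on [0, 1];
    b_w and r_2 are uniform on [0, 7] and [0, 10].
    """

    mu_p_bounds: tuple[float, float] = (_LOG_FLOOR, math.log(0.05))
    mu_dstar_bounds: tuple[float, float] = (_LOG_FLOOR, math.log(1.0))
    mu_delay_bounds: tuple[float, float] = (_LOG_FLOOR, math.log(21.0))
    sigma_bounds: tuple[float, float] = (0.0, 1.0)
    b_w_bounds: tuple[float, float] = (0.0, 7.0)
    r_2_bounds: tuple[float, float] = (0.0, 10.0)
    f_bounds: tuple[float, float] = (1e-6, 1 - 1e-6)
    delta_bounds: tuple[float, float] = (1e-4, 1.0)
    # supports for the individual kinetic parameters (point backend bounds;
    # the lognormal population distribution concentrates mass well inside)
    p_bounds: tuple[float, float] = (1e-6, 0.2)
    dstar_bounds: tuple[float, float] = (1e-4, 2.0)
    delay_bounds: tuple[float, float] = (0.0, 21.0)
    log_noise_bounds: tuple[float, float] = (math.log(1e-7), math.log(0.1))


@dataclass
class FitResult:
    """Parameter estimates from either backend.

    ``individuals`` has one row per individual (f, b_w, r_2);
    ``series`` one row per fitted T cell population (p, d_star, delay,
    lifespan = 1/p, half_life = ln2/p), with ``*_lo``/``*_hi`` 95%
    interval columns for the Bayesian backend.  ``converged`` is False
    when an optimiser failed or an MCMC diagnostic exceeded its
    threshold — never a silent success.
    """

    backend: str
    delta: float
    individuals: pd.DataFrame
    series: pd.DataFrame
    hyper: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def lifespan_table(self) -> pd.DataFrame:
        cols = ["individual_id", "subset", "kir_class", "p", "lifespan",
                "half_life"]
        return self.series[cols].copy()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(directory / "individuals.csv", index=False)
        self.series.to_csv(directory / "series.csv", index=False)
        meta = {"backend": self.backend, "delta": self.delta,
                "hyper": self.hyper, "diagnostics": self.diagnostics,
                "converged": self.converged, "seed": self.seed,
                "config": self.config}
        (directory / "fit.json").write_text(json.dumps(meta, indent=2,
                                                       default=float))


# --------------------------------------------------------------------------
# data preparation


def _series_groups(df: pd.DataFrame, compartment: str):
    sub = df[df["compartment"] == compartment]
    out = {}
    for ind, grp in sub.groupby("individual_id", sort=True):
        out[str(ind)] = (grp["time_days"].to_numpy(float),
                         grp["enrichment"].to_numpy(float))
    return out


def _tcell_groups(df: pd.DataFrame):
    sub = df[df["compartment"] == "tcell"]
    out = []
    keys = ["individual_id", "subset", "kir_class"]
    for (ind, subset, kc), grp in sub.groupby(keys, sort=True):
        out.append({"individual_id": str(ind), "subset": subset,
                    "kir_class": kc,
                    "t": grp["time_days"].to_numpy(float),
                    "y": grp["enrichment"].to_numpy(float)})
    return out


# --------------------------------------------------------------------------
# stage 1: body water


def fit_body_water(data: pd.DataFrame,
                   protocol: LabelingProtocol | None = None,
                   priors: HierarchicalPriors | None = None):
    """Fit per-individual f and a single shared delta to saliva series.

    Returns ``(delta, f_by_individual, flags)`` where ``flags`` lists
    warnings (e.g. an f estimate pinned at its lower boundary for an
    all-zero series).
    """
    protocol = protocol or LabelingProtocol()
    priors = priors or HierarchicalPriors()
    saliva = _series_groups(validate_enrichment(data), "saliva")
    if not saliva:
        raise ValueError("no saliva series in the data")
    for ind, (t, _) in saliva.items():
        if np.unique(t).size < 3:
            raise ValueError(f"individual {ind}: need >=3 saliva time points")
    inds = sorted(saliva)

    def resid(x):
        delta = x[0]
        out = []
        for i, ind in enumerate(inds):
            t, y = saliva[ind]
            model = BodyWaterModel(f=x[1 + i], delta=delta, protocol=protocol)
            out.append(model.signal()(t) - y)
        return np.concatenate(out)

    f0 = np.array([min(max(1.5 * y.max(), 1e-4), 0.5)
                   for _, y in (saliva[i] for i in inds)])
    x0 = np.concatenate([[0.06], f0])
    lo = np.concatenate([[priors.delta_bounds[0]],
                         np.full(len(inds), priors.f_bounds[0])])
    hi = np.concatenate([[priors.delta_bounds[1]],
                         np.full(len(inds), priors.f_bounds[1])])
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14)
    flags = []
    if not sol.success:
        flags.append("body-water optimiser did not report success")
    f_by_ind = {}
    for i, ind in enumerate(inds):
        f_hat = float(sol.x[1 + i])
        # degenerate series leave f at the bottom of its support; use a
        # loose threshold because the optimiser stops near, not on, it
        if f_hat <= max(priors.f_bounds[0] * 1.01, 1e-4):
            msg = (f"individual {ind}: f pinned at the lower boundary "
                   "(all-zero or degenerate saliva series?)")
            warnings.warn(msg)
            flags.append(msg)
        f_by_ind[ind] = f_hat
    return float(sol.x[0]), f_by_ind, flags


# --------------------------------------------------------------------------
# stage 2/3 helpers


def _fit_monocyte(t, y, water: BodyWaterModel, priors: HierarchicalPriors):
    plateau = water.plateau()

    def resid(x):
        model = MonocyteModel(b_w=x[0], r_2=x[1])
        return model.blood_signal(water)(t) - y

    b0 = min(max(y.max() / max(plateau, 1e-9), 0.1), 6.9)
    best = None
    for r0 in (0.5, 1.5, 4.0):
        sol = least_squares(resid, [b0, r0],
                            bounds=([priors.b_w_bounds[0], priors.r_2_bounds[0] + 1e-6],
                                    [priors.b_w_bounds[1], priors.r_2_bounds[1]]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    return float(best.x[0]), float(best.x[1]), bool(best.success)


def _fit_tcell_series(t, y, b_w: float, water: BodyWaterModel,
                      priors: HierarchicalPriors):
    s2 = water.plateau()

    def resid(x):
        kin = TcellKinetics(p=x[0], d_star=x[1], delay=x[2])
        return kin.observed_signal(b_w, water)(t) - y

    peak = max(y.max(), 1e-9)
    best = None
    for d0 in (0.01, 0.05):
        p0 = min(max(peak * d0 / max(b_w * s2, 1e-9), 2e-6), 0.1)
        for delay0 in (0.5, 3.0, 8.0):
            sol = least_squares(
                resid, [p0, d0, delay0],
                bounds=(np.array([priors.p_bounds[0], priors.dstar_bounds[0],
                                  priors.delay_bounds[0]]),
                        np.array([priors.p_bounds[1], priors.dstar_bounds[1],
                                  priors.delay_bounds[1]])),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
    return (float(best.x[0]), float(best.x[1]), float(best.x[2]),
            bool(best.success))


# --------------------------------------------------------------------------
# point backend


def fit_point(data: pd.DataFrame,
              priors: HierarchicalPriors | None = None,
              protocol: LabelingProtocol | None = None,
              joint_refine: bool | None = None) -> FitResult:
    """Bounded least-squares point estimates for the full joint model.

    Stages: shared-delta body-water fit, per-individual monocyte fit
    (b_w, r_2), per-series T cell fit (p, d*, delay).  With
    ``joint_refine`` (default for small datasets) a final simultaneous
    least-squares polish over all parameters is run from the staged
    solution.
    """
    priors = priors or HierarchicalPriors()
    protocol = protocol or LabelingProtocol()
    df = validate_enrichment(data)
    tcells = _tcell_groups(df)
    if not tcells:
        raise ValueError("no T cell series in the data")
    mono = _series_groups(df, "monocyte")
    for rec in tcells:
        if rec["individual_id"] not in mono:
            raise ValueError(
                f"T cell series for {rec['individual_id']} lacks a matching "
                "monocyte series")

    delta, f_by_ind, flags = fit_body_water(df, protocol, priors)
    inds = sorted(f_by_ind)
    ok = True

    ind_rows = []
    bw_by_ind, r2_by_ind = {}, {}
    for ind in inds:
        water = BodyWaterModel(f=f_by_ind[ind], delta=delta, protocol=protocol)
        if ind in mono:
            t, y = mono[ind]
            b_w, r_2, success = _fit_monocyte(t, y, water, priors)
            ok &= success
        else:
            b_w, r_2 = math.nan, math.nan
        bw_by_ind[ind], r2_by_ind[ind] = b_w, r_2
        ind_rows.append({"individual_id": ind, "f": f_by_ind[ind],
                         "b_w": b_w, "r_2": r_2})

    series_rows = []
    for rec in tcells:
        ind = rec["individual_id"]
        water = BodyWaterModel(f=f_by_ind[ind], delta=delta, protocol=protocol)
        p, d_star, delay, success = _fit_tcell_series(
            rec["t"], rec["y"], bw_by_ind[ind], water, priors)
        ok &= success
        series_rows.append({"individual_id": ind, "subset": rec["subset"],
                            "kir_class": rec["kir_class"], "p": p,
                            "d_star": d_star, "delay": delay})

    if joint_refine is None:
        joint_refine = len(tcells) <= 8
    if joint_refine:
        delta, ind_rows, series_rows, success = _joint_polish(
            df, protocol, priors, delta, ind_rows, series_rows)
        ok &= success

    series = pd.DataFrame(series_rows)
    series["lifespan"] = 1.0 / series["p"]
    series["half_life"] = math.log(2.0) / series["p"]
    diagnostics = {"flags": flags,
                   "identifiability": _identifiability_flags(series, priors)}
    return FitResult(backend="point", delta=delta,
                     individuals=pd.DataFrame(ind_rows), series=series,
                     diagnostics=diagnostics, converged=ok,
                     config={"joint_refine": joint_refine})


def _identifiability_flags(series: pd.DataFrame,
                           priors: HierarchicalPriors) -> list[str]:
    out = []
    hi = priors.dstar_bounds[1]
    for _, row in series.iterrows():
        if row["d_star"] >= 0.99 * hi:
            msg = (f"series ({row['individual_id']}, {row['subset']}, "
                   f"{row['kir_class']}): d* at its upper support; poorly "
                   "identified")
            warnings.warn(msg)
            out.append(msg)
    return out


def _joint_polish(df, protocol, priors, delta, ind_rows, series_rows):
    """Simultaneous least squares over all parameters from the staged x0."""
    inds = [r["individual_id"] for r in ind_rows]
    saliva = _series_groups(df, "saliva")
    mono = _series_groups(df, "monocyte")
    tcells = _tcell_groups(df)
    n = len(inds)

    def unpack(x):
        return (x[0], x[1:1 + n], x[1 + n:1 + 2 * n], x[1 + 2 * n:1 + 3 * n],
                x[1 + 3 * n:].reshape(-1, 3))

    def resid(x):
        d, fs, bws, r2s, kin = unpack(x)
        out = []
        waters = {}
        for i, ind in enumerate(inds):
            w = BodyWaterModel(f=fs[i], delta=d, protocol=protocol)
            waters[ind] = (w, bws[i])
            if ind in saliva:
                t, y = saliva[ind]
                out.append(w.signal()(t) - y)
            if ind in mono:
                t, y = mono[ind]
                m = MonocyteModel(b_w=bws[i], r_2=r2s[i])
                out.append(m.blood_signal(w)(t) - y)
        for j, rec in enumerate(tcells):
            w, bw = waters[rec["individual_id"]]
            k = TcellKinetics(p=kin[j, 0], d_star=kin[j, 1], delay=kin[j, 2])
            out.append(k.observed_signal(bw, w)(rec["t"]) - rec["y"])
        return np.concatenate(out)

    x0 = np.concatenate(
        [[delta], [r["f"] for r in ind_rows], [r["b_w"] for r in ind_rows],
         [r["r_2"] for r in ind_rows],
         np.array([[r["p"], r["d_star"], r["delay"]] for r in series_rows]
                  ).ravel()])
    lo = np.concatenate(
        [[priors.delta_bounds[0]], np.full(n, priors.f_bounds[0]),
         np.full(n, priors.b_w_bounds[0]), np.full(n, priors.r_2_bounds[0]),
         np.tile([priors.p_bounds[0], priors.dstar_bounds[0],
                  priors.delay_bounds[0]], len(series_rows))])
    hi = np.concatenate(
        [[priors.delta_bounds[1]], np.full(n, priors.f_bounds[1]),
         np.full(n, priors.b_w_bounds[1]), np.full(n, priors.r_2_bounds[1]),
         np.tile([priors.p_bounds[1], priors.dstar_bounds[1],
                  priors.delay_bounds[1]], len(series_rows))])
    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    d, fs, bws, r2s, kin = unpack(sol.x)
    ind_rows = [{"individual_id": ind, "f": float(fs[i]), "b_w": float(bws[i]),
                 "r_2": float(r2s[i])} for i, ind in enumerate(inds)]
    series_rows = [{"individual_id": rec["individual_id"],
                    "subset": rec["subset"], "kir_class": rec["kir_class"],
                    "p": float(kin[j, 0]), "d_star": float(kin[j, 1]),
                    "delay": float(kin[j, 2])}
                   for j, rec in enumerate(tcells)]
    return float(d), ind_rows, series_rows, bool(sol.success)


# --------------------------------------------------------------------------
# hierarchical Bayesian backend (emcee ensemble sampler)


class _JointModel:
    """Log-posterior of the full hierarchical model."""

    def __init__(self, df, protocol, priors):
        self.protocol = protocol
        self.priors = priors
        self.saliva = _series_groups(df, "saliva")
        self.mono = _series_groups(df, "monocyte")
        self.tcells = _tcell_groups(df)
        self.inds = sorted(set(self.saliva) | set(self.mono)
                           | {r["individual_id"] for r in self.tcells})
        self.n = len(self.inds)
        self.m = len(self.tcells)
        self.ind_index = {ind: i for i, ind in enumerate(self.inds)}
        # layout: delta | f (n) | b_w (n) | r_2 (n) | 6 hypers |
        #         log p, log d*, log delay (3m) | 3 log noise sds
        self.ndim = 1 + 3 * self.n + 6 + 3 * self.m + 3

    def unpack(self, x):
        n, m = self.n, self.m
        i = 1 + 3 * n
        hyp = x[i:i + 6]
        kin = x[i + 6:i + 6 + 3 * m].reshape(m, 3)
        sds = np.exp(x[i + 6 + 3 * m:])
        return (x[0], x[1:1 + n], x[1 + n:1 + 2 * n], x[1 + 2 * n:1 + 3 * n],
                hyp, kin, sds)

    def log_prior(self, x):
        pr = self.priors
        delta, fs, bws, r2s, hyp, kin, _ = self.unpack(x)
        mu_p, mu_d, mu_dl, s_p, s_d, s_dl = hyp
        checks = [
            pr.delta_bounds[0] <= delta <= pr.delta_bounds[1],
            np.all((fs >= pr.f_bounds[0]) & (fs <= pr.f_bounds[1])),
            np.all((bws >= pr.b_w_bounds[0]) & (bws <= pr.b_w_bounds[1])),
            np.all((r2s >= pr.r_2_bounds[0]) & (r2s <= pr.r_2_bounds[1])),
            pr.mu_p_bounds[0] <= mu_p <= pr.mu_p_bounds[1],
            pr.mu_dstar_bounds[0] <= mu_d <= pr.mu_dstar_bounds[1],
            pr.mu_delay_bounds[0] <= mu_dl <= pr.mu_delay_bounds[1],
            all(1e-3 <= s <= pr.sigma_bounds[1] for s in (s_p, s_d, s_dl)),
            np.all(kin[:, 2] <= math.log(pr.delay_bounds[1] + 1.0)),
            pr.log_noise_bounds[0] <= x[-3] <= pr.log_noise_bounds[1],
            pr.log_noise_bounds[0] <= x[-2] <= pr.log_noise_bounds[1],
            pr.log_noise_bounds[0] <= x[-1] <= pr.log_noise_bounds[1],
        ]
        if not all(checks):
            return -np.inf
        # hierarchical (lognormal population) terms on the kinetic params
        lp = 0.0
        for col, mu, sd in ((0, mu_p, s_p), (1, mu_d, s_d), (2, mu_dl, s_dl)):
            z = (kin[:, col] - mu) / sd
            lp += -0.5 * np.sum(z * z) - self.m * math.log(sd)
        return lp

    def log_likelihood(self, x):
        delta, fs, bws, r2s, _, kin, sds = self.unpack(x)
        sd_sal, sd_mono, sd_tc = sds
        ll = 0.0
        waters = {}
        try:
            for ind in self.inds:
                i = self.ind_index[ind]
                w = BodyWaterModel(f=fs[i], delta=delta,
                                   protocol=self.protocol)
                waters[ind] = w
                if ind in self.saliva:
                    t, y = self.saliva[ind]
                    r = w.signal()(t) - y
                    ll += _gauss_ll(r, sd_sal)
                if ind in self.mono:
                    t, y = self.mono[ind]
                    m = MonocyteModel(b_w=bws[i], r_2=r2s[i])
                    r = m.blood_signal(w)(t) - y
                    ll += _gauss_ll(r, sd_mono)
            for j, rec in enumerate(self.tcells):
                i = self.ind_index[rec["individual_id"]]
                k = TcellKinetics(p=math.exp(kin[j, 0]),
                                  d_star=math.exp(kin[j, 1]),
                                  delay=math.exp(kin[j, 2]))
                r = k.observed_signal(bws[i], waters[rec["individual_id"]]
                                      )(rec["t"]) - rec["y"]
                ll += _gauss_ll(r, sd_tc)
        except (ValueError, OverflowError):
            return -np.inf
        return ll

    def __call__(self, x):
        lp = self.log_prior(x)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(x)


def _gauss_ll(resid, sd):
    return float(-0.5 * np.sum((resid / sd) ** 2)
                 - resid.size * math.log(sd)
                 - 0.5 * resid.size * math.log(2 * math.pi))


def fit_hierarchical(data: pd.DataFrame,
                     priors: HierarchicalPriors | None = None,
                     protocol: LabelingProtocol | None = None,
                     n_walkers: int | None = None,
                     n_steps: int = 500,
                     n_burn: int | None = None,
                     seed: int = 0,
                     rhat_threshold: float = 1.05,
                     ess_threshold: float = 400.0) -> FitResult:
    """Joint hierarchical posterior over all labeling-model parameters.

    Walkers are initialised around the staged point estimates (a cheap
    analogue of starting chains at the mode) and run with emcee; the
    returned estimates are posterior medians with 2.5/97.5 percentile
    intervals.  Non-convergence (split-R̂ above ``rhat_threshold`` or
    bulk ESS below ``ess_threshold`` for any kinetic parameter) flags
    the result; it never fails silently.
    """
    import arviz as az
    import emcee

    priors = priors or HierarchicalPriors()
    protocol = protocol or LabelingProtocol()
    df = validate_enrichment(data)
    point = fit_point(df, priors, protocol, joint_refine=False)
    model = _JointModel(df, protocol, priors)

    # centre of the walker cloud from the staged point fit
    f0 = point.individuals.set_index("individual_id")
    x0 = np.empty(model.ndim)
    x0[0] = point.delta
    for i, ind in enumerate(model.inds):
        x0[1 + i] = f0.loc[ind, "f"]
        x0[1 + model.n + i] = np.clip(f0.loc[ind, "b_w"], 0.05, 6.95)
        x0[1 + 2 * model.n + i] = np.clip(f0.loc[ind, "r_2"], 0.05, 9.95)
    s0 = point.series.set_index(["individual_id", "subset", "kir_class"])
    logp = np.log(np.clip(
        [s0.loc[(r["individual_id"], r["subset"], r["kir_class"]), "p"]
         for r in model.tcells], 1e-6, None))
    logd = np.log(np.clip(
        [s0.loc[(r["individual_id"], r["subset"], r["kir_class"]), "d_star"]
         for r in model.tcells], 1e-4, None))
    logdl = np.log(np.clip(
        [s0.loc[(r["individual_id"], r["subset"], r["kir_class"]), "delay"]
         for r in model.tcells], 1e-2, None))
    base = 1 + 3 * model.n
    x0[base:base + 6] = [np.clip(logp.mean(), *priors.mu_p_bounds),
                         np.clip(logd.mean(), *priors.mu_dstar_bounds),
                         np.clip(logdl.mean(), *priors.mu_delay_bounds),
                         max(logp.std(), 0.05), max(logd.std(), 0.05),
                         max(logdl.std(), 0.05)]
    x0[base + 6:base + 6 + 3 * model.m] = np.column_stack(
        [logp, logd, logdl]).ravel()
    x0[-3:] = math.log(5e-4)

    rng = np.random.default_rng(seed)
    if n_walkers is None:
        n_walkers = 2 * model.ndim + 2
    if n_burn is None:
        n_burn = n_steps // 2
    if n_burn >= n_steps:
        raise ValueError("n_burn must be smaller than n_steps")
    init = x0[None, :] + 1e-3 * rng.standard_normal((n_walkers, model.ndim))
    init[:, 0] = np.clip(init[:, 0], *priors.delta_bounds)
    # make sure every walker starts inside the prior support
    for w in range(n_walkers):
        while not np.isfinite(model.log_prior(init[w])):
            init[w] = x0 + 1e-4 * rng.standard_normal(model.ndim)

    np.random.seed(seed % (2**32))
    sampler = emcee.EnsembleSampler(n_walkers, model.ndim, model)
    sampler.run_mcmc(init, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)      # (steps, walkers, dim)

    # diagnostics on the kinetic block (the scientific quantities)
    kin_idx = list(range(base + 6, base + 6 + 3 * model.m))
    azdata = az.convert_to_dataset(
        np.moveaxis(chain[:, :, kin_idx], 0, 1))   # (chain, draw, dim)
    rhat = float(az.rhat(azdata)["x"].max())
    ess = float(az.ess(azdata)["x"].min())
    converged = (rhat <= rhat_threshold) and (ess >= ess_threshold)

    flat = chain.reshape(-1, model.ndim)

    def q(ix, transform=lambda v: v):
        v = transform(flat[:, ix])
        return (float(np.median(v)), float(np.percentile(v, 2.5)),
                float(np.percentile(v, 97.5)))

    ind_rows = []
    for i, ind in enumerate(model.inds):
        f_m, f_lo, f_hi = q(1 + i)
        b_m, b_lo, b_hi = q(1 + model.n + i)
        r_m, r_lo, r_hi = q(1 + 2 * model.n + i)
        ind_rows.append({"individual_id": ind, "f": f_m, "f_lo": f_lo,
                         "f_hi": f_hi, "b_w": b_m, "b_w_lo": b_lo,
                         "b_w_hi": b_hi, "r_2": r_m, "r_2_lo": r_lo,
                         "r_2_hi": r_hi})
    series_rows = []
    for j, rec in enumerate(model.tcells):
        row = {"individual_id": rec["individual_id"], "subset": rec["subset"],
               "kir_class": rec["kir_class"]}
        for col, name in ((0, "p"), (1, "d_star"), (2, "delay")):
            m_, lo_, hi_ = q(base + 6 + 3 * j + col, np.exp)
            row[name], row[f"{name}_lo"], row[f"{name}_hi"] = m_, lo_, hi_
        series_rows.append(row)
    series = pd.DataFrame(series_rows)
    series["lifespan"] = 1.0 / series["p"]
    series["half_life"] = math.log(2.0) / series["p"]

    hyper_names = ["mu_p", "mu_dstar", "mu_delay", "sigma_p", "sigma_dstar",
                   "sigma_delay"]
    hyper = {name: q(base + k)[0] for k, name in enumerate(hyper_names)}
    noise = {name: float(np.median(np.exp(flat[:, -3 + k])))
             for k, name in enumerate(["sd_saliva", "sd_monocyte",
                                       "sd_tcell"])}
    delta_m = q(0)[0]
    diagnostics = {"rhat_max": rhat, "ess_min": ess,
                   "acceptance_fraction": float(
                       np.mean(sampler.acceptance_fraction)),
                   "noise": noise}
    if not converged:
        warnings.warn(
            f"hierarchical fit flagged: rhat_max={rhat:.3f}, "
            f"ess_min={ess:.0f}")
    return FitResult(backend="hierarchical", delta=delta_m,
                     individuals=pd.DataFrame(ind_rows), series=series,
                     hyper=hyper, diagnostics=diagnostics,
                     converged=converged, seed=seed,
                     config={"n_walkers": n_walkers, "n_steps": n_steps,
                             "n_burn": n_burn})


# --------------------------------------------------------------------------
# recovery report


def recovery_report(truth: pd.DataFrame, fit: FitResult,
                    params: tuple[str, ...] = ("p", "d_star", "delay")
                    ) -> pd.DataFrame:
    """Bias / relative RMSE (and interval coverage, if available) of a fit
    against a generator truth table.

    ``truth`` must carry the same key columns as the fitted series table
    (individual_id, subset, kir_class) plus one column per parameter.
    """
    keys = ["individual_id", "subset", "kir_class"]
    est = fit.series
    merged = truth.merge(est, on=keys, suffixes=("_true", ""),
                         how="inner")
    if len(merged) != len(truth) or len(merged) != len(est):
        raise ValueError("truth and estimates are not keyed identically")
    rows = []
    for name in params:
        tcol, ecol = f"{name}_true", name
        if tcol not in merged or ecol not in merged:
            continue
        err = merged[ecol] - merged[tcol]
        rel = err / merged[tcol]
        row = {"parameter": name, "bias": float(err.mean()),
               "rmse": float(np.sqrt((err ** 2).mean())),
               "relative_rmse": float(np.sqrt((rel ** 2).mean()))}
        lo, hi = f"{name}_lo", f"{name}_hi"
        if lo in merged.columns and hi in merged.columns:
            inside = ((merged[tcol] >= merged[lo])
                      & (merged[tcol] <= merged[hi]))
            row["coverage"] = float(inside.mean())
        rows.append(row)
    return pd.DataFrame(rows)
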