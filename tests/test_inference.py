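"""Parameter inference: staged point fits, hierarchical sampler, reports."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ikirspan import (BodyWaterModel, LabelingProtocol, MonocyteModel,
                      TcellKinetics, fit_body_water, fit_hierarchical,
                      fit_point, generate_cohort, generate_labeling_data,
                      get_preset, monocyte_enrichment, recovery_report,
                      saliva_enrichment, tcell_enrichment)

SALIVA_T = np.array([0.0, 2.0, 5.0, 7.0, 14.0, 21.0, 35.0, 49.0, 63.0,
                     84.0, 112.0])
BLOOD_T = np.array([7.0, 14.0, 21.0, 35.0, 49.0, 63.0, 84.0, 112.0])


def _dataset(individuals, noise=0.0, rng=None, replicates=1):
    """Build an enrichment table from explicit generative parameters.

    ``individuals`` maps id -> dict(f, delta, b_w, r_2, series=[(subset,
    kir_class, p, d_star, delay), ...]).
    """
    proto = LabelingProtocol()
    rows = []

    def emit(ind, compartment, subset, kir_class, t, y):
        for rep in range(1, replicates + 1):
            obs = y if noise == 0 else np.clip(
                y + rng.normal(0.0, noise, y.shape), 0.0, None)
            for ti, yi in zip(t, obs):
                rows.append({"individual_id": ind,
                             "compartment": compartment, "subset": subset,
                             "kir_class": kir_class, "time_days": ti,
                             "enrichment": yi, "replicate": rep})

    for ind, spec in individuals.items():
        water = BodyWaterModel(f=spec["f"], delta=spec["delta"],
                               protocol=proto)
        emit(ind, "saliva", "none", "none", SALIVA_T,
             saliva_enrichment(SALIVA_T, water))
        mono = MonocyteModel(b_w=spec["b_w"], r_2=spec["r_2"])
        emit(ind, "monocyte", "none", "none", BLOOD_T,
             monocyte_enrichment(BLOOD_T, mono, water))
        for subset, kir_class, p, d_star, delay in spec.get("series", []):
            kin = TcellKinetics(p=p, d_star=d_star, delay=delay)
            emit(ind, "tcell", subset, kir_class, BLOOD_T,
                 tcell_enrichment(BLOOD_T, kin, spec["b_w"], water))
    return pd.DataFrame(rows)


BASE = {"f": 0.02, "delta": 0.06, "b_w": 4.0, "r_2": 1.5,
        "series": [("Tcm", "functional", 0.005, 0.02, 3.0)]}


# --------------------------------------------------------------------------
# body water


def test_body_water_noise_free_recovery():
    spec = dict(BASE, f=0.02, delta=0.035, series=[])
    data = _dataset({"P1": spec})
    delta, f_by_ind, flags = fit_body_water(data)
    assert delta == pytest.approx(0.035, rel=1e-3)
    assert f_by_ind["P1"] == pytest.approx(0.02, rel=1e-3)
    assert flags == []


def test_body_water_shared_delta_two_individuals():
    rng = np.random.default_rng(21)
    data = _dataset({"P1": dict(BASE, f=0.015, series=[]),
                     "P2": dict(BASE, f=0.025, series=[])},
                    noise=1e-4, rng=rng, replicates=3)
    delta, f_by_ind, _ = fit_body_water(data)
    assert delta == pytest.approx(0.06, rel=0.01)
    assert f_by_ind["P1"] == pytest.approx(0.015, rel=0.02)
    assert f_by_ind["P2"] == pytest.approx(0.025, rel=0.02)


def test_body_water_all_zero_series_flagged():
    data = _dataset({"P1": dict(BASE, series=[])})
    data["enrichment"] = 0.0
    with pytest.warns(UserWarning, match="lower boundary"):
        delta, f_by_ind, flags = fit_body_water(data)
    assert flags


def test_body_water_input_errors():
    data = _dataset({"P1": dict(BASE, series=[])})
    with pytest.raises(ValueError):
        fit_body_water(data[data["compartment"] != "saliva"])
    short = data[data["compartment"].eq("saliva")
                 & data["time_days"].isin([0.0, 2.0])]
    with pytest.raises(ValueError):
        fit_body_water(short)


# --------------------------------------------------------------------------
# point backend


def test_point_noise_free_single_series():
    fit = fit_point(_dataset({"P1": BASE}))
    row = fit.series.iloc[0]
    assert row["p"] == pytest.approx(0.005, rel=0.01)
    assert row["d_star"] == pytest.approx(0.02, rel=0.01)
    assert row["delay"] == pytest.approx(3.0, rel=0.01)
    assert fit.converged


def test_point_noise_free_full_recovery():
    individuals = {
        "P1": dict(BASE, f=0.018, b_w=3.5,
                   series=[("Tcm", "functional", 0.006, 0.03, 2.0),
                           ("Temra", "negative", 0.012, 0.05, 6.0)]),
        "P2": dict(BASE, f=0.023, r_2=1.2,
                   series=[("Tcm", "nonfunctional", 0.004, 0.015, 4.0)]),
    }
    fit = fit_point(_dataset(individuals))
    assert fit.delta == pytest.approx(0.06, rel=0.01)
    inds = fit.individuals.set_index("individual_id")
    assert inds.loc["P1", "f"] == pytest.approx(0.018, rel=0.01)
    assert inds.loc["P1", "b_w"] == pytest.approx(3.5, rel=0.01)
    assert inds.loc["P2", "r_2"] == pytest.approx(1.2, rel=0.01)
    truth = pd.DataFrame([
        {"individual_id": "P1", "subset": "Tcm", "kir_class": "functional",
         "p": 0.006, "d_star": 0.03, "delay": 2.0},
        {"individual_id": "P1", "subset": "Temra", "kir_class": "negative",
         "p": 0.012, "d_star": 0.05, "delay": 6.0},
        {"individual_id": "P2", "subset": "Tcm",
         "kir_class": "nonfunctional", "p": 0.004, "d_star": 0.015,
         "delay": 4.0},
    ])
    report = recovery_report(truth, fit)
    assert (report.set_index("parameter")["relative_rmse"] < 0.01).all()


def test_point_lifespan_identities():
    fit = fit_point(_dataset({"P1": BASE}))
    for _, row in fit.series.iterrows():
        assert row["lifespan"] == 1.0 / row["p"]
        assert row["half_life"] == math.log(2.0) / row["p"]
    table = fit.lifespan_table()
    assert set(table.columns) == {"individual_id", "subset", "kir_class",
                                  "p", "lifespan", "half_life"}


def test_point_respects_prior_supports():
    rng = np.random.default_rng(33)
    data = _dataset({"P1": BASE}, noise=5e-4, rng=rng, replicates=3)
    fit = fit_point(data)
    inds = fit.individuals
    assert inds["b_w"].between(0.0, 7.0).all()
    assert inds["r_2"].between(0.0, 10.0).all()
    assert fit.series["p"].gt(0).all()
    assert fit.series["delay"].between(0.0, 21.0).all()


def test_point_input_errors():
    no_tcell = _dataset({"P1": dict(BASE, series=[])})
    with pytest.raises(ValueError):
        fit_point(no_tcell)
    data = _dataset({"P1": BASE})
    no_mono = data[data["compartment"] != "monocyte"]
    with pytest.raises(ValueError):
        fit_point(no_mono)


# --------------------------------------------------------------------------
# recovery report


def _toy_fit(series: pd.DataFrame):
    from ikirspan import FitResult
    series = series.copy()
    series["lifespan"] = 1.0 / series["p"]
    series["half_life"] = math.log(2.0) / series["p"]
    return FitResult(backend="point", delta=0.06,
                     individuals=pd.DataFrame(), series=series)


def test_recovery_report_identity_and_bias():
    truth = pd.DataFrame([
        {"individual_id": "P1", "subset": "Tcm", "kir_class": "functional",
         "p": 0.005, "d_star": 0.02, "delay": 3.0}])
    est = truth.copy()
    report = recovery_report(truth, _toy_fit(est)).set_index("parameter")
    assert (report["bias"] == 0).all() and (report["rmse"] == 0).all()
    shifted = truth.copy()
    shifted[["p", "d_star", "delay"]] -= 0.1     # truth = estimate - 0.1
    report = recovery_report(shifted, _toy_fit(est)).set_index("parameter")
    assert report["bias"].to_numpy() == pytest.approx(0.1)


def test_recovery_report_key_mismatch():
    truth = pd.DataFrame([
        {"individual_id": "P9", "subset": "Tcm", "kir_class": "functional",
         "p": 0.005, "d_star": 0.02, "delay": 3.0}])
    est = truth.assign(individual_id="P1")
    with pytest.raises(ValueError):
        recovery_report(truth, _toy_fit(est))


def test_recovery_report_rmse_matches_analytic():
    rng = np.random.default_rng(17)
    n = 100
    sigma = 0.001
    truth = pd.DataFrame({
        "individual_id": [f"P{i}" for i in range(n)],
        "subset": "Tcm", "kir_class": "functional",
        "p": 0.005, "d_star": 0.02, "delay": 3.0})
    est = truth.copy()
    est["p"] = truth["p"] + rng.normal(0.0, sigma, n)
    report = recovery_report(truth, _toy_fit(est)).set_index("parameter")
    assert report.loc["p", "rmse"] == pytest.approx(sigma, rel=0.2)


# --------------------------------------------------------------------------
# hierarchical backend


def test_hierarchical_smoke_and_backend_agreement():
    rng = np.random.default_rng(55)
    data = _dataset({"P1": BASE}, noise=2e-4, rng=rng, replicates=3)
    point = fit_point(data)
    bayes = fit_hierarchical(data, n_steps=400, n_burn=200, seed=1)
    assert bayes.backend == "hierarchical"
    # supports respected in the summary
    assert bayes.individuals["b_w"].between(0.0, 7.0).all()
    assert bayes.individuals["r_2"].between(0.0, 10.0).all()
    # interval columns exist and bracket the median
    row = bayes.series.iloc[0]
    assert row["p_lo"] <= row["p"] <= row["p_hi"]
    # point estimates and posterior medians agree on low-noise data
    assert row["p"] == pytest.approx(point.series.iloc[0]["p"], rel=0.10)
    # diagnostics are reported either way
    assert "rhat_max" in bayes.diagnostics


def test_hierarchical_more_replicates_narrow_intervals():
    import warnings as _warnings
    narrower = []
    for seed in (1, 2):
        widths = {}
        for reps in (2, 4):
            rng = np.random.default_rng(100 + seed)
            data = _dataset({"P1": BASE}, noise=5e-4, rng=rng,
                            replicates=reps)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fit = fit_hierarchical(data, n_steps=400, n_burn=200,
                                       seed=seed)
            row = fit.series.iloc[0]
            widths[reps] = float(row["p_hi"] - row["p_lo"])
        narrower.append(widths[4] < widths[2])
    assert all(narrower)
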