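"""Association statistics: Wilcoxon, regressions, J test, CD57."""

from __future__ import annotations

import itertools
import json
import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ikirspan import (adjusted_lifespan, between_individual_regression,
                      cd57_regression, compare_nonnested,
                      ikir_expression_regression, permutation_threshold,
                      within_individual_test)


def _paired_frame(pairs, subset="Tcm"):
    rows = []
    for i, (func, nonfunc) in enumerate(pairs):
        rows.append({"individual_id": f"P{i}", "subset": subset,
                     "kir_class": "functional", "lifespan": func})
        rows.append({"individual_id": f"P{i}", "subset": subset,
                     "kir_class": "nonfunctional", "lifespan": nonfunc})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# within-individual Wilcoxon


def test_wilcoxon_identical_pairs():
    res = within_individual_test(_paired_frame([(100, 100), (90, 90)]))
    assert res.p_value == 1.0


def test_wilcoxon_frozen_five_pairs():
    pairs = [(100, 90), (110, 95), (120, 100), (130, 105), (140, 110)]
    res = within_individual_test(_paired_frame(pairs))
    # exhaustive enumeration over the 2^5 sign assignments gives 2/32
    assert res.p_value == pytest.approx(0.0625)
    assert res.method == "exact"


def test_wilcoxon_single_pair():
    res = within_individual_test(_paired_frame([(100, 90)]))
    assert res.p_value == 1.0


def _enumeration_pvalue(diffs):
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    stats_all = np.array([
        ranks[np.array(signs) > 0].sum()
        for signs in itertools.product([1, -1], repeat=d.size)])
    return float(np.mean(np.abs(stats_all - mean)
                         >= abs(w_obs - mean) - 1e-12))


def test_wilcoxon_matches_enumeration_small_n():
    rng = np.random.default_rng(5)
    for trial in range(25):
        n = int(rng.integers(2, 11))
        # continuous draws: untied ranks, matching the exact null
        diffs = rng.normal(0.0, 10.0, n)
        pairs = [(100 + d, 100.0) for d in diffs]
        res = within_individual_test(_paired_frame(pairs))
        assert res.p_value == pytest.approx(_enumeration_pvalue(diffs),
                                            abs=1e-12)


def test_wilcoxon_negative_fallback_and_exclusion():
    df = pd.DataFrame([
        {"individual_id": "P0", "subset": "Tcm", "kir_class": "functional",
         "lifespan": 120.0},
        {"individual_id": "P0", "subset": "Tcm", "kir_class": "negative",
         "lifespan": 100.0},
        {"individual_id": "P1", "subset": "Tcm", "kir_class": "functional",
         "lifespan": 90.0},
        {"individual_id": "P1", "subset": "Tcm", "kir_class": "nonfunctional",
         "lifespan": 95.0},
    ])
    assert within_individual_test(df).n_pairs == 2
    assert within_individual_test(df, exclude_negative=True).n_pairs == 1
    with pytest.raises(ValueError):
        within_individual_test(df[df["kir_class"] == "functional"])


# --------------------------------------------------------------------------
# between-individual regression


def _constructed_records(beta=0.41, n=24):
    rng = np.random.default_rng(2)
    rows = []
    subsets = {"Tcm": 0.0, "Temra": 0.25}
    infections = {"uninfected": 0.0, "HIV-1": -0.35, "HCV": -0.15}
    for i in range(n):
        count = i % 5
        subset = ["Tcm", "Temra"][i % 2]
        infection = ["uninfected", "HIV-1", "HCV"][i % 3]
        log_ls = (4.5 + beta * count + subsets[subset]
                  + infections[infection])
        rows.append({"individual_id": f"P{i}", "subset": subset,
                     "kir_class": "functional", "infection": infection,
                     "functional_count": count,
                     "lifespan": math.exp(log_ls)})
    return pd.DataFrame(rows)


def test_regression_exact_recovery():
    records = _constructed_records(beta=0.41)
    fit = between_individual_regression(records)
    assert fit.coef("functional_count") == pytest.approx(0.41, abs=1e-12)


def test_regression_constant_predictor_rejected():
    records = _constructed_records()
    records["functional_count"] = 2
    with pytest.raises(ValueError):
        between_individual_regression(records)


def test_regression_other_predictors():
    records = _constructed_records()
    records["inhibitory_score"] = records["functional_count"] * 1.5
    records["raw_ikir_count"] = records["functional_count"]
    fit = between_individual_regression(records, "inhibitory_score")
    assert fit.coef("inhibitory_score") == pytest.approx(0.41 / 1.5,
                                                         abs=1e-10)
    with pytest.raises(ValueError):
        between_individual_regression(records, "lifespan")


# --------------------------------------------------------------------------
# adjusted lifespans


def test_adjusted_lifespan_baseline_identity():
    records = _constructed_records()
    fit = between_individual_regression(records)
    adj = adjusted_lifespan(records, fit)
    base = records[(records["subset"] == "Tcm")
                   & (records["infection"] == "uninfected")]
    assert np.allclose(adj[base.index], base["lifespan"], rtol=1e-10)


def test_adjusted_lifespan_inverts_offsets():
    records = _constructed_records()
    fit = between_individual_regression(records)
    adj = adjusted_lifespan(records, fit)
    hiv = records[records["infection"] == "HIV-1"]
    # exact construction: HIV offset -0.35, Temra offset +0.25
    for idx, row in hiv.iterrows():
        expected = row["lifespan"] / math.exp(-0.35)
        if row["subset"] == "Temra":
            expected /= math.exp(0.25)
        assert adj[idx] == pytest.approx(expected, rel=1e-9)


def test_adjusted_lifespan_preserves_ranks():
    records = _constructed_records()
    fit = between_individual_regression(records)
    adj = adjusted_lifespan(records, fit)
    stratum = records[(records["subset"] == "Temra")
                      & (records["infection"] == "HCV")]
    raw_order = stratum["lifespan"].rank()
    adj_order = adj[stratum.index].rank()
    assert (raw_order == adj_order).all()


# --------------------------------------------------------------------------
# Davidson-MacKinnon J test


def _jtest_frame(n=500, seed=3):
    rng = np.random.default_rng(seed)
    x_true = rng.normal(size=n)
    x_noise = rng.normal(size=n)
    y = 2.0 + 1.5 * x_true + rng.normal(scale=0.5, size=n)
    return pd.DataFrame({"y": y, "x_true": x_true, "x_noise": x_noise})


def test_jtest_directional_behavior():
    df = _jtest_frame()
    res = compare_nonnested(df, "y", ["x_true"], ["x_noise"])
    assert res.p_a_in_b < 0.01     # true model adds signal to noise model
    assert res.p_b_in_a > 0.1      # noise model adds nothing


def test_jtest_swap_symmetry():
    df = _jtest_frame()
    ab = compare_nonnested(df, "y", ["x_true"], ["x_noise"])
    ba = compare_nonnested(df, "y", ["x_noise"], ["x_true"])
    assert ab.p_a_in_b == pytest.approx(ba.p_b_in_a)
    assert ab.p_b_in_a == pytest.approx(ba.p_a_in_b)


def test_jtest_identical_specs_degenerate():
    df = _jtest_frame()
    with pytest.raises(ValueError):
        compare_nonnested(df, "y", ["x_true"], ["x_true"])


def test_jtest_collinear_fitted_values_flagged():
    df = _jtest_frame(n=60)
    df["x_copy"] = 2.0 * df["x_true"]   # same column space, different spec
    with pytest.raises(ValueError):
        compare_nonnested(df, "y", ["x_true"], ["x_copy"])


def test_jtest_matches_R_lmtest():
    df = _jtest_frame(n=40, seed=9)
    ours = compare_nonnested(df, "y", ["x_true"], ["x_noise"])
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lmtest))
        d <- read.csv("{csv}")
        j <- jtest(lm(y ~ x_true, data=d), lm(y ~ x_noise, data=d))
        cat(j[1, "Pr(>|t|)"], j[2, "Pr(>|t|)"], sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
    p_m1_fit2, p_m2_fit1 = [float(v) for v in out.stdout.split()]
    # R row 1 is "M1 + fitted(M2)": model B's fit added to model A
    assert ours.p_b_in_a == pytest.approx(p_m1_fit2, rel=1e-6)
    assert ours.p_a_in_b == pytest.approx(p_m2_fit1, rel=1e-6)


# --------------------------------------------------------------------------
# CD57 regression


def _cd57_frame(beta=0.03, noise=0.0, n=63, seed=4):
    rng = np.random.default_rng(seed)
    rows = []
    baselines = {"naive_Tscm": 0.10, "early_Tcm": 0.12, "late_Tcm": 0.15,
                 "Tem": 0.30, "Temra": 0.40}
    for i in range(n):
        count = int(rng.integers(0, 5))
        age = float(rng.uniform(60, 91))
        cmv = bool(rng.random() < 0.6)
        for subset, base in baselines.items():
            frac = (base + beta * count + 0.002 * (age - 75)
                    + 0.03 * cmv + rng.normal(0.0, noise))
            rows.append({"individual_id": f"P{i}", "subset": subset,
                         "lineage": "CD8", "fraction_cd57": frac,
                         "age": age, "cmv": cmv,
                         "functional_count": count})
    return pd.DataFrame(rows)


def test_cd57_exact_recovery_noise_free():
    fit = cd57_regression(_cd57_frame(beta=0.03))
    assert fit.coef("functional_count") == pytest.approx(0.03, abs=1e-12)
    assert fit.coef("age") == pytest.approx(0.002, abs=1e-12)


def test_cd57_subset_filter():
    df = _cd57_frame(beta=0.03)
    fit = cd57_regression(df, subset_filter=("Tem", "Temra"))
    assert fit.coef("functional_count") == pytest.approx(0.03, abs=1e-10)
    with pytest.raises(ValueError):
        cd57_regression(df, subset_filter=("nonexistent",))


# --------------------------------------------------------------------------
# iKIR expression determinants


def _expression_frame(n=400, seed=6, effect=0.6):
    rng = np.random.default_rng(seed)
    diff = rng.integers(1, 6, n)
    df = pd.DataFrame({
        "differentiation": diff,
        "lineage": rng.choice(["CD4", "CD8"], n),
        "ikir": rng.choice(["KIR2DL1", "KIR2DL2/L3", "KIR3DL1"], n),
        "age": rng.uniform(20, 80, n),
        "sex": rng.choice(["F", "M"], n),
        "cmv": rng.random(n) < 0.5,
        "infection": rng.choice(["uninfected", "HIV-1"], n),
    })
    logit_mu = -3.0 + effect * df["differentiation"]
    frac = 1.0 / (1.0 + np.exp(-(logit_mu + rng.normal(0, 0.4, n))))
    df["fraction_positive"] = frac
    return df


def test_expression_regression_detects_differentiation_only():
    fit = ikir_expression_regression(_expression_frame())
    pv = fit.pvalues
    assert pv["differentiation"] < 0.01
    others = [name for name in pv.index
              if name != "Intercept" and "differentiation" not in name]
    assert all(pv[name] > 0.01 for name in others)


def test_expression_regression_permuted_response_null():
    df = _expression_frame(n=200, seed=7)
    rng = np.random.default_rng(8)
    n_sig = 0
    for _ in range(100):
        perm = df.copy()
        perm["fraction_positive"] = rng.permutation(
            df["fraction_positive"].to_numpy())
        fit = ikir_expression_regression(perm)
        pv = fit.pvalues.drop("Intercept")
        n_sig += int((pv < 0.01).any())
    # with m ~ 8 coefficient tests per dataset, the chance that any is
    # below 0.01 under the null is ~1-(0.99)^8 = 7.7%; bound at the
    # 99.9th percentile of Binomial(100, 0.077)
    assert n_sig <= 18


def test_expression_regression_duplication_invariance():
    df = _expression_frame(n=150, seed=10)
    fit1 = ikir_expression_regression(df)
    fit2 = ikir_expression_regression(pd.concat([df, df],
                                                ignore_index=True))
    assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(),
                       rtol=1e-8)


def test_expression_regression_constant_covariate_warns():
    df = _expression_frame(n=100, seed=11)
    df["cmv"] = True
    with pytest.warns(UserWarning, match="cmv"):
        ikir_expression_regression(df)


def test_expression_regression_stepwise_selects_signal():
    fit = ikir_expression_regression(_expression_frame(), stepwise=True)
    assert "differentiation" in fit.params.index


def test_permutation_threshold_is_below_alpha():
    df = _expression_frame(n=150, seed=12)

    def fit_fn(frame):
        return ikir_expression_regression(frame)

    thr = permutation_threshold(df.assign(y=df["fraction_positive"]),
                                fit_fn, n_hypotheses=5, n_permutations=50,
                                alpha=0.05, seed=13,
                                response="fraction_positive")
    assert 0.0 < thr < 0.05


# --------------------------------------------------------------------------
# null-effect uniformity (generator + regression, reduced size)


def test_null_effect_pvalues_uniform():
    from ikirspan import generate_cohort, generate_labeling_data, get_preset

    import dataclasses
    cfg = get_preset("null-effect")
    cfg = dataclasses.replace(cfg, replicates=1)
    pvals = []
    for seed in range(200):
        cohort = generate_cohort(cfg, seed=seed)
        lab = generate_labeling_data(cohort, cfg, seed=seed)
        truth = lab["truth_series"]
        fit = between_individual_regression(truth)
        pvals.append(float(fit.pvalues["functional_count"]))
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
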