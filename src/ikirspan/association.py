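"""Association statistics linking genotype, lifespan and immunophenotype.

Implements the study's statistical battery:

* within-individual paired comparison of functional- vs nonfunctional-
  iKIR-expressing T cell lifespans (exact Wilcoxon signed-rank);
* between-individual log-linear regression of lifespan on the
  iKIR-ligand gene-pair count with cell-subset and infection covariates;
* covariate-adjusted lifespans on the uninfected-Tcm baseline scale;
* Davidson-MacKinnon J test for non-nested predictor comparisons
  (pair count vs inhibitory score vs ligand-blind iKIR count);
* multivariate regression of CD57-positive fractions on the functional
  iKIR count, CMV, age and differentiation state;
* determinants-of-iKIR-expression regression on logit-transformed
  positive fractions.

Lifespans are modelled on the natural-log scale: a coefficient beta per
gene pair multiplies lifespan by e^beta per additional pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "PairedTestResult",
    "RegressionResult",
    "JTestResult",
    "within_individual_test",
    "between_individual_regression",
    "adjusted_lifespan",
    "compare_nonnested",
    "cd57_regression",
    "ikir_expression_regression",
    "permutation_threshold",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    method: str


@dataclass(frozen=True)
class RegressionResult:
    """A coefficient table plus the underlying statsmodels fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    n_obs: int
    model: object

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.params, "se": self.bse,
                            "p": self.pvalues})
        out[["ci_lo", "ci_hi"]] = self.conf_int
        return out


@dataclass(frozen=True)
class JTestResult:
    """Both directions of the Davidson-MacKinnon J procedure.

    ``p_a_in_b``: significance of model A's fitted values added to model
    B (small p => A captures signal B misses); ``p_b_in_a`` vice versa.
    """

    t_a_in_b: float
    p_a_in_b: float
    t_b_in_a: float
    p_b_in_a: float


# --------------------------------------------------------------------------
# within-individual paired test


def within_individual_test(records: pd.DataFrame,
                           exclude_negative: bool = False
                           ) -> PairedTestResult:
    """Paired two-tailed Wilcoxon signed-rank test of functional-iKIR
    expression on lifespan within (individual, subset).

    Each functional series is paired with the matched nonfunctional
    series of the same individual and subset, falling back to the
    iKIR-negative series when no nonfunctional one exists (disabled by
    ``exclude_negative``).  Zero differences are dropped (signed-rank
    convention); the exact null distribution is used for n <= 25 and
    the normal approximation with continuity correction above.
    """
    required = {"individual_id", "subset", "kir_class", "lifespan"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    func, other = [], []
    for (ind, subset), grp in records.groupby(["individual_id", "subset"]):
        by_class = {k: g["lifespan"].mean()
                    for k, g in grp.groupby("kir_class")}
        if "functional" not in by_class:
            continue
        if "nonfunctional" in by_class:
            partner = by_class["nonfunctional"]
        elif "negative" in by_class and not exclude_negative:
            partner = by_class["negative"]
        else:
            continue
        func.append(by_class["functional"])
        other.append(partner)
    if not func:
        raise ValueError("no functional/non-functional pairs in the records")
    diffs = np.asarray(func) - np.asarray(other)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return PairedTestResult(statistic=0.0, p_value=1.0,
                                n_pairs=len(diffs), method="degenerate")
    method = "exact" if nonzero.size <= EXACT_WILCOXON_MAX_N else "approx"
    res = stats.wilcoxon(diffs, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return PairedTestResult(statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)),
                            n_pairs=len(diffs), method=method)


# --------------------------------------------------------------------------
# between-individual regression


_PREDICTORS = ("functional_count", "inhibitory_score", "raw_ikir_count")


def _lifespan_formula(predictor: str, extra_covariates=()) -> str:
    terms = [predictor, "C(subset)", "C(infection)"]
    terms += list(extra_covariates)
    return "np.log(lifespan) ~ " + " + ".join(terms)


def between_individual_regression(records: pd.DataFrame,
                                  predictor: str = "functional_count",
                                  extra_covariates: tuple = ()
                                  ) -> RegressionResult:
    """OLS of log(lifespan) on a genotype predictor with cell-subset and
    infection-status covariates.

    ``predictor`` is one of ``functional_count`` (iKIR-ligand gene
    pairs), ``inhibitory_score`` or ``raw_ikir_count``; optional extras
    (age, sex, cmv, ...) may be appended.  The returned coefficient is
    per predictor unit on the natural-log-days scale.
    """
    if predictor not in _PREDICTORS:
        raise ValueError(f"predictor must be one of {_PREDICTORS}")
    if records[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has no contrast")
    fit = smf.ols(_lifespan_formula(predictor, extra_covariates),
                  data=records).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        warnings.warn("collinear design; coefficients are not unique")
    return RegressionResult(params=fit.params, bse=fit.bse,
                            pvalues=fit.pvalues, conf_int=fit.conf_int(),
                            n_obs=int(fit.nobs), model=fit)


def adjusted_lifespan(records: pd.DataFrame, fit: RegressionResult
                      ) -> pd.Series:
    """Covariate-adjusted lifespans on the uninfected-Tcm baseline scale.

    Removes the fitted subset and infection effects from each raw
    lifespan (division by e^effect), so individuals become comparable as
    if all series were Tcm cells from uninfected donors.  Levels the
    model never saw raise.
    """
    params = fit.params
    fitted_frame = fit.model.model.data.frame
    adj = np.log(records["lifespan"].to_numpy(float))
    baselines = {"subset": "Tcm", "infection": "uninfected"}
    for col, baseline in baselines.items():
        prefix = f"C({col})[T."
        effects = {name[len(prefix):-1]: float(val)
                   for name, val in params.items()
                   if name.startswith(prefix)}
        seen = set(fitted_frame[col].unique())
        # the model's (alphabetical) reference level carries effect 0
        effects.update({lvl: 0.0 for lvl in seen - set(effects)})
        ref = effects.get(baseline, 0.0)
        for i, level in enumerate(records[col]):
            if level not in effects:
                raise ValueError(f"unseen {col} level {level!r} in "
                                 "adjustment")
            adj[i] -= effects[level] - ref
    return pd.Series(np.exp(adj), index=records.index,
                     name="adjusted_lifespan")


# --------------------------------------------------------------------------
# Davidson-MacKinnon J test


def compare_nonnested(records: pd.DataFrame, response: str,
                      predictors_a: list[str], predictors_b: list[str],
                      log_response: bool = False) -> JTestResult:
    """Davidson-MacKinnon J test between two non-nested linear models.

    Model A's fitted values are added as a regressor to model B and
    vice versa; each direction reports the t statistic and two-tailed p
    of the added-fit coefficient.  Identical specifications (or
    collinear fitted values) are degenerate and raise.
    """
    if set(predictors_a) == set(predictors_b):
        raise ValueError("model specifications are identical (nested J test "
                         "is degenerate)")
    y = records[response].to_numpy(float)
    if log_response:
        y = np.log(y)

    def design(cols):
        parts = []
        for c in cols:
            v = records[c]
            if v.dtype == object or str(v.dtype) == "category" \
                    or v.dtype == bool:
                parts.append(pd.get_dummies(v, prefix=c, drop_first=True,
                                            dtype=float))
            else:
                parts.append(v.astype(float).rename(c).to_frame())
        X = pd.concat(parts, axis=1)
        return sm.add_constant(X.to_numpy(float))

    Xa, Xb = design(predictors_a), design(predictors_b)
    fit_a = sm.OLS(y, Xa).fit()
    fit_b = sm.OLS(y, Xb).fit()

    def augment(X_host, fitted_other):
        X_aug = np.column_stack([X_host, fitted_other])
        if np.linalg.matrix_rank(X_aug) < X_aug.shape[1]:
            raise ValueError("fitted values are collinear with the host "
                             "model; J test is degenerate")
        fit = sm.OLS(y, X_aug).fit()
        return float(fit.tvalues[-1]), float(fit.pvalues[-1])

    t_a_in_b, p_a_in_b = augment(Xb, fit_a.fittedvalues)
    t_b_in_a, p_b_in_a = augment(Xa, fit_b.fittedvalues)
    return JTestResult(t_a_in_b=t_a_in_b, p_a_in_b=p_a_in_b,
                       t_b_in_a=t_b_in_a, p_b_in_a=p_b_in_a)


# --------------------------------------------------------------------------
# CD57 regression


def cd57_regression(records: pd.DataFrame,
                    subset_filter: tuple | None = None,
                    lineage: str | None = "CD8") -> RegressionResult:
    """Multivariate linear regression of CD57-positive fractions.

    Response: ``fraction_cd57``; predictors: functional iKIR gene count,
    CMV serostatus, age, and cell differentiation state (as subset
    categories).  ``subset_filter`` restricts to e.g. ("Tem", "Temra");
    ``lineage`` selects CD8 (default), CD4, or both (None).
    """
    df = records
    if lineage is not None:
        df = df[df["lineage"] == lineage]
    if subset_filter is not None:
        df = df[df["subset"].isin(subset_filter)]
    if df.empty:
        raise ValueError("no records left after filtering")
    df = df.copy()
    df["cmv"] = df["cmv"].astype(int)
    terms = ["functional_count", "cmv", "age"]
    if df["subset"].nunique() > 1:
        terms.append("C(subset)")
    fit = smf.ols("fraction_cd57 ~ " + " + ".join(terms), data=df).fit()
    return RegressionResult(params=fit.params, bse=fit.bse,
                            pvalues=fit.pvalues, conf_int=fit.conf_int(),
                            n_obs=int(fit.nobs), model=fit)


# --------------------------------------------------------------------------
# iKIR-expression determinants


def _logit(frac: np.ndarray, correction: float) -> np.ndarray:
    f = (frac + correction) / (1.0 + 2.0 * correction)
    return np.log(f / (1.0 - f))


def ikir_expression_regression(table: pd.DataFrame,
                               correction: float = 0.005,
                               stepwise: bool = False,
                               criterion: str = "aic") -> RegressionResult:
    """Determinants of iKIR expression on T cell subsets.

    Response: logit-transformed iKIR-positive fraction (continuity
    correction for zero fractions); candidate predictors: cell
    differentiation stage (ordinal), lineage (CD4/CD8), iKIR identity,
    age, sex, CMV serostatus and infection status.  The full model is
    the default; ``stepwise`` enables bidirectional search by
    information criterion.
    """
    df = table.copy()
    df["y"] = _logit(df["fraction_positive"].to_numpy(float), correction)
    candidates = []
    for col, cat in (("differentiation", False), ("lineage", True),
                     ("ikir", True), ("age", False), ("sex", True),
                     ("cmv", True), ("infection", True)):
        if col not in df.columns:
            continue
        if df[col].nunique() < 2:
            warnings.warn(f"constant covariate {col!r} dropped")
            continue
        candidates.append(f"C({col})" if cat else col)
    if not candidates:
        raise ValueError("no usable covariates")
    if stepwise:
        chosen = _stepwise(df, "y", candidates, criterion)
    else:
        chosen = candidates
    fit = smf.ols("y ~ " + " + ".join(chosen), data=df).fit()
    return RegressionResult(params=fit.params, bse=fit.bse,
                            pvalues=fit.pvalues, conf_int=fit.conf_int(),
                            n_obs=int(fit.nobs), model=fit)


def _stepwise(df, response, candidates, criterion):
    def score(terms):
        formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
        fit = smf.ols(formula, data=df).fit()
        return getattr(fit, criterion)

    chosen: list[str] = []
    best = score(chosen)
    improved = True
    while improved:
        improved = False
        moves = [(c, "add") for c in candidates if c not in chosen]
        moves += [(c, "drop") for c in chosen]
        for term, action in moves:
            trial = (chosen + [term] if action == "add"
                     else [c for c in chosen if c != term])
            s = score(trial)
            if s < best - 1e-9:
                best, chosen, improved = s, trial, True
    return chosen or ["1"]


# --------------------------------------------------------------------------
# permutation threshold utility


def permutation_threshold(df: pd.DataFrame, fit_fn, n_hypotheses: int,
                          n_permutations: int = 200, alpha: float = 0.05,
                          seed: int = 0, response: str = "y") -> float:
    """Permutation-derived family-wise p-value threshold.

    Permutes the response, refits via ``fit_fn(df) -> RegressionResult``
    and records the minimum p over the tested coefficients; the returned
    threshold is the ``alpha`` quantile of those minima, i.e. the
    per-test p value controlling the family-wise error at ``alpha`` over
    ``n_hypotheses`` hypotheses.
    """
    rng = np.random.default_rng(seed)
    minima = []
    work = df.copy()
    for _ in range(n_permutations):
        work[response] = rng.permutation(df[response].to_numpy())
        fit = fit_fn(work)
        minima.append(float(fit.pvalues.iloc[1:1 + n_hypotheses].min()))
    return float(np.quantile(minima, alpha))
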