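"""Reproducible simulate → fit → associate → age-model pipeline stages.

Each stage reads/writes a self-describing artifact directory: the data
tables, plus a ``manifest.json`` echoing the configuration, seed and
package version.  All stages are pure functions of their inputs; the
point backend and the generator are byte-stable under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .age_structure import (AgeModelParams, dD_dmu, mean_age,
                            simulate_age_distribution, steady_state)
from .association import (between_individual_regression, cd57_regression,
                          compare_nonnested, within_individual_test)
from .genotype import count_functional_ikir
from .inference import FitResult, fit_hierarchical, fit_point
from .io import (SchemaError, read_enrichment, read_genotypes,
                 validate_enrichment, write_enrichment, write_genotypes)
from .labeling import LabelingProtocol
from .synthetic import (generate_cd57_cohort, generate_cohort,
                        generate_labeling_data, get_preset)

__all__ = [
    "NonConvergenceError",
    "run_simulate",
    "run_fit",
    "run_associate",
    "run_age_model",
]


class NonConvergenceError(RuntimeError):
    """An inference backend finished without meeting its diagnostics."""


def _write_manifest(out: Path, command: str, payload: dict) -> None:
    payload = {"command": command, "version": __version__, **payload}
    (out / "manifest.json").write_text(json.dumps(payload, indent=2,
                                                  default=str))


def run_simulate(preset: str, seed: int, out_dir: str | Path) -> Path:
    """Generate a synthetic dataset directory from a named preset.

    Writes ``enrichment.csv``, ``genotypes.csv``, ``metadata.csv``,
    truth tables, ``cd57.csv`` when the preset carries an
    immunophenotype section, and a manifest.
    """
    config = get_preset(preset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config, seed)
    genotypes, meta = cohort
    write_genotypes(genotypes, out / "genotypes.csv")
    meta.to_csv(out / "metadata.csv", index=False)
    manifest: dict = {"preset": preset, "seed": seed}
    if config.cd57 is not None:
        cd = generate_cd57_cohort(config, seed)
        cd["records"].to_csv(out / "cd57.csv", index=False)
        manifest["config"] = cd["manifest"]["config"]
    else:
        lab = generate_labeling_data(cohort, config, seed)
        write_enrichment(lab["enrichment"], out / "enrichment.csv")
        lab["truth_series"].to_csv(out / "truth_series.csv", index=False)
        lab["truth_individuals"].to_csv(out / "truth_individuals.csv",
                                        index=False)
        manifest["config"] = lab["manifest"]["config"]
    _write_manifest(out, "simulate", manifest)
    return out


def run_fit(data_dir: str | Path, out_dir: str | Path,
            backend: str = "point", seed: int = 0,
            n_steps: int = 2000, n_burn: int | None = None) -> FitResult:
    """Fit the kinetic model to a dataset directory and save the result.

    ``backend`` is ``point`` (bounded least squares, deterministic) or
    ``bayes`` (ensemble MCMC with convergence diagnostics).  Raises
    :class:`NonConvergenceError` when diagnostics fail; the partial
    result is still saved with ``converged: false``.
    """
    data_dir, out = Path(data_dir), Path(out_dir)
    data = read_enrichment(data_dir / "enrichment.csv")
    if backend == "point":
        fit = fit_point(data)
    elif backend == "bayes":
        fit = fit_hierarchical(data, seed=seed, n_steps=n_steps,
                               n_burn=n_burn)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    out.mkdir(parents=True, exist_ok=True)
    fit.save(out)
    _write_manifest(out, "fit", {"backend": backend, "seed": seed,
                                 "data_dir": str(data_dir),
                                 "converged": fit.converged})
    if not fit.converged:
        raise NonConvergenceError(
            f"{backend} backend did not converge: {fit.diagnostics}")
    return fit


def _merged_series(fit_dir: Path, genotypes_file: Path,
                   metadata_file: Path | None) -> pd.DataFrame:
    series = pd.read_csv(fit_dir / "series.csv")
    genotypes = read_genotypes(genotypes_file)
    scores = pd.DataFrame(
        [{"individual_id": g.individual_id,
          **count_functional_ikir(g).__dict__} for g in genotypes])
    merged = series.merge(scores, on="individual_id", how="left",
                          validate="many_to_one")
    if merged["functional_count"].isna().any():
        missing = merged.loc[merged["functional_count"].isna(),
                             "individual_id"].unique()
        raise SchemaError(
            f"individuals without genotypes: {sorted(missing)[:5]}")
    if metadata_file is None:
        metadata_file = genotypes_file.parent / "metadata.csv"
    if metadata_file.exists():
        meta = pd.read_csv(metadata_file)
        keep = [c for c in ("individual_id", "infection", "age", "sex",
                            "cmv") if c in meta.columns]
        merged = merged.merge(meta[keep], on="individual_id", how="left",
                              validate="many_to_one")
    if "infection" not in merged.columns or merged["infection"].isna().any():
        raise SchemaError("metadata with infection status is required for "
                          "the between-individual regression")
    return merged


def run_associate(fit_dir: str | Path, genotypes_file: str | Path,
                  out_dir: str | Path,
                  metadata_file: str | Path | None = None,
                  cd57_file: str | Path | None = None) -> dict:
    """Run the association battery on fitted lifespans and write a report.

    The JSON report contains the within-individual paired Wilcoxon test,
    the between-individual log-lifespan regression for each of the three
    genotype predictors, pairwise Davidson-MacKinnon J tests between the
    predictors, and — when a CD57 table is supplied — the CD57 fraction
    regression.
    """
    fit_dir, genotypes_file = Path(fit_dir), Path(genotypes_file)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _merged_series(fit_dir, genotypes_file,
                        None if metadata_file is None else Path(metadata_file))
    report: dict = {}

    wres = within_individual_test(df)
    report["within_individual"] = wres.__dict__

    report["between_individual"] = {}
    usable = []
    for predictor in ("functional_count", "inhibitory_score",
                      "raw_ikir_count"):
        try:
            fit = between_individual_regression(df, predictor)
        except ValueError as err:
            report["between_individual"][predictor] = {"error": str(err)}
            continue
        usable.append(predictor)
        ci = fit.conf_int.loc[predictor]
        report["between_individual"][predictor] = {
            "coefficient": fit.coef(predictor),
            "se": float(fit.bse[predictor]),
            "p": float(fit.pvalues[predictor]),
            "ci95": [float(ci.iloc[0]), float(ci.iloc[1])],
            "n_obs": fit.n_obs,
        }

    report["j_tests"] = {}
    covs = ["subset", "infection"]
    for a, b in [("functional_count", "raw_ikir_count"),
                 ("functional_count", "inhibitory_score")]:
        if a not in usable or b not in usable:
            continue
        try:
            jt = compare_nonnested(df, "lifespan", [a] + covs, [b] + covs,
                                   log_response=True)
        except ValueError as err:
            report["j_tests"][f"{a}_vs_{b}"] = {"error": str(err)}
            continue
        report["j_tests"][f"{a}_vs_{b}"] = jt.__dict__

    if cd57_file is not None:
        cd = pd.read_csv(cd57_file)
        cfit = cd57_regression(cd)
        ci = cfit.conf_int.loc["functional_count"]
        report["cd57"] = {
            "coefficient": cfit.coef("functional_count"),
            "p": float(cfit.pvalues["functional_count"]),
            "ci95": [float(ci.iloc[0]), float(ci.iloc[1])],
            "n_obs": cfit.n_obs,
        }

    (out / "associations.json").write_text(json.dumps(report, indent=2,
                                                      default=float))
    _write_manifest(out, "associate", {"fit_dir": str(fit_dir),
                                       "genotypes": str(genotypes_file)})
    return report


def run_age_model(params_file: str | Path, out_dir: str | Path) -> dict:
    """Solve the age-structured homeostasis model for a parameter file.

    ``params_file`` is JSON with ``lam``, ``s``, ``k``, ``mu`` (and
    optional ``da``/``horizon``).  Writes a summary JSON (steady state,
    loss rate D, mean age, dD/dmu) and the simulated equilibrium age
    distribution as CSV.
    """
    params_file, out = Path(params_file), Path(out_dir)
    raw = json.loads(params_file.read_text())
    try:
        params = AgeModelParams(lam=float(raw["lam"]), s=float(raw["s"]),
                                k=float(raw["k"]), mu=float(raw["mu"]))
    except KeyError as err:
        raise SchemaError(f"age-model params missing field {err}") from err
    out.mkdir(parents=True, exist_ok=True)
    z_bar, loss = steady_state(params)
    summary = {"z_bar": z_bar, "loss_rate_D": loss,
               "mean_age": mean_age(params), "dD_dmu": dD_dmu(params),
               "params": raw}
    sim_kwargs = {k: float(raw[k]) for k in ("da", "horizon") if k in raw}
    dist = simulate_age_distribution(params, **sim_kwargs)
    pd.DataFrame({"age": dist.ages, "density": dist.density}).to_csv(
        out / "age_distribution.csv", index=False)
    (out / "age_model.json").write_text(json.dumps(summary, indent=2,
                                                   default=float))
    _write_manifest(out, "age-model", {"params_file": str(params_file)})
    return summary
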