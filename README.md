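# ikirspan

Quantifying how inhibitory KIR–HLA genotype shapes the in vivo lifespan of
human CD8⁺ T cells, using deuterated-water (²H₂O) labeling kinetics.

## The science

Killer-cell immunoglobulin-like receptors (KIRs) are expressed on NK cells and
on a subset of T cells. An **inhibitory KIR (iKIR)** can only deliver its
signal if the person's HLA genotype encodes the matching ligand: KIR2DL1
pairs with HLA-C group C2, KIR2DL2 with C1 or C2, KIR2DL3 with C1, and
KIR3DL1 with the Bw4 motif (including HLA-A\*23/24/32). The **functional
iKIR–ligand gene-pair count** (0–4) summarises how much inhibitory education a
genome can support.

To measure T cell lifespans directly, volunteers drink small amounts of heavy
water on a three-phase schedule (full dose for a week, two-thirds dose to
day 49, then washout). Deuterium incorporates into the DNA of dividing
cells, so the enrichment of sorted CD8⁺ memory subsets over ~16 weeks reveals
each population's proliferation rate *p*; the expected lifespan is 1/*p*.
Saliva enrichment calibrates body water, and monocytes — fast-turnover cells
whose label plateaus at the body-water level times an amplification factor
*b*<sub>w</sub> — calibrate the precursor enrichment.

This package provides:

- **Forward models** of saliva, monocyte, and T cell enrichment as exact
  piecewise-exponential signals (`labeling`).
- **Inference**: staged bounded least squares for point estimates, and a
  hierarchical Bayesian backend (ensemble MCMC) for partial pooling across
  individuals (`inference`).
- **Genotyping**: iKIR–ligand scoring, per-cell functional/nonfunctional
  classification from expressed receptors, and KIR3DL2-ligand cohort filters
  (`genotype`).
- **Association statistics**: exact paired Wilcoxon tests within individuals,
  log-lifespan regressions between individuals, covariate-adjusted lifespans,
  Davidson–MacKinnon J tests for comparing non-nested genotype predictors,
  CD57/differentiation regressions, and permutation thresholds
  (`association`).
- **An age-structured model** linking death rate to mean cell age at
  population steady state (`age_structure`).
- **Synthetic cohorts** with known ground truth for validation and power
  analysis (`synthetic`), plus a command-line pipeline (`ikirspan`).

## Worked example

Simulate an 18-person mixed-infection cohort (three CD8⁺ memory subsets each,
54 enrichment series), fit every series, and test whether the functional
gene-pair count predicts lifespan:

```python
from ikirspan import (between_individual_regression, compare_nonnested,
                      fit_point, generate_cohort, generate_labeling_data,
                      get_preset, within_individual_test)

config = get_preset("cohort1-default")          # generative effect: +0.41/gene
cohort = generate_cohort(config, seed=1)
lab = generate_labeling_data(cohort, config, seed=1)

fit = fit_point(lab["enrichment"])
records = fit.series.merge(
    cohort[1][["individual_id", "functional_count", "raw_ikir_count",
               "infection"]], on="individual_id")

print(within_individual_test(records).p_value)
print(between_individual_regression(records).params["functional_count"])
```

On seed 1 this prints a within-individual Wilcoxon p of **0.26** (expressing
an iKIR on the cell itself does not change its lifespan) and a
between-individual effect of **+0.360 log-days per functional gene pair**
(95% CI +0.267 to +0.453, p ≈ 5×10⁻¹⁰), recovering the generative truth of
+0.41. A J test confirms the ligand-aware count explains the data where the
ligand-blind raw iKIR count does not (p ≈ 2×10⁻⁷ vs p = 0.74 for the
reverse direction). Each extra functional pair multiplies lifespan by
e^0.36 ≈ 1.4, and the age-structured model translates lower death rates into
older mean cell ages (e.g. λ=1, s=0.1, k=1000, μ=0.05 gives a steady state of
519 cells, removal rate D = λ/z̄ ≈ 0.0019/day, mean age ≈ 519 days).

The `examples/` directory walks through each piece: forward labeling curves
(`01`), parameter recovery from a simulated study (`02`), genotype scoring
(`03`), the full association battery (`04`), and the age-structured model
(`05`). Each is a short script; run them with `python examples/<name>.py`.

## Command-line pipeline

```bash
ikirspan simulate --preset cohort1-default --seed 1 --out data/
ikirspan fit --data data/ --out results/ --backend point
ikirspan associate --fit results/ --genotypes data/genotypes.csv --out results/
ikirspan age-model --params params.json --out results/
```

`simulate` writes genotypes, metadata, enrichment series, and ground-truth
tables; `fit` writes per-series kinetic estimates and lifespans; `associate`
writes the statistical report as JSON; `age-model` solves the steady state
and writes the equilibrium age distribution.

## Layout

- `src/ikirspan/` — the library
- `tests/` — pytest suite (seeded and deterministic)
- `examples/` — narrative example scripts
- `scripts/acceptance.py` — end-to-end reproduction script
- `docs/methods.md` — models, parameters, and numerical methods
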