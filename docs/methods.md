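# Methods

Models, default parameters, generator design, and numerical choices.

## 1. Labeling models

### Body water

Deuterium enrichment in body water follows a three-phase protocol
(`LabelingProtocol`, defaults `t_full_dose = 7`, `t_end_label = 49`,
`observation_horizon = 112` days):

- **Phase 1** (0 ≤ t < 7, full dose): S(t) = f·(1 − e^(−δt)), where f is the
  per-dose plateau fraction and δ the body-water turnover rate.
- **Phase 2** (7 ≤ t < 49, 2/3 dose): S relaxes exponentially at rate δ from
  its phase-1 endpoint toward the reduced plateau (2/3)·f.
- **Phase 3** (t ≥ 49, washout): S decays exponentially at rate δ.

Defaults: f = 0.02, δ = 0.06 /day. `BodyWaterModel.plateau()` returns the
sustained phase-2 plateau (2/3)·f.

### Monocytes

Monocytes descend from dividing bone-marrow precursors. Blood monocytes are
modelled as a delayed copy of the marrow compartment with marrow
proliferation rate p_m = r₂ / (M/B), marrow-to-blood pool ratio M/B = 2.6,
and post-mitotic delay Δ = 1.6 days. Enrichment is normalised so that under
an indefinitely sustained full dose the blood-monocyte label converges to
b_w · f, where b_w is the amplification factor between body water and DNA
(default 4.0, bounds in the priors). This plateau identity is invariant to
M/B and Δ, which makes b_w identifiable from the monocyte curve alone.

### T cells

Each sorted CD8⁺ subset is a kinetically homogeneous population with
proliferation rate p and label-loss rate d\*:

dL/dt = p · b_w · S(t) − d\* · L(t),    O(t) = L(t − Δ_L),

with sampling delay Δ_L (default 3.5 days). The scientific quantities are
**lifespan = 1/p** and half-life = ln 2 / p. d\* exceeds p when labelled
cells are preferentially lost (recently divided cells die or leave blood
faster than average), so d\* is estimated separately and never used to report
lifespan.

### Piecewise-exponential signal algebra

All forward curves are computed exactly (no ODE solver) with an internal
algebra over signals of the form Σᵢ cᵢ t^{kᵢ} e^{−rᵢ t} on each protocol
segment (`_pwexp.py`). Linear first-order filtering (the monocyte and T cell
ODEs) and pure delays are closed operations on this class. When a filter
rate coincides with a signal rate within 10⁻⁹ (resonance, e.g. d\* = δ), the
algebra switches to the t·e^(−rt) solution branch instead of dividing by a
near-zero difference. Tests confirm agreement with high-accuracy ODE
integration to < 10⁻⁶ absolute across parameter grids.

## 2. Inference

### Point backend (`fit_point`)

Staged bounded nonlinear least squares (scipy `least_squares`, TRF):

1. fit (f, δ) to saliva (optionally sharing δ across individuals),
2. fit (b_w, r₂) to monocytes given body water,
3. fit (p, d\*, Δ_L) per T cell series,
4. a joint polish over all parameters when the problem is small (≤ 8 series
   per individual).

Bounds come from `Priors` (e.g. p ∈ [10⁻⁵, 0.2] /day). Estimates at or
within 1% of a lower bound — or below 10⁻⁴ for f — set a boundary flag and
mark the fit non-converged.

### Hierarchical backend (`fit_hierarchical`)

Partial pooling of log p across individuals: log pᵢ ~ Normal(μ, σ), with
weakly-informative hyperpriors and per-series measurement noise. Sampling
uses an affine-invariant ensemble sampler (emcee), walkers initialised near
the point fit, with convergence monitored by split-R̂ (≤ 1.05) and effective
sample size (≥ 400) via arviz. Defaults: 32 walkers, `n_burn = n_steps // 2`.
Per-individual posterior medians and credible intervals are reported; the
interval width shrinks as replicate series per individual increase.

### Precision limits

A single noisy labeling series carries an irreducible uncertainty in 1/p.
With measurement noise sd 5×10⁻⁴ and the default schedule, the Cramér–Rao
bound on the relative sd of the lifespan estimate is ≈ 6% for a 125-day
population and ≈ 12% for a 250-day population (slower populations
incorporate less label, so the signal-to-noise ratio falls). Point
estimates from one series should therefore be read with that error bar;
pooling replicates or individuals is required for tighter inference.

## 3. Genotype scoring

Ligand rules: KIR2DL1–C2, KIR2DL2–C1 or C2, KIR2DL3–C1, KIR3DL1–Bw4.
HLA-C alleles are assigned C1/C2 by allele group (with B\*46 and B\*73
contributing C1); Bw4 includes the HLA-A motifs A\*23/24/32. The
**functional count** is the number of carried iKIR genes whose ligand is
also carried (0–4); the **inhibitory score** optionally weights pairs; the
**raw iKIR count** ignores ligands and serves as the comparison predictor.

`classify_cell` maps flow-cytometry expression channels (KIR2DL1,
KIR2DL2/L3, KIR3DL1) onto functional / nonfunctional / negative: a cell is
functional if any expressed receptor has its ligand; the composite
KIR2DL2/L3 channel is ambiguous only when both genes are carried and the
genome is C2-only (the two receptors then disagree).

`kir3dl2_filter` excludes carriers of KIR3DL2 ligands (A\*03, A\*11, B\*27)
from the primary analysis; the sensitivity mode excludes only B\*27.

## 4. Association statistics

- **Within individual**: per individual, mean lifespan of functional-iKIR⁺
  cells minus functional-iKIR⁻ cells (falling back to iKIR-negative cells
  when no nonfunctional population exists), tested with the exact Wilcoxon
  signed-rank test for n ≤ 25 pairs (normal approximation above).
- **Between individuals**: OLS of log(lifespan) on the genotype predictor
  with categorical adjustment for T cell subset and infection status.
  `adjusted_lifespan` removes the fitted subset/infection effects and
  re-expresses every observation on the central-memory / uninfected
  baseline.
- **Non-nested comparison**: the Davidson–MacKinnon J test. Each model is
  augmented with the fitted values of the other; the t test on that
  augmentation coefficient asks whether the rival model captures signal the
  first one misses. A genotype predictor "wins" when it adds to its rival
  but the rival does not add to it.
- **CD57 / differentiation**: linear regression of the CD57⁺ fraction on
  functional count, CMV status, and age, with optional subset adjustment
  and subset/lineage filters.
- **iKIR expression**: per-cell-population logistic regression of the
  expressed-iKIR fraction (with a small-count correction) on candidate
  covariates, with optional bidirectional stepwise selection by AIC.
- **Permutation thresholds**: empirical null quantiles of any statistic
  under response permutation.

## 5. Age-structured model

The memory pool z(t) obeys dz/dt = λ + s·z(1 − z/k) − μz (source λ,
density-dependent proliferation s with carrying scale k, death μ). At the
stable equilibrium z̄, every cell is removed at the constant rate
**D = λ / z̄** (influx equals removal at steady state), so the equilibrium
age density is exponential, w(a) = λ e^(−Da), with mean age 1/D.
∂D/∂μ > 0 always: longer-lived cells (smaller μ) accumulate into a larger
pool with slower per-cell removal and hence an **older** mean age — mean
age and lifespan need not track each other across genotypes.

z̄ is the positive root of the equilibrium quadratic, computed with the
cancellation-free root formula (q = −(b + sign(b)·√disc)/2, root = max(q/a,
c/q)) plus one Newton step, so the identity D·z̄ = λ holds to machine
precision even as s → 0. The transport equation for w(a, t) is solved
exactly along characteristics; `simulate_age_distribution` rejects grids
with D·da > 0.2 to keep the discretised density accurate.

## 6. Synthetic data

`generate_cohort(config, seed)` draws genotypes from published-range KIR and
HLA carrier frequencies and assigns infection status; `generate_labeling_data`
simulates the forward models with lognormal between-individual lifespan
variation (genotype effect β on log lifespan) and iid Gaussian measurement
noise, returning enrichment series plus ground-truth tables.

Presets:

| preset | design | purpose |
|---|---|---|
| `scenario-2pair` / `scenario-4pair` | 1 individual, fixed genotype, lifespan pinned to 125 / 250 d, σ = 0 | single-series estimation benchmarks |
| `cohort1-default` | 18 individuals × 3 subsets, β = 0.41, mixed infection | association power |
| `null-effect` | as above with β = 0 | type-I error calibration |
| `cohort3-cd57` / `cohort3-cd57-em` | 63 individuals, CD57 fractions by subset (all subsets / effector-memory only) | differentiation analyses |

Limits: the generator assumes kinetically homogeneous subsets, iid Gaussian
noise, no dropout or sampling-time jitter, and genotype effects that act
only through the lifespan. It is a validation harness, not a cohort
emulator.

## 7. Reproducibility

Every stochastic routine takes an explicit integer seed; the test suite is
fully derandomised (fixed hypothesis profile) and the acceptance script
derives all randomness from its `--seed` argument. No network access or
external data are required.
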