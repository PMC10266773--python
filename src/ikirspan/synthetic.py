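"""Synthetic study generator.

Produces complete synthetic labeling studies — KIR/HLA genotypes with
cohort metadata, three-compartment enrichment time courses with
replicate-level noise, and CD57 immunophenotype cohorts — with the
statistical structure the analysis assumes: per-individual body-water
kinetics, monocyte amplification, per-subset T cell kinetics drawn from
lognormal population distributions with a log-linear genotype effect on
lifespan, and a linear functional-iKIR effect on CD57 fractions.

Every generator is a pure function of ``(config, seed)``; a truth table
accompanies each dataset so recovery can be scored without peeking.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype import Genotype, count_functional_ikir
from .labeling import (BodyWaterModel, LabelingProtocol, MonocyteModel,
                       TcellKinetics)

__all__ = [
    "KineticPopulation",
    "Cd57Config",
    "ScenarioConfig",
    "get_preset",
    "PRESETS",
    "generate_cohort",
    "generate_labeling_data",
    "generate_cd57_cohort",
]

# default sampling schedule: serial saliva during and after labeling,
# blood draws from the first week to the end of follow-up, 3 replicate
# measurements per point
SALIVA_TIMES = (0.0, 2.0, 5.0, 7.0, 14.0, 21.0, 35.0, 49.0, 63.0, 84.0, 112.0)
BLOOD_TIMES = (7.0, 14.0, 21.0, 35.0, 49.0, 63.0, 84.0, 112.0)


@dataclass(frozen=True)
class KineticPopulation:
    """Lognormal population model for per-series T cell kinetics.

    The median log-lifespan of a series is
    ``log_lifespan_base + beta_pairs*(functional_count - reference_count)
    + subset_offset + infection_offset`` with lognormal scatter
    ``sigma_log_lifespan``; p = 1/lifespan.  d* and the trafficking
    delay have their own lognormal distributions.  iKIR expression class
    (functional/nonfunctional/negative) carries no effect — matching
    the study's within-individual null.
    """

    log_lifespan_base: float = math.log(125.0)   # uninfected Tcm, ref count
    beta_pairs: float = 0.41                     # per iKIR-ligand gene pair
    reference_count: int = 2
    sigma_log_lifespan: float = 0.25
    subset_offsets: tuple = (("Tcm", 0.0), ("Temra", 0.25))
    infection_offsets: tuple = (("uninfected", 0.0), ("HIV-1", -0.35),
                                ("HCV", -0.15), ("HTLV-1", -0.15))
    dstar_median: float = 0.03
    dstar_sigma: float = 0.3
    delay_median: float = 3.5
    delay_sigma: float = 0.3


@dataclass(frozen=True)
class Cd57Config:
    """Linear model for CD57-positive fractions in an older-adult cohort.

    fraction = baseline(lineage, subset) + beta_count(lineage, subset) *
    functional_count + beta_age*(age - 75) + beta_cmv*CMV + noise,
    clipped to [0, 1].  The genotype effect sits on the differentiated
    subsets (Tem, Temra) and is zero for naive/Tcm, which express very
    little CD57.
    """

    subsets: tuple = ("naive_Tscm", "early_Tcm", "late_Tcm", "Tem", "Temra")
    lineages: tuple = ("CD8", "CD4")
    baselines: tuple = (
        (("CD8", "naive_Tscm"), 0.10), (("CD8", "early_Tcm"), 0.12),
        (("CD8", "late_Tcm"), 0.15), (("CD8", "Tem"), 0.30),
        (("CD8", "Temra"), 0.40),
        (("CD4", "naive_Tscm"), 0.08), (("CD4", "early_Tcm"), 0.10),
        (("CD4", "late_Tcm"), 0.12), (("CD4", "Tem"), 0.20),
        (("CD4", "Temra"), 0.25),
    )
    beta_count: tuple = (
        (("CD8", "naive_Tscm"), 0.0), (("CD8", "early_Tcm"), 0.0),
        (("CD8", "late_Tcm"), 0.0), (("CD8", "Tem"), 0.078),
        (("CD8", "Temra"), 0.078),
        (("CD4", "naive_Tscm"), 0.0), (("CD4", "early_Tcm"), 0.0),
        (("CD4", "late_Tcm"), 0.0), (("CD4", "Tem"), 0.05),
        (("CD4", "Temra"), 0.05),
    )
    beta_age: float = 0.0025      # 3% per 12 years of age
    beta_cmv: float = 0.03
    noise_sd: float = 0.05
    age_range: tuple[int, int] = (60, 91)
    cmv_prob: float = 0.6
    subset_filter: tuple | None = None   # e.g. ("Tem", "Temra")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative specification of a synthetic study."""

    name: str = "custom"
    n_individuals: int = 18
    # allele-group sampling frequencies
    kir_freqs: tuple = (("KIR2DL1", 0.95), ("KIR2DL2", 0.55),
                        ("KIR2DL3", 0.85), ("KIR3DL1", 0.95),
                        ("KIR3DL2", 1.0))
    c1_allele_freq: float = 0.6    # per HLA-C allele; else C2 group
    bw4_allele_freq: float = 0.35  # per HLA-B allele; else Bw6
    a24_freq: float = 0.2          # per HLA-A allele (Bw4 motif)
    a3_freq: float = 0.0           # per HLA-A allele (KIR3DL2 ligand)
    infection_mix: tuple = (("uninfected", 4), ("HCV", 6), ("HIV-1", 6),
                            ("HTLV-1", 2))
    kinetics: KineticPopulation = field(default_factory=KineticPopulation)
    protocol: LabelingProtocol = field(default_factory=LabelingProtocol)
    # per-individual physiological parameters
    f_mean: float = 0.02
    f_sd: float = 0.002
    delta: float = 0.06
    b_w_mean: float = 4.0
    b_w_sd: float = 0.4
    r_2_mean: float = 1.5
    r_2_sd: float = 0.2
    # sampling design
    saliva_times: tuple = SALIVA_TIMES
    blood_times: tuple = BLOOD_TIMES
    replicates: int = 3
    noise_sd: tuple = (("saliva", 5e-4), ("monocyte", 5e-4),
                       ("tcell", 5e-4))
    series_per_individual: int = 3
    fixed_series: tuple | None = None     # ((subset, kir_class), ...)
    fixed_genotype: tuple | None = None   # (kir genes, hla alleles)
    cd57: Cd57Config | None = None

    def __post_init__(self):
        for name, p in self.kir_freqs:
            if not 0 <= p <= 1:
                raise ValueError(f"KIR frequency for {name} outside [0, 1]")
        for p in (self.c1_allele_freq, self.bw4_allele_freq, self.a24_freq,
                  self.a3_freq):
            if not 0 <= p <= 1:
                raise ValueError("allele frequencies must be in [0, 1]")
        if self.a24_freq + self.a3_freq > 1:
            raise ValueError("HLA-A allele frequencies exceed 1")
        if any(sd < 0 for _, sd in self.noise_sd):
            raise ValueError("noise sd must be non-negative")
        if sum(n for _, n in self.infection_mix) != self.n_individuals:
            raise ValueError("infection_mix must sum to n_individuals")
        horizon = self.protocol.observation_horizon
        if max(self.saliva_times) > horizon or max(self.blood_times) > horizon:
            raise ValueError("sampling times outside the observation horizon")

    @property
    def noise(self) -> dict:
        return dict(self.noise_sd)


# --------------------------------------------------------------------------
# presets


def _scenario(name: str, lifespan_days: float, count: int) -> ScenarioConfig:
    """Single uninfected individual with deterministic baseline kinetics."""
    if count == 2:
        # KIR2DL1-C2 and KIR2DL3-C1: exactly two iKIR-ligand gene pairs
        genotype = (("KIR2DL1", "KIR2DL3", "KIR3DL2"),
                    ("C*04:01", "C*07:01", "B*08:01", "B*07:02",
                     "A*01:01", "A*02:01"))
    else:
        # all four scored genes paired: C1, C2 and Bw4 motifs all present
        genotype = (("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1", "KIR3DL2"),
                    ("C*04:01", "C*07:01", "B*57:01", "B*07:02",
                     "A*01:01", "A*02:01"))
    return ScenarioConfig(
        name=name, n_individuals=1,
        fixed_genotype=genotype,
        infection_mix=(("uninfected", 1),),
        kinetics=KineticPopulation(
            log_lifespan_base=math.log(lifespan_days), beta_pairs=0.0,
            reference_count=count, sigma_log_lifespan=0.0,
            dstar_sigma=0.0, delay_sigma=0.0),
        f_sd=0.0, b_w_sd=0.0, r_2_sd=0.0,
        fixed_series=(("Tcm", "functional"),),
    )


def _cohort1(beta: float) -> ScenarioConfig:
    return ScenarioConfig(
        name="cohort1-default" if beta else "null-effect",
        n_individuals=18,
        kinetics=KineticPopulation(beta_pairs=beta),
    )


def _cohort3(subset_filter=None) -> ScenarioConfig:
    return ScenarioConfig(
        name="cohort3-cd57" if subset_filter is None else "cohort3-cd57-em",
        n_individuals=63,
        infection_mix=(("uninfected", 63),),
        cd57=Cd57Config(subset_filter=subset_filter),
    )


PRESETS = {
    "scenario-2pair": lambda: _scenario("scenario-2pair", 125.0, 2),
    "scenario-4pair": lambda: _scenario("scenario-4pair", 250.0, 4),
    "cohort1-default": lambda: _cohort1(0.41),
    "null-effect": lambda: _cohort1(0.0),
    "cohort3-cd57": lambda: _cohort3(None),
    "cohort3-cd57-em": lambda: _cohort3(("Tem", "Temra")),
}


def get_preset(name: str) -> ScenarioConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None


# --------------------------------------------------------------------------
# genotype / metadata generation

# representative common alleles per motif group used to realise sampled
# motif frequencies as concrete allele names
_C1_ALLELES = ("C*07:01", "C*03:04", "C*12:03")
_C2_ALLELES = ("C*04:01", "C*05:01", "C*06:02")
_BW4_ALLELES = ("B*57:01", "B*44:02", "B*51:01")
_BW6_ALLELES = ("B*08:01", "B*07:02", "B*35:01")
_A_NEUTRAL = ("A*01:01", "A*02:01", "A*68:01")
_A24 = "A*24:02"
_A3 = "A*03:01"


def generate_cohort(config: ScenarioConfig, seed: int
                    ) -> tuple[list[Genotype], pd.DataFrame]:
    """Sample genotypes and cohort metadata.

    Returns the genotype list and a metadata table with age, sex, CMV
    serostatus, infection status and the derived genotype scores.
    """
    rng = np.random.default_rng(seed)
    infections = [inf for inf, n in config.infection_mix for _ in range(n)]
    genotypes, rows = [], []
    for i in range(config.n_individuals):
        ind = f"P{i + 1:03d}"
        if config.fixed_genotype is not None:
            kir, fixed_alleles = config.fixed_genotype
            g = Genotype.make(ind, kir, fixed_alleles)
            score = count_functional_ikir(g)
            genotypes.append(g)
            rows.append({"individual_id": ind, "age": int(rng.integers(25, 66)),
                         "sex": "F" if rng.random() < 0.5 else "M",
                         "cmv": bool(rng.random() < 0.5),
                         "infection": infections[i],
                         "functional_count": score.functional_count,
                         "inhibitory_score": score.inhibitory_score,
                         "raw_ikir_count": score.raw_ikir_count})
            continue
        kir = {gene for gene, q in config.kir_freqs if rng.random() < q}
        alleles = []
        for _ in range(2):   # HLA-C
            pool = _C1_ALLELES if rng.random() < config.c1_allele_freq \
                else _C2_ALLELES
            alleles.append(pool[rng.integers(len(pool))])
        for _ in range(2):   # HLA-B
            pool = _BW4_ALLELES if rng.random() < config.bw4_allele_freq \
                else _BW6_ALLELES
            alleles.append(pool[rng.integers(len(pool))])
        for _ in range(2):   # HLA-A
            u = rng.random()
            if u < config.a24_freq:
                alleles.append(_A24)
            elif u < config.a24_freq + config.a3_freq:
                alleles.append(_A3)
            else:
                alleles.append(_A_NEUTRAL[rng.integers(len(_A_NEUTRAL))])
        g = Genotype.make(ind, kir, alleles)
        score = count_functional_ikir(g)
        genotypes.append(g)
        if config.cd57 is not None:
            lo, hi = config.cd57.age_range
            age = int(rng.integers(lo, hi + 1))
            cmv = bool(rng.random() < config.cd57.cmv_prob)
        else:
            age = int(rng.integers(25, 66))
            cmv = bool(rng.random() < 0.5)
        rows.append({"individual_id": ind, "age": age,
                     "sex": "F" if rng.random() < 0.5 else "M",
                     "cmv": cmv, "infection": infections[i],
                     "functional_count": score.functional_count,
                     "inhibitory_score": score.inhibitory_score,
                     "raw_ikir_count": score.raw_ikir_count})
    return genotypes, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# labeling data generation

_SERIES_MENU = (("Tcm", "functional"), ("Tcm", "nonfunctional"),
                ("Temra", "functional"), ("Temra", "negative"))


def generate_labeling_data(cohort: tuple[list[Genotype], pd.DataFrame],
                           config: ScenarioConfig, seed: int) -> dict:
    """Simulate the three-compartment enrichment study for a cohort.

    Returns a dict with the long-format ``enrichment`` table, the
    ``truth_series`` and ``truth_individuals`` tables, and a manifest
    echoing the configuration and seed.
    """
    genotypes, meta = cohort
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    kin = config.kinetics
    subset_off = dict(kin.subset_offsets)
    infect_off = dict(kin.infection_offsets)
    noise = config.noise
    meta_ix = meta.set_index("individual_id")

    enr_rows, truth_series, truth_ind = [], [], []
    for g in genotypes:
        ind = g.individual_id
        f = float(np.clip(rng.normal(config.f_mean, config.f_sd)
                          if config.f_sd else config.f_mean, 1e-3, 0.5))
        b_w = float(np.clip(rng.normal(config.b_w_mean, config.b_w_sd)
                            if config.b_w_sd else config.b_w_mean, 0.5, 6.5))
        r_2 = float(np.clip(rng.normal(config.r_2_mean, config.r_2_sd)
                            if config.r_2_sd else config.r_2_mean, 0.2, 9.5))
        water = BodyWaterModel(f=f, delta=config.delta,
                               protocol=config.protocol)
        mono = MonocyteModel(b_w=b_w, r_2=r_2)
        truth_ind.append({"individual_id": ind, "f": f, "delta": config.delta,
                          "b_w": b_w, "r_2": r_2})

        _emit(enr_rows, rng, ind, "saliva", "none", "none",
              config.saliva_times, water.signal(), noise["saliva"],
              config.replicates)
        _emit(enr_rows, rng, ind, "monocyte", "none", "none",
              config.blood_times, mono.blood_signal(water),
              noise["monocyte"], config.replicates)

        if config.fixed_series is not None:
            series = list(config.fixed_series)
        else:
            pick = rng.permutation(len(_SERIES_MENU))
            series = [_SERIES_MENU[k]
                      for k in sorted(pick[:config.series_per_individual])]
        count = int(meta_ix.loc[ind, "functional_count"])
        infection = meta_ix.loc[ind, "infection"]
        for subset, kir_class in series:
            log_ls = (kin.log_lifespan_base
                      + kin.beta_pairs * (count - kin.reference_count)
                      + subset_off[subset] + infect_off[infection])
            if kin.sigma_log_lifespan:
                log_ls += rng.normal(0.0, kin.sigma_log_lifespan)
            lifespan = math.exp(log_ls)
            p = 1.0 / lifespan
            d_star = kin.dstar_median * (
                math.exp(rng.normal(0.0, kin.dstar_sigma))
                if kin.dstar_sigma else 1.0)
            delay = min(kin.delay_median * (
                math.exp(rng.normal(0.0, kin.delay_sigma))
                if kin.delay_sigma else 1.0), 21.0)
            tk = TcellKinetics(p=p, d_star=d_star, delay=delay)
            _emit(enr_rows, rng, ind, "tcell", subset, kir_class,
                  config.blood_times, tk.observed_signal(b_w, water),
                  noise["tcell"], config.replicates)
            truth_series.append({"individual_id": ind, "subset": subset,
                                 "kir_class": kir_class, "p": p,
                                 "d_star": d_star, "delay": delay,
                                 "lifespan": lifespan,
                                 "functional_count": count,
                                 "infection": infection})
    manifest = {"preset": config.name, "seed": int(seed),
                "config": asdict(config)}
    return {"enrichment": pd.DataFrame(enr_rows),
            "truth_series": pd.DataFrame(truth_series),
            "truth_individuals": pd.DataFrame(truth_ind),
            "manifest": manifest}


def _emit(rows, rng, ind, compartment, subset, kir_class, times, signal,
          sd, replicates):
    times = np.asarray(times, dtype=float)
    clean = signal(times)
    for rep in range(1, replicates + 1):
        obs = clean + (rng.normal(0.0, sd, size=times.size) if sd else 0.0)
        for t, v in zip(times, np.clip(obs, 0.0, None)):
            rows.append({"individual_id": ind, "compartment": compartment,
                         "subset": subset, "kir_class": kir_class,
                         "time_days": t, "enrichment": float(v),
                         "replicate": rep})


# --------------------------------------------------------------------------
# CD57 cohort generation


def generate_cd57_cohort(config: ScenarioConfig, seed: int) -> dict:
    """Simulate a CD57 immunophenotype cohort.

    Returns ``records`` (one row per individual x lineage x subset with
    the noisy clipped CD57-positive fraction), the cohort metadata, and
    a manifest.  A ``subset_filter`` in the CD57 config restricts the
    emitted subsets (e.g. Tem/Temra only).
    """
    if config.cd57 is None:
        raise ValueError("config has no cd57 section")
    cd = config.cd57
    genotypes, meta = generate_cohort(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    baselines = dict(cd.baselines)
    betas = dict(cd.beta_count)
    subsets = cd.subset_filter or cd.subsets
    rows = []
    for _, m in meta.iterrows():
        for lineage in cd.lineages:
            for subset in subsets:
                mean = (baselines[(lineage, subset)]
                        + betas[(lineage, subset)] * m["functional_count"]
                        + cd.beta_age * (m["age"] - 75)
                        + cd.beta_cmv * float(m["cmv"]))
                frac = float(np.clip(
                    mean + (rng.normal(0.0, cd.noise_sd) if cd.noise_sd
                            else 0.0), 0.0, 1.0))
                rows.append({"individual_id": m["individual_id"],
                             "subset": subset, "lineage": lineage,
                             "fraction_cd57": frac, "age": m["age"],
                             "cmv": m["cmv"],
                             "functional_count": m["functional_count"]})
    manifest = {"preset": config.name, "seed": int(seed),
                "config": asdict(config)}
    return {"records": pd.DataFrame(rows), "metadata": meta,
            "manifest": manifest}
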