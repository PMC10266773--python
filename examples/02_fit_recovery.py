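"""Simulate a labeling study and recover the kinetic parameters.

Generates the two-gene-pair baseline scenario (mean memory CD8+ T cell
lifespan 125 days by construction), fits the full model with the
point-estimation backend, and compares estimates with the generative
truth.
"""

from ikirspan import (fit_point, generate_cohort, generate_labeling_data,
                      get_preset, recovery_report)

config = get_preset("scenario-2pair")
cohort = generate_cohort(config, seed=1)
lab = generate_labeling_data(cohort, config, seed=1)

fit = fit_point(lab["enrichment"])
print("converged:", fit.converged)
print()
print("lifespan table (days):")
print(fit.lifespan_table().to_string(index=False))
print()
truth = lab["truth_series"][["individual_id", "subset", "kir_class",
                             "p", "d_star", "delay"]]
print("recovery against the generator truth:")
print(recovery_report(truth, fit).to_string(index=False))
print()
print("With measurement noise sd 5e-4 the lifespan estimate scatters by"
      " roughly 5-15% around the truth from seed to seed; rerun with"
      " other seeds to see the spread.")
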