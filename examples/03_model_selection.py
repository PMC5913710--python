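"""Multimodel DIC ranking on data with non-assimilatory electron flow.

Generates curves whose fluorescence signal overstates assimilatory electron
transport by 12% (alternative electron sinks) and lets DIC arbitrate between
the fluorescence-ETR and light-response-ETR model variants.
"""

import fvcbayes as fb

jm = fb.ModelSpec.from_code("CaCc_Jm")
jf = fb.ModelSpec.from_code("CaCc_Jf")

truth = fb.default_truth(jm, genotypes=("demo",), n_individuals=4,
                         delta_alt=0.12, seed=5)
curves, _ = fb.generate_dataset(truth)

scores = {}
for spec in (jm, jf):
    config = fb.RunConfig(chains=2, iterations=2000, burn_in=2000, thin=4, seed=3)
    draws = fb.run_mcmc(curves, spec, config)
    scores[("demo", spec.code)] = fb.compute_dic(draws, curves, spec)

table = fb.delta_dic(scores, threshold=10.0)
print(table.to_frame().round(1).to_string(index=False))
print(
    "\ndelta_DIC is each model's DIC above the genotype minimum; models within "
    "10 units are equally supported (top tier).  The light-response variant "
    "should win here because the fluorescence ETR is inflated by electrons "
    "that never reach carbon fixation."
)
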