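"""HDI trait-variance screen on a constructed two-genotype contrast.

Generates two genotypes whose Jmax25 truths differ by 60 umol m-2 s-1 while
every other trait is shared, fits each genotype independently, and grades
trait differentiation by the largest HDI mass excluding zero.
"""

import fvcbayes as fb

spec = fb.ModelSpec.from_code("CaCc_Jm")
truth = fb.default_truth(
    spec, genotypes=("hi", "lo"),
    overrides={"hi": {"Jmax25": 201.0}, "lo": {"Jmax25": 141.0}},
    n_individuals=4, seed=8,
)
curves, _ = fb.generate_dataset(truth)

runs = {}
for k, geno in enumerate(("hi", "lo")):
    sub = [c for c in curves if c.genotype_id == geno]
    config = fb.RunConfig(chains=2, iterations=2500, burn_in=2500, thin=5,
                          seed=30 + k)
    runs[geno] = fb.run_mcmc(sub, spec, config)

for sym in ("mu_Jmax25", "mu_Vcmax25", "mu_thetaJ"):
    diff = fb.genotype_difference_distribution(runs["hi"], runs["lo"], sym,
                                               seed=0)
    res = fb.max_hdi_level_excluding_zero(diff, symbol=sym)
    level = "none" if res.max_hdi_level is None else f"{res.max_hdi_level:.2f}"
    print(f"{sym:>14}: mean difference {diff.mean():8.2f}, "
          f"max HDI excluding zero: {level}")
print(
    "\nA high level (>= 0.95) marks credible genotypic differentiation; "
    "'none' means zero lies inside even the 50% highest-density interval. "
    "Only the constructed Jmax25 contrast should be flagged."
)
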