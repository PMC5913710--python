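# Methods

## The model and the screen

`fvcbayes` treats a leaf's A/Ci response — net CO2 assimilation `A_n`
measured over a ladder of CO2 setpoints at saturating light — as the data
of a hierarchical Bayesian inference problem, and treats the *structure* of
the photosynthesis model as an experimental factor.  Eight variants of the
Farquhar–von Caemmerer–Berry (FvCB) C3 model are formed by crossing three
binary assumptions:

1. **Mesophyll conductance** (`CiCc` codes): CO2 transfer from the
   intercellular airspace to the chloroplast is limited by a finite
   conductance `g_m`, making the rate laws quadratics in `A`
   (Ethier–Livingston form).  The alternative (`CaCc`) assumes infinite
   `g_m` and drives the supply function from ambient CO2 through the
   measured stomatal conductance `g_s`.
2. **Electron transport rate** (`Jf` vs `Jm`): `J` either comes from
   chlorophyll fluorescence, `J_f = phiPSII * f * Q * alpha_leaf`
   (`f = 0.5`, `alpha_leaf = 0.85`), or from the non-rectangular-hyperbola
   light response parameterized by `Jmax`, `phiJ`, `thetaJ` (smaller root
   of `thetaJ J^2 - (I2 + Jmax) J + I2 Jmax = 0`, `I2 = Q phiJ alpha_leaf`).
3. **Temperature constraint** (`_Temp` suffix): kinetic parameters follow
   an Arrhenius response `p(T) = p25 exp[E_i (T_K - 298) / (298 R T_K)]`
   with per-parameter activation energies `E_i` (kJ mol-1); the reference
   is exactly 298 K, matching the published formulation.

Per observation the expected rate is `A_exp = min(A_c, A_j)`.  Both
limitation rates solve `a A^2 + b A + c = 0` with `a = -1/g`; the quadratic
is evaluated in the algebraically identical form `2c / (-b - sqrt(b^2 -
4ac))`, which is stable as `g -> inf` and reduces there to the classic
closed forms.  Two typographic defects of the printed equations are
corrected deliberately: the RuBisCO-limited `c` coefficient carries the
standard `-Vcmax (C - Gamma*)` term (without which the quadratic has no
carboxylation-limited behaviour; the restored form is validated by the
infinite-conductance limit), and the light-response quadratic uses
`I2 = Q phiJ alpha_leaf` consistently in both `b` and `c`.  A
triose-phosphate-utilization limitation is not modelled: at the trait
scales involved the generated ladder tops out near 40 umol m-2 s-1, far
below the >93 umol m-2 s-1 regime where TPU becomes relevant.

## Probability model

Observations are Gaussian around the forward prediction,
`A_n ~ N(A_exp, tau)`, `tau = sigma^-2`, with one process sd `sigma` per
(model, genotype) run.  Traits are nested: individual values
`mu_Y_i ~ N(mu_Y_geno, tau_Y_geno)` for the physiologically plastic traits
(`Vcmax25`, `Jmax25`, `Rd25`, `Gamma_star25`, `gm25`, `phiJ`, `thetaJ`),
while evolutionarily conserved quantities (`Kc25`, `Ko25`, all activation
energies) are estimated once per genotype.  Genotype means carry
literature Normal priors specified as (mean, precision) — e.g.
`Vcmax25 ~ N(90, 0.000625)`, `Jmax25 ~ N(171, 0.000308)`, `Ko25 ~
N(30400, 1e-5)` — kept at their printed values; the full 16-entry catalog
is in `hierarchy.default_prior_catalog` and can be overridden from YAML
(this is also how the posterior-to-prior updating loop feeds back).  All
partial pressures are carried in Pa; this makes `O/Ko ~ 0.7`, which is the
physically sensible reading of the prior table.

Hyperpriors: `Gamma(0.01, 0.01)` on each genotype-level precision (the
methodology fixes only that these are weakly-informative gammas; the exact
constants are configuration), and a half-Cauchy with scale 2.5 on `sigma` (the published
folded-Cauchy/truncated-t construction; we place it on the sd rather than
the precision, the standard reading of that construction).  Priors are
untruncated Normals by default; proposals that are physically inadmissible
(non-positive capacities, `thetaJ` outside (0, 1]) are rejected through a
`-inf` likelihood rather than by truncating the prior, with an optional
truncate-at-zero flag for users who want proper truncation.

## Sampling

Each (model variant, genotype) pair is one independent inference unit.
The kernel is adaptive Metropolis-within-Gibbs:

* conjugate Gibbs draws for the genotype means (normal-normal) and
  genotype precisions (gamma) of the nested traits;
* vectorized per-individual random-walk Metropolis for individual trait
  values (the likelihood factorizes over individuals, so per-individual
  accept/reject in one sweep is exact);
* scalar Metropolis for the genotype-level kinetic symbols and for
  `log sigma` (with Jacobian);
* for `Jm` variants, an extra symmetric proposal per nested ETR pair that
  moves `(phiJ, Jmax25)` and `(thetaJ, Jmax25)` jointly along the fixed
  direction of the light-response `J` contour, estimated once at the prior
  means.  At a single saturating irradiance only the realized `J` is
  identified, so the three ETR parameters lie on a long, gently curved
  ridge; without the correlated moves a coordinatewise walk crosses it far
  too slowly for desk-scale schedules.

Step sizes adapt in batches of 50 toward a 0.44 acceptance rate during
burn-in only, so retained draws come from a fixed kernel.  Chains start
from jittered prior means (re-jittered up to 50 times if the start is
inadmissible).  Per-chain seeds are split deterministically from the run
seed; identical (data, config, seed) reproduce draws bitwise.  The
deviance `D(theta) = -2 log p(Y|theta)` is monitored alongside the draws;
the data-only standardizing term of the general deviance definition is
constant across models and dropped.

Schedules: the `paper` preset reproduces the published arithmetic
(4 chains x 250,000 iterations after 200,000 burn-in, thinned by 20 =
50,000 retained draws per run).  The `desk` preset (4 x 5,000/5,000,
thin 5) and the reduced test schedules (2 x 2,500-3,000) are sized for a
single CPU; the replicated studies in the test suite use them with 2-6
individuals per genotype, which is the scale at which the whole suite
completes in tens of minutes.  Convergence is reported as Gelman–Rubin
univariate PSRF per parameter and the Brooks–Gelman multivariate PSRF,
threshold 1.2.

## Model scoring and trait screening

DIC uses the Spiegelhalter decomposition: `pD = Dbar - D(theta_bar)` with
`theta_bar` the componentwise posterior mean over all chains, and
`DIC = D(theta_bar) + 2 pD = Dbar + pD`.  Within each genotype,
`dDIC = DIC - min DIC`; models within 10 units are reported as equally
supported ("top tier").  A known limitation, inherited from mean-based
DIC itself: on the `Jm` ETR ridge the componentwise mean can fall off the
ridge, occasionally producing unstable or negative `pD` at short
schedules.  The ranking by dDIC is much more stable than `pD`; the test
suite exercises the pD-ordering property on the mesophyll-conductance
nesting, where it is well behaved.

Trait differentiation between two genotypes is graded by differencing
their (independent) posteriors of the genotype-level mean: the draw
vectors are randomly paired (seeded; equivalent to sampling the
convolution), and the difference sample is tested at the eight HDI masses
50, 60, 70, 80, 85, 90, 95, 99%.  The reported statistic is the largest
mass whose shortest (highest-density) interval excludes zero, or "none".
For unimodal samples exclusion is monotone in the mass; violations are
detected and resolved conservatively with a warning.  Predictive checks
use central credible intervals of `A_exp` over a driver grid (genotype,
individual, or pooled-across-genotypes scope), optionally adding
`N(0, sigma)` observation noise per draw; HDIs are reserved for the
differencing test.

## Synthetic data

The generator mirrors the measurement protocol the screen expects: a
12-step CO2 ladder (50-2000 umol mol-1) at `Q = 2000 umol m-2 s-1`, leaf
temperature `N(22, 0.5) C`, pressure 101,325 Pa, O2 at 21% of pressure.
Individual traits are drawn Normal around genotype means with
between-individual spreads of a few percent of trait scale (e.g. 5 for
`Vcmax25`, 8 for `Jmax25`), and observation noise has sd 0.5 umol m-2 s-1
by default — a strong-signal regime in which recovery is expected to
succeed.  For infinite-`g_m` generating variants, stomatal conductance is
drawn per individual (mean 3 umol m-2 s-1 Pa-1 on the CO2 pressure basis)
and the reported `Ci` is the consistent diagnostic `Ca - A/gs`; for
`g_m`-limited variants `Ci` is a configured stomatal drawdown of ambient
(default `Ci = 0.7 Ca`, jittered), a quantity the generator must invent
because measured drawdowns exist only in real data.  PSII yield is derived
by inverting the fluorescence ETR relation from the generating `J`; the
`delta_alt >= 0` knob inflates it to emulate non-assimilatory electron
sinks, which is what lets tests reproduce the qualitative fluorescence-ETR
misfit finding.  The sensitivity harness adds `N(0, 2.0^2)` noise to
assimilation only, mimicking infrared gas-analyzer instrument error.

What the generator does *not* emulate: instrument drift, CO2 leaks,
non-steady-state transients, light gradients within the leaf, correlated
trait variation between individuals, or any TPU limitation.  Passing
recovery tests therefore demonstrate internal consistency of model,
sampler and screen under the assumed error structure — not robustness to
the full failure modes of field data.

A caution about the sensitivity harness under these conditions: adding
sd-2.0 noise to strong-signal (sigma 0.5) data widens the posteriors of
the bounded and ridge-identified traits (`Rd25` near its positivity
bound, `Jmax25` along the ETR ridge) asymmetrically, so their median
shifts need not be sign-symmetric trait by trait.  The suite's
no-systematic-sign check therefore aggregates to one sign per replicate
(the median standardized shift across the genotype-mean traits) before
the exact sign test, which is the statistic robust to this skewness while
still detecting a genuinely directional harness.

## Numerical choices

* Quadratic roots via the `2c/(-b -/+ sqrt(disc))` forms; negative
  discriminants are flagged invalid and propagate as `-inf`
  log-likelihood, never as exceptions inside the sampler.
* HDI: shortest contiguous window over the sorted sample containing
  `ceil(mass * n)` points; at least 100 samples required.
* Boxplot quartiles use linear interpolation (NumPy default).
* Posterior-mean state for DIC is the componentwise mean, as published.
* `psrf_univariate` returns NaN when the within-chain variance is zero;
  the multivariate statistic drops zero-variance coordinates and
  ridge-regularizes a singular within-chain covariance with a warning.
* Unit conversions: CO2 mole fraction to Pa via `x 1e-6 P`; stomatal
  conductance to water vapour (mol m-2 s-1) to CO2 pressure basis via
  `gsw / 1.6 * 1e6 / P`.

## Open design points resolved here

* Field-site pressure is never stated by the protocol; the reader accepts
  a pressure column or a configured constant (the generator uses standard
  atmosphere).
* Leaf absorptance: 0.85 is used in both ETR formulations and `Q` is
  treated as incident flux; the separately quoted blue/red absorptances
  are a measurement detail not used by the model equations.
* `Cc = C - A/g` is available as a derived diagnostic only; it plays no
  role in inference.
* Missing fluorescence data is an error at fit time for `Jf` variants
  only; `Jm`-only workflows need none.
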