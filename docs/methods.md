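# Methods

## Model

The unit of dynamics is a single nucleotide variant whose within-host
frequency `f` is interpreted as the relative abundance of the strain
carrying it. The stochastic logistic model (SLM)

    df/dt = (f/τ)(1 − f/K) + sqrt(σ/τ) f η(t),   ⟨η(t)η(t′)⟩ = δ(t − t′)

is read in the Itô convention throughout; via the Fokker–Planck equation
its stationary density is `Gamma(2/σ − 1, 2/(Kσ))`, which exists only for
`σ < 2` (enforced at parameter construction). The mean is `K(1 − σ/2)` and
the squared CV is `σ/(2 − σ)`. Because neither `K` nor `σ` is observable
directly, all predictions use the moment parameterization
`Gamma(β, β/f̄)`, with `f̄` the across-host mean frequency and
`β = f̄²/σ_f²` the squared inverse CV. Both moments are computed over *all*
hosts at adequate depth, zeros included: under the ecological reading a
zero is a sampling miss of a strain that is present, and the excess-zero
alternative (competitive exclusion / zero-inflated gamma) is deliberately
out of scope since it can only lower predicted prevalence, the direction in
which the model already errs when it errs. A nonzero-only variant of the
moment estimator is available (`include_zeros=False`) for sensitivity
analysis.

Two linearized single-locus models provide evolutionary gammas for
comparison, valid in the `f ≪ 1` regime:
purifying selection `Gamma(2Nμ, 2N|s|)` (mean `μ/|s|`) and positive
selection `Gamma(2Nμ, 1/f_max)` with `f_max = (e^{st} − 1)/(2Ns)`. Note the
shape parameter — hence `β` — equals `2Nμ` in both regimes; statements
elsewhere that `β = (2Nμ)²` (or its reciprocal) are inconsistent with the
distributions themselves and are not used. The neutral case `s = 0` has no
gamma stationary form here and is rejected.

## Sampling and prevalence

Given depth `D`, the alternate-read count is modeled as Poisson(`D f`) —
the `D ≫ 1`, `f ≪ 1` limit of binomial sampling — and the gamma mixture
gives the closed form

    Pr[A | D, β, β/f̄] = Γ(β+A)/(A! Γ(β)) · (f̄D/(β+f̄D))^A · (β/(β+f̄D))^β,

computed in log space via `gammaln`; it is algebraically a negative
binomial, which the tests exploit as an independent cross-check. Absence is
the `A = 0` term, `(1 + D f̄/β)^{−β}`. Predicted prevalence averages the
presence probability over each site's per-host depths; the truncated form
sums the pmf over `A < A_cutoff` to honor the minor-allele detection
cutoff, and reduces exactly to the plain form at `A_cutoff = 1`. Observed
prevalence is the fraction of hosts with `f > 0` after filtering; accuracy
is the relative error `ε = |obs − pred|/obs`, defined only for sites
observed at least once. Hosts below the depth minimum are excluded from
*both* observed and predicted prevalence so the two condition on the same
host set. Predictions are deliberately Poisson-based only; no
binomial-exact variant is offered.

## Filters and estimators

Defaults mirror the processing conventions of cohort-scale metagenomic
pipelines: minimum within-host depth `D ≥ 20`; minor-allele count cutoff
`A ≥ 10` (below it, `f` is recorded as 0); polarization onto the
across-host minor allele (sites with mean frequency > 0.5 flipped
`f → 1 − f`, `A → D − A`; an exact 0.5 tie is left unflipped). Variances
are population (`ddof = 0`) moments; sites that are all-zero or whose
variance is at the floating-point rounding floor (`var ≤ (10⁻⁹ f̄)²`) are
excluded with a logged count. The Taylor analysis excludes sites detected
in fewer than 35% of hosts (strict `<`, so the boundary is kept) and fits
OLS of `log10 σ_f²` on `log10 f̄` over sites with `f̄ ≤ 0.35`; above that
ceiling the variance tracks the Bhatia–Davis bound `(1 − f̄)f̄` — a
constraint of bounded support, not ecology — which `compute_site_moments`
asserts on every row as an internal sanity check. The 95% CI comes from a
percentile bootstrap that resamples *sites* (the CI quantifies across-site
scatter), 10,000 resamples by default.

The distribution-collapse procedure pools nonzero frequencies per species,
log10-transforms, and z-scores. Family comparison is done on the log scale,
where the fits live: the log of a gamma variate is log-gamma (3 free
parameters: shape, location, scale) and the log of a lognormal is Gaussian
(2 parameters), both fit by maximum likelihood through SciPy and compared
by `AIC = 2k − 2 logL` with the parameter counts recorded. Pooling across
species into one fit is the default; per-species fits can be assembled from
the same primitives. For the across-host *mean*-frequency variant of the
collapse, sites containing `f = 1` observations can be excluded
(`exclude_f1`), since exact ones reflect the bounded support.

## Permutation tests

Within a species, the statistic is the Pearson correlation between log10
observed prevalence and `ε`; the null shuffles `ε` against prevalence
(10,000 permutations by default, seeded) and the 95% window is the
2.5–97.5 percentile range. Across species, the strain-structure scan
computes each species' mean `ε` over sites with observed prevalence at or
above each threshold (20 log10-spaced thresholds over [0.01, 0.5] by
default; a between-thresholds window variant is available), keeps a species
at a threshold only if it holds ≥ 10 such sites, and correlates those means
with the fraction of hosts carrying strain structure. Its null permutes
`ε` within species and recomputes all threshold means before
recorrelating; since a permuted subset of size k receives k exchangeable
draws, the implementation realizes this scheme as prefix means of permuted
error vectors sorted by prevalence, which keeps the full null distribution
exact while vectorizing over permutations. This null preserves each
species' overall error level by construction — it has power against
*within-species* dependence of error on prevalence, not against differences
in species-wide error scale. Thresholds where fewer than 3 species survive,
or where strain fractions are constant, are reported as undefined.

## Synthetic cohorts

The generator emulates the processed product of a cohort pipeline, not
reads or sequences. Defaults are the study-scale conditions: 182 hosts;
10,000 sites of which 2,000 are "evolutionary"; strain-backed site means
log-uniform on [10⁻³, 0.35] with a shared `β = 1`; evolutionary sites drawn
from the purifying-selection gamma with `N = 10⁶`, `μ = 2.5×10⁻⁸`,
`s = −2.5×10⁻⁶` (shape `2Nμ = 0.05`, mean `μ/|s| = 0.01` — low-frequency,
low-prevalence alleles at the edge of the observable window); coverage from
a discretized lognormal with median 40 and log-sd 0.5, resampled to respect
`D ≥ 20`; binomial read sampling by default (Poisson available, matching
the prediction's approximation regime); and an independent per-host
Bernoulli strain-structure indicator (default fraction 0.27). The
multi-species ensemble helper spaces strain fractions over [0.089, 0.64]
and decreases the evolutionary-site share with strain fraction, the
mechanism by which prediction error couples to strain structure.

Latent gamma draws are clipped at 1. Because clipping changes the law
actually sampled, the recorded per-site ground truth is the analytic mean
and squared inverse CV of `min(X, 1)` (computed from incomplete-gamma
integrals), with the nominal gamma parameters kept alongside. At the
default `β = 1` the clip probability reaches `e^{−1/f̄}` ≈ 5.7% for the
topmost site means, and a warning is logged whenever it exceeds 1% at any
site.

The generator emulates the *statistical* structure of processed data only.
Real cohorts have correlated coverage across sites within a host,
linkage between sites on the same genome, species- and host-dependent
error rates, and evolutionary alleles that are genuinely non-stationary
rather than gamma-distributed; none of these are modeled. Passing tests
therefore demonstrate internal consistency of the estimators and
predictions under the stated model, not performance on real metagenomes.

## Numerical choices

SDE integration is Euler–Maruyama under Itô. Default step `dt = τ/100`,
burn-in `50τ`; the stationary sampler uses `dt = τ/400` and one sample per
`τ` per chain across many parallel chains, which brings discretization bias
in the stationary mean below 1% across `K ∈ [0.05, 0.5]`, `σ ∈ [0.2, 1]`.
Negative excursions are reflected (`f → |f|`) and counted; at default
parameters boundary events are below 0.1% of steps. The SLM simulator is
*unbounded above* by default: its analytic stationary gamma has unbounded
support, and capping at 1 would truncate up to ~2% of stationary mass at
large `K` and `σ`, silently biasing comparisons against the closed form.
An optional `clip_upper` restores bounded trajectories when frequencies
must remain in [0, 1] (the cohort generator clips its latent draws
independently). The evolutionary Langevin simulator warns when a
trajectory reaches `f ≥ 0.5`, outside its linearization regime.

The sampling pmf, absence probability and truncated prevalence are all
evaluated in log space; the truncated prediction accumulates the `A`-sum
term by term, and a partial-sum brute-force oracle in the tests confirms
exact agreement. Bootstrap and permutation machinery is chunked to bound
memory and fully seeded; every pipeline stage is byte-reproducible under a
fixed config and seed.

## Known limitations

* Moment estimation from read counts inflates the variance by
  `E[f(1−f)/D]`; at shallow depth this deflates `β̂` — and with it the
  predicted prevalence — for sites with `f̄ ≲ β/D`. The estimator is kept
  as defined (no noise correction) because the prediction's claim is
  zero-free-parameter use of the observed moments; consumers should read
  low-`f̄` errors with this in mind. The parameter-recovery tests use deep
  coverage to isolate estimator bias from read noise.
* The truncated prediction assumes a single global `A_cutoff`; pipelines
  whose effective cutoff varies with depth are only approximated.
* Time-dependent solutions `p(f, t)` and the full nonlinear
  mutation–selection–drift equation are out of scope; only stationary (or
  `f_max`-parameterized) forms are provided.
* The strain-structure indicator is consumed as input (or simulated as
  ground truth); no strain inference is performed.
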