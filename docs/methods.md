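# Methods

## The discrete-choice model

The core of the package is a hierarchical Bayesian probit model of
pairwise purchase choices. A choice task presents two cars, each a
(programming model, price) pair drawn from the 3×3 grid of programmes
{save-the-most, save-the-occupants, save-the-pedestrians} × prices
{£15k, £19k, £23k}; the canonical design enumerates all C(9,2) = 36
unordered pairs of distinct offers in a fixed deterministic order. Yen
prices are converted at the 150 ¥/£ rate implied by the matched
GBP/JPY price lists, so all utilities live on the £k scale.

For participant *i*, the utility difference between cars A and B is
ΔU = (Price_B − Price_A) + (Prog_A − Prog_B), with Prog equal to 0 for
save-the-most and to the individual utilities Ped_i or Occ_i (£k) for
the other two programmes. The probability of choosing A is
Φ(τ_i ΔU), a single-trial Bernoulli likelihood per record. Individual
parameters are exchangeable draws from population normals:
Ped_i, Occ_i ~ N(HPed/HOcc, 1/Ht) and τ_i ~ N(Hτ, 1/Ht2). The priors
are weakly informative: N(0, variance 10) on HPed and HOcc (on the £k
scale, so ±2 prior sd spans roughly ±£6,300) and Gamma(shape ½, rate ½)
on Hτ, Ht and Ht2. All prior constants are overridable through
`PriorConfig`.

Willingness to pay is the premium −1000 × utility in pounds, so a
positive premium means the programme is disfavoured relative to
save-the-most and the population would need a discount of that size to
accept it. HDIs are transformed the same way (negation swaps the
endpoints).

## Sampler

Sampling uses Albert–Chib latent-variable augmentation: each Bernoulli
record is represented by a latent normal z ~ N(τ_i ΔU, 1) truncated to
the side of zero matching the observed choice. Conditional on z every
block is conjugate:

* (Ped_i, Occ_i): bivariate normal, solved in closed form per
  participant (the 2×2 cross-product matrix of programme contrasts is a
  design constant);
* τ_i: scalar normal, untruncated, following the hierarchy as written;
* HPed, HOcc: normal; Ht, Ht2: gamma.

Only Hτ, whose gamma prior is not conjugate to the normal hierarchy,
takes a scalar random-walk Metropolis step. Its proposal scale is
adapted toward 44% acceptance during burn-in only, so the retained
portion of each chain is a fixed-kernel Markov chain. Truncated-normal
draws use the complementary inverse-CDF form
`t = −Φ⁻¹((1−u)·Φ(−a))`, which remains accurate far into the tails.

Chains are initialised at prior/population means with per-chain jitter;
per-chain generators derive from a single seed via `SeedSequence`, so
identical (data, config, seed) reruns are bitwise identical. The default
desk-scale configuration is 3 chains × 5,000 samples with 1,000 burn-in;
the original survey-scale setting (3 × 50,000, burn-in 5,000) is
available behind `--paper-scale`. Convergence is summarised by the
classic whole-chain Gelman–Rubin R̂ (not split-R̂ — the convention of
the era of tooling the analysis mirrors; arviz's rank-normalised
version is available through `PosteriorSamples.to_inference_data`).
Zero-variance parameter chains report R̂ = 1 by convention. The HDI is
the shortest contiguous interval containing ⌈mass·n⌉ sorted draws.

With zero records the sampler is still defined and targets the prior
exactly (every conditional collapses to its prior); this is used as a
standing prior-recovery check.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
one independent seeded stream per table:

* **Choices.** Individuals drawn from the hierarchy above; one Bernoulli
  record per (individual, scenario) over the full 36-scenario design.
  τ_i is truncated below at 0 in the generator — a negative sensitivity
  would invert a respondent's preference ordering — while the fitted
  model keeps the untruncated hierarchy exactly as specified. With the
  default precisions the truncated mass is below 0.2%, so the mismatch
  is negligible; the WTP report flags any posterior putting more than 1%
  predictive mass on negative sensitivity.
* **Categorical preferences.** One latent unframed draw per participant
  from the country's marginal shares; each family framing switches the
  latent draw to the frame-congruent option (occupants for the
  family-as-passenger frame, pedestrians for family-as-pedestrian) with
  a per-frame probability π; the moral question is an independent draw
  from the same marginal, reflecting that stated moral preference need
  not match purchase preference. Independent draws make the
  moral-vs-unframed pair exchangeable, which doubles as the symmetric
  null for calibrating the Bowker test.
* **Likert willingness.** One latent N(baseline_mean, baseline_sd) per
  participant; a mandate subtracts `mandate_drop` before discretisation
  iff the mandated programme differs from the participant's unframed
  preference (a RANDOM preference differs from every mandate); latents
  are rounded then clipped to 1..7.

### Preset values

Country presets fix the population means to the published estimates
(UK: HPed −10.7 £k, HOcc −3.17 £k, Hτ 0.291 per £k, n = 186; Japan:
HPed +4.18, HOcc −6.47, Hτ 0.388, n = 346) and the categorical/Likert
settings to the observed marginal shares and means. The hierarchy
precisions have no published point values, so the presets carry package
defaults, chosen once: Ht = 0.25 (individual programme-utility sd of
£2k) and Ht2 = 100 (individual sensitivity sd of 0.1 per £k). These
were picked so that (a) population means are estimable at the study's
sample sizes — the sampling error of a population mean is then an order
of magnitude below the premium scales of interest — and (b) the
generator's τ truncation at 0 is a ≥3σ event. Real survey populations
are likely more heterogeneous than this (published individual-level
distributions spread over tens of thousands of pounds), which is the
main respect in which passing recovery tests do **not** certify
real-data behaviour: with substantially larger individual spread the
population means carry proportionally more sampling noise at n ≈ 200.

The generator also does not emulate attention checks, drop-out,
demographics, item non-response, or any correlation between a
participant's discrete-choice utilities and their categorical/Likert
answers beyond the mandate-drop mechanism.

## Known limitation: sensitivity-scale coupling

τ_i and the utilities enter the likelihood only through the product
τ_i ΔU, so the split of scale between them is identified by the fixed
price differences. With 36 binary records per participant the
individual τ_i are weakly informed, their posteriors are right-skewed,
and the Gamma(½,½) prior on Ht2 (prior mean 1) resists the large
precision (100) the generator uses. The net effect, confirmed against
an independent ensemble sampler on the same data (so it is a property
of the posterior, not of the Gibbs implementation), is a modest upward
drift of the posterior mean of Hτ (≈ +5–12% at the preset scales) with
a matching few-percent shrink of the utility magnitudes. Point
recovery of all population parameters stays comfortably within the
recovery tolerances, and interval coverage for HPed/HOcc holds at
roughly nominal rates (the `recover` subcommand tabulates this), but
95% HDIs for Hτ itself under-cover the generating value at the Japan
scale. This is the expected behaviour of the specified model when the
generating precision sits in its prior's far tail, and is why the
recovery experiment reports coverage per hyperparameter rather than a
single pass/fail.

## Numerical and convention choices

* Bowker's symmetry statistic sums (n_ij − n_ji)²/(n_ij + n_ji) over
  informative pairs only (pair-sum > 0), and df counts those pairs —
  the behaviour of common statistics packages, and the published df 6
  on a full 4×4. On a 2×2 the statistic is the uncorrected McNemar.
  Degenerate tables (no informative pair) raise an error.
* The two-sample t-test is pooled-variance Student (df n₁+n₂−2), which
  is what reproduces a df of 530 at group sizes 186 and 346; the paired
  test uses df n−1. A paired test on identical vectors reports t = 0,
  p = 1 by convention.
* "Likely to buy" means response > 4; response 4 is "neither". Shares
  are reported in percent, rounded half-up to one decimal.
* Percentages in the eight-cell mandate-overlap partition are computed
  over participants with all three mandate responses; incomplete
  participants are excluded with a logged count. Readers of the raw
  tables should note the partition is exhaustive including empty cells.
* Table readers validate enumerations, ranges and key uniqueness and
  report the 1-based file line of the first offending row; responses
  are never imputed.
* Problem sizes: the acceptance script and the recovery tests run the
  preset sample sizes (186 and 346 participants × 36 scenarios) with
  3 chains × 6,000 samples (1,500 burn-in), a scale at which hyper-
  parameter R̂ is typically below 1.05 and posterior-mean Monte Carlo
  error is small relative to the recovery tolerances; replicated
  coverage experiments use 2 chains × 3,000 samples.
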