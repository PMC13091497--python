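# Methods

`adaptsel` quantifies the efficiency of selection strategies that must pick
the true top performers of a cohort while only observing imperfect
predictors: measurable traits, and win/loss outcomes from repeated 1v1
contests. This note records the model, its assumptions, the numerical
choices, and what the synthetic data do and do not establish.

## The simulated cohort

Each replicate draws a population of `n_individuals` (default 100) per sex.
Traits live on a standardized scale and are linked by a Gaussian chain with
unit slopes and zero intercepts:

    body_length  ~ N(0, 1)
    claw_size    = body_length + N(0, s_cs)      s_cs: 0.26 (M), 0.22 (F)
    claw_strength= claw_size   + N(0, s_st)      s_st: 0.54 (M), 0.69 (F)

Only the residual standard deviations are sex-specific; with unit slopes
they fully determine the trait correlation structure
(Var(claw_strength) = 1 + s_cs² + s_st², verified by Monte Carlo in the
tests). The composite trait score is the equally weighted sum of the
sex-relevant components — claw size + claw strength for males, body length
+ claw strength for females.

Latent competitive ability ("true dominance") is the composite score
standardized to unit variance plus Gaussian noise with s.d. 0.7:

    y = z(x) + N(0, 0.7)

The noise is applied on the standardized-predictor scale so that 0.7 is
interpretable as a fraction of the predictor's spread; the implied
trait–dominance correlation is 1/√(1 + 0.7²) ≈ 0.82. Ranking by y defines
the true rank; the true top k is the best `true_top_fraction` (default 10%,
k = 10) of the population. All ranks in the package use one convention:
rank 1 is best, dense 1..N, exact ties broken deterministically (by id, or
by trait rank where stated).

## Contests

Each round pairs individuals uniformly at random without replacement (odd
cohorts: one uniformly chosen sit-out). The higher true dominance always
wins; outcomes are deterministic and therefore transitive, and a tie in
dominance is surfaced as an error rather than broken silently. The default
schedule is 20 rounds of 50 pairs.

## Bradley–Terry ranking

P(i beats j) = σ(a_i − a_j). Deterministic outcomes are perfectly
consistent with a total order, i.e. quasi-completely separated, so the
unpenalized MLE diverges. The fitter exposes two regimes:

- **λ > 0 (ridge)** — maximizes
  Σ log σ(a_w − a_l) − λ Σ a_i² by damped Newton iteration (backtracking on
  the strictly concave objective) to gradient norm < 1e−8. Because the
  likelihood depends only on differences, the maximizer automatically sums
  to zero. This regime is tested against brute-force grid-search oracles and
  is the right choice when finite, converged abilities are needed.
- **λ = 0 (ML, the default)** — plain Newton/IRLS from a zero start with
  the standard GLM iteration cap of 25 and a reference individual fixed at
  zero (a 1e−10 diagonal stabilizer handles disconnected comparison
  graphs). Under separation the iterates grow steadily and the cap
  terminates the fit; the returned estimates are the conventional
  capped-iteration solution produced by logistic-regression Bradley–Terry
  software on such data, and their *ordering* is the usable output.

The ML regime is the experiment default because the reproduction target is
the behaviour of standard paired-comparison fits on separable contest data.
The ridge regime ranks sparse deterministic records noticeably better (it
pools strength-of-schedule information fully), which is desirable for new
analyses but does not describe the standard procedure; the two regimes
agree as data accumulate. Individuals with no contests keep ability 0,
are flagged (`n_contests = 0`), and rank after contested individuals of
equal ability. Fits are refit on cumulative records every two rounds.

## Selection strategies and the capture statistic

A strategy's cost is `min_selected`: the smallest cutoff c such that the
top-c set of the candidate ranking contains every member of the true top k
— equivalently the worst candidate rank held by a true-top member
(brute-force-verified for all instance sizes ≤ 12). Strategies:

- **trait-only** — rank by composite trait score (available pre-contest);
- **contest-only** — rank by fitted Bradley–Terry ability;
- **hybrid(α)** — re-rank by h_i = α·trait_rank_i + (1−α)·contest_rank_i,
  on the grid α ∈ {0, 0.1, …, 1}; α = 1 and α = 0 reproduce the pure
  strategies exactly. Hybrid ties break by trait rank then id. Combining
  rank vectors (rather than standardized scores) was also checked
  empirically: the two conventions give statistically indistinguishable
  grid means here, and ranks are the simpler, scale-free choice.

Two scenarios share a single contest stream per replicate. The
*all-individuals* scenario uses every contest. The *pre-cut* scenario
models squad pre-selection: only the top 40 by trait rank are admitted, and
only contests fought among them are used — so each admitted individual
accrues roughly 40% as many usable contests per round, which is why early
pre-cut rankings are noisier than the same rounds in the full scenario.
The true top k stays defined on the full population; when trait noise
pushes a true-top member below the cut (about a quarter to a third of
replicates at the default noise levels), capture is unattainable in that
replicate, the cell is recorded as missing, excluded from the mean, and
counted in the log (`n_effective` reports the remaining replicates).

## Aggregation

20 replicates per sex. Per cell (sex × scenario × round × α): mean,
standard error, and a t-based 95% interval, mean ± t(0.975, n−1)·s/√n. The
"optimal α" per round is the grid arg-min of the cell means, ties resolved
toward larger α (trait information is free before contests, so at equal
cost the trait-heavier weighting is cheaper to run). A cell with fewer than
two usable replicates raises rather than reporting a degenerate interval.

## Empirical-format pipeline

For raw measured data the pipeline derives, within sex:

- **claw size** — PC1 of the seven claw dimensions, computed separately per
  claw on the correlation scale (columns standardized before
  eigendecomposition, since widths and lengths live on different mm
  scales), oriented so larger claws score higher, then averaged over claws
  and re-standardized;
- **claw strength** — the mean of the two per-claw maxima over all trials
  and days, standardized;
- **composite score and trait rank** — as in the simulation.

The capture trajectory uses the Bradley–Terry ranking on all rounds through
the final round as the "true" top k. That choice makes the final-round
capture value equal k by construction — it is the best available estimate
of the hierarchy, not an oracle — and the informative content is how
quickly earlier rounds approach it.

Because no measured cohort ships with the package, a synthetic fixture
generator emulates the layout: 27 males and 32 females; latent traits from
the simulation chain; seven claw dimensions from a one-factor model
(loading 0.9, unique s.d. √(1−0.9²) ≈ 0.44) mapped to positive mm scales;
strength trials (3 per claw per day, 2 days) with 1.5 N trial scatter on a
~22 ± 4 N scale; 10 random contest rounds plus an eleventh round paired by
adjacent preliminary ranks. The fixture reproduces the *structure* of
measured data — factor-correlated dimensions, trial noise, sparse
unbalanced contests — but not its biology (no allometry, no claw loss, no
behavioural effects), so pipeline tests establish correctness of the
computations, not field validity.

## Problem sizes and determinism

The default experiment (2 sexes × 20 replicates × 20 rounds, ~10 cumulative
fits of ~100 abilities each per scenario) runs in well under a minute on a
single core; all analysis drivers and the acceptance script use these full
default sizes. A master seed spawns one independent RNG stream per
(sex, replicate) via `numpy.random.SeedSequence` spawn keys, so replicates
are bit-reproducible in isolation and independent of execution order.

## Known limitations

- Trait-link slopes are fixed at 1 on the standardized scale; real
  morphometric allometry is not modelled.
- Contest outcomes are deterministic; probabilistic (logistic) outcomes
  would weaken contest information and shift the trait/contest trade-off.
- The ML regime's ability *magnitudes* are artifacts of the iteration cap
  under separation; only rankings should be consumed from it.
- Pre-cut cells with excluded replicates have reduced effective sample
  size, and their means condition on the true top surviving the cut.
- The optimal-α report does not propagate uncertainty in the arg-min.
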