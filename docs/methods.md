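# Methods

## The clustered binomial model

A dauer assay plate with `n` animals and `y` dauers contributes a binomial
observation whose log-odds combine a strain mean and three Gaussian random
intercepts:

```
logit p = beta_strain + b_day + b_strain:day + b_plate
```

* `sd_day` (sD) — day-to-day variation shared by every plate run on a day
  (incubator temperature, handling).
* `sd_history` (sG) — strain-by-day culture-history variation: each
  strain's growth batch pushes it in its own direction on a given day, so
  the intercept is drawn independently per strain x day cell.
* `sd_plate` (sP) — residual plate-to-plate variation.  With one binomial
  observation per plate this component is only weakly identified (it is
  confounded with binomial noise); its estimate shrinking toward zero on
  small designs is expected behavior, not a defect.

All three are standard deviations on the logit scale.  The defaults used
by the simulation study are `low = (0.25, 0.25, 0.25)` and
`high = (1.0, 0.5, 0.5)`; the magnitudes are package choices (chosen so
the high preset visibly breaks the plate-level tests while remaining
within the range of day effects seen in real assay variation), and every
study accepts custom values.

## Laplace maximum likelihood

The frequentist GLMM integrates the random effects out with the Laplace
approximation: for each candidate `(beta, log sd)` the inner Newton solver
finds the joint mode over the random effects and the marginal likelihood
is evaluated from the mode and the log-determinant of the joint Hessian.
A random-intercept block with one level per observation (the plate effect)
has a diagonal Hessian block, so the Newton step and determinant are
computed through the Schur complement on the remaining small blocks; cost
is linear in the number of plates.  The inner solver is JIT-compiled
(numba) with a pure-numpy fallback; both paths share the same arithmetic.

Outer optimization is L-BFGS-B over `(beta, log sd)` with the variance
parameters floored at `log sd = -10`.  Because the profile likelihood of a
null variance component has a flat shoulder, a boundary polish step snaps
any component to the floor when that does not worsen the fit, then
re-optimizes the fixed effects.  Wald covariance conditions on the fitted
variance components (the usual mixed-model convention), so the reported
intervals slightly understate variance-parameter uncertainty — visible as
coverage a little below nominal on 3-day designs.  With no random terms
the model reduces to an ordinary binomial GLM (statsmodels), for which a
pure strain-indicator design gives exactly the logits of pooled
proportions.

Complete separation (an all-0 or all-1 strain) is handled by a weak ridge
penalty on the fixed effects (default 0.01) plus a `degenerate` flag,
keeping estimates finite without failing the fit.

## The Bayesian GLMM

Priors are weakly informative: Normal(0, 2.5) on each strain log-odds and
half-Normal(0, 1) on each random-effect sd (configurable).  Rather than
sampling the high-dimensional joint posterior, the sampler reuses the
Laplace marginalization and runs MCMC on the low-dimensional marginal
posterior over `(beta, log sd)`:

1. locate the posterior mode and build a Student-t (df 5) proposal from
   the inverse Hessian, ~30% wider than the matched posterior sd;
2. refine the proposal once by importance-weighted moment matching on a
   200-point pilot sample (kept only if the weights retain enough
   effective sample size);
3. run independent seeded chains of a mixture kernel — 60% independence
   proposals accepted with the full Hastings ratio, 40% preconditioned
   random-walk moves — thinned (default 8) so the retained draws are
   nearly independent.

Convergence is declared when every parameter's split-R-hat is at most
1.05; the flag, R-hat and acceptance rates are in `diagnostics`.  The
Laplace approximation inside the likelihood is very accurate for binomial
plates with tens of animals; its error is far below Monte-Carlo noise at
the default draw counts.  Credible intervals are equal-tailed quantiles of
the response-scale posterior draws (95% and 75%, the thick/thin interval
bars convention); "detection" of a contrast means its 95% interval
excludes zero, with the posterior two-sided tail probability stored so
detection can be re-evaluated at any level.  A prior-only mode draws from
the priors directly, as a check that intervals reproduce prior quantiles.

## The method-comparison study

Each condition simulates a control plus two test genotypes, 6 plates over
3 days per group, ~50 animals per plate; the effect scenario shifts one
genotype by 1 logit.  The baseline log-odds is 0 (p = 0.5), a package
choice exposed in `ComparisonCondition.baseline_logit`.  Unbalanced
designs keep the control on every day and drop each test group from one
day, reallocating its plates; the bias condition adds `+1 x sd_day` to the
control's day effect on a randomly chosen third of days (control only).
Per-comparison rejection (raw p < alpha for the frequentist methods, 95%
credible interval excluding 0 for the Bayesian fit) is the primary metric;
family-wise (multivariate-t adjusted) rejections are logged alongside, and
the per-replicate log allows recomputing rates at any alpha without
refitting.  Replicates where a fit does not converge are excluded from
that method's rates and counted.  Monte-Carlo uncertainty is
`sqrt(r(1-r)/n_reps)`.

## Multiple comparisons

Dunnett (each vs control) and Tukey (all pairs) families use the
single-step max-|T| adjustment: `p_adj = Pr(max_j |T_j| >= |t_i|)` under
the central multivariate t with the fit's df and the contrast correlation
matrix (multivariate normal for Wald/z contrasts).  Rectangle
probabilities come from scipy's QMC integrators under a fixed seed;
adjusted values are reproducible to three decimals and never fall below
the raw p.

## Track analytics

The turn angle at an interior frame is
`arccos[(v12 . v23)/(|v12| |v23|)]` in degrees (0 straight, 180 reversal),
where v12, v23 are consecutive displacement vectors; the raw cosine is
also exposed for audit.  Frames where either displacement falls below the
stationary threshold (default 1e-4 mm/s over one frame) have undefined
angle and are excluded from bin means — zero-filling them would bias
dwelling bins toward low turning.  Bins are consecutive complete 10-s
windows (30 frames at 3 fps; trailing partial bin dropped; a bin with >50%
undefined angles is labeled undefined).  A bin is roaming when
`speed > slope x angular velocity` with slope 2 on the working scale —
speed in um/s against degrees/frame by default; because the separating
line is defined on plotted axes whose units are an assay convention, both
unit multipliers are configuration.  Ties go to dwelling by default.

Grid-entry scoring lays a square lattice over the circular arena, keeping
cells whose centers fall inside; the cell size is chosen so the kept-cell
count is closest to the 188-square convention (the realized count is
reported).  An entry is a transition into a cell from a different cell,
plus one for the starting cell; per-cell counts cap at 10.  The score
depends only on the sequence of distinct cells visited, hence is invariant
to temporal upsampling of the same path.  Positions outside the arena are
clipped to the rim with a warning count.  No Kalman or other smoothing is
applied; an optional moving-average smoother was considered and rejected
as out of scope for coordinate-table input.

## The synthetic-data generators

The assay generator draws exactly the clustered model above (day effects
shared across strains; history effects independent per strain x day;
per-plate effects; binomial sampling), with unbalanced allocation and
control-day bias as in the comparison study.  The track generator is a
two-state Markov chain per frame (dwell/roam) with state-specific speed
(mean, sd in mm/s; dwell 0.02, roam 0.15) and Gaussian heading increments
(dwell 50 deg/frame, roam 5 deg/frame), positions folded radially at the
arena wall; default switch rates 0.0015 (dwell->roam) and 0.0035 per frame
give stationary roaming occupancy 0.30 with state durations of one to a
few minutes.  The grid-count generator is Poisson with lognormal day and
per-worm multipliers, truncated at the maximum attainable score.

What the generators deliberately omit: within-state speed autocorrelation,
posture and omega-turns, lawn-edge behavior, tracker segmentation noise,
dauer-exit dynamics, and any non-Gaussian day effects.  Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real video or assay data.

Randomness: every public entry point takes one seed; replicates and worms
use spawned child streams, so replicate k is reproducible in isolation and
identical seeds give byte-identical outputs.

## Numerical choices and limitations

* Logits are clipped at +/-30 inside likelihoods; variance floors at
  `exp(-10)`; Welch tests floor a zero group variance at 1e-12 and flag
  the contrast degenerate.
* Likelihood-ratio tests use the naive chi-square with df = parameter
  difference (matching the df = 1 reporting convention for single-locus
  effects); a boundary-corrected 50:50 mixture variant is provided for
  variance components.
* The study presets in `wormassay.studies` run at 10,000 calibration
  plates, 200 recovery replicates, 50 Bayesian-coverage replicates, 200
  error-rate replicates per condition (Bayesian fits at 2 chains x 500
  draws), and 20 tracked worms — sizes chosen to keep Monte-Carlo error
  well inside the properties being checked while remaining desk-scale.
* Known limitations: sP is weakly identified from one observation per
  plate; Wald coverage conditions on variance estimates, and with only 3
  days of clustering the frequentist GLMM's Wald tests can be markedly
  anticonservative under unbalanced, biased designs; conversely the
  Bayesian GLMM is strongly conservative on small designs — with
  half-Normal(0, 1) priors the posterior on three variance components
  cannot concentrate near zero from 18 plates, so its null rejection rate
  at the default detection rule sits well below alpha (the flip side of
  its robustness under heavy clustering); the Bayesian sampler is tuned
  for the low-dimensional marginal posterior and would need re-tuning for
  models with many fixed effects; the LRT between mixed-model fits
  compares Laplace-approximate likelihoods.
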