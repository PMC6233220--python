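# Methods

## Setting

A WHO cone bioassay exposes 5 mosquitoes for 3 minutes under a plastic cone
pressed on a netting piece; each net contributes 5 pieces (top + 4 sides)
with 4 cones each, 100 mosquitoes in total.  Knock-down (KD) is scored 60
minutes after exposure, mortality 24 hours after; the two are separate
endpoints scored on different schedules, so the package never enforces an
ordering between KD and dead counts.  A net is valid under the mortality
rule if pooled mortality ≥ 80%, under the KD rule if pooled KD ≥ 95%, and
under the mixed rule if either holds.  Thresholds are inclusive.  "Pooled"
means total events over total exposed across the selected cones; with the
balanced design (equal exposure per cone) this equals the unweighted mean of
cone proportions, and pooling stays well defined if exposures ever differ.

## Danger zones (single-net misclassification)

For m mosquitoes treated as i.i.d. Bernoulli(p) trials, the net passes when
the event count X ~ Binomial(m, p) reaches the pass count t.  Conventions:

- **Pass count**: t = the integer nearest cutoff·m (halves up).  For the KD
  cutoff with 3 cones this gives 71 of 75 (a discretized pass mark of
  94.7%), not the 72 that rounding up would give.  This is the
  discretization that reproduces the published reference intervals for this
  design; it also keeps the pass mark as close as possible to the nominal
  cutoff.
- **Misclassification probability**: P(X < t) when p ≥ cutoff (truly valid),
  P(X ≥ t) otherwise.  Exact tails (`scipy.stats.binom`), no normal
  approximation; equality of the two computations with a direct pmf
  summation is asserted to 1e-12 for all m ≤ 100.
- **Zone limits**: on each side of the cutoff the relevant tail is monotone
  in p, so the boundary where it crosses the risk threshold (default 10%)
  is a unique root, found by bisection (`brentq`, xtol 1e-13).  Limits are
  reported to 0.1 pp; the width is the difference of the *unrounded* roots,
  also to 0.1 pp.  (This is why the 1-cone mortality zone is printed as
  66.0–86.9 with width 20.8: the roots are 66.034 and 86.877.)
- A side on which the risk never exceeds the threshold is reported as open
  (`None`); at high thresholds (e.g. 50%) zones become one-sided because
  just below the cutoff the pass probability still exceeds the threshold
  while just above it the fail probability does not.

Deliberately no hierarchy here: between-net/side/cone variability is
excluded so the zone is a property of design size and cutoff alone.

## Hierarchical Bayesian reference model

Per endpoint (mortality, KD), with cones within a side sharing one rate,
side totals y_is out of m_is are sufficient:

    y_is ~ Binomial(m_is, logit⁻¹(α + u_i + v_is))
    u_i ~ N(0, σ_net²),  v_is ~ N(0, σ_side²)
    α ~ N(0, 2.5²),  σ_net, σ_side ~ Half-Normal(1)

The two variance components capture heterogeneity between nets and between
the five pieces of one net; cone-level variation is binomial only.  The
priors are weakly informative on the logit scale: N(0, 2.5²) is flat over
any plausible rate, and Half-Normal(1) admits between-net spreads far wider
than bioassay data show while keeping the scales proper.

A net's quantity of interest is its side-averaged rate, q_i = (1/5) Σ_s
logit⁻¹(α + u_i + v_is) (and p_i for KD) — the model analog of "average
over all cones" in the balanced design.  Posterior draws give each net
Pr(q_i < 0.80), Pr(p_i < 0.95) and the joint Pr(both), the probability of
failing the mixed rule.  Mortality and KD are fitted separately (no
cross-endpoint correlation structure is imposed); the joint probability
pairs draws by index across the two fits, which requires identical
chain/draw settings.  By construction the joint failure probability never
exceeds either marginal.

The *reference classification* of a net is validity probability ≥ 0.5
(inclusive).  A cohort's *expected proportion valid* is the mean of the
validity probabilities, not of the binary flags; both are reported because
they answer different questions (individual classification vs indicator
estimation) and genuinely diverge — three nets at probability 0.6 give a
binary proportion of 1.0 but an expected proportion of 0.6.

### Sampling

No general-purpose MCMC backend being part of the package's dependency
footprint, the sampler is authored here: a vectorized adaptive
Metropolis-within-Gibbs sweep over (v, u, α, log σ_net, log σ_side) with
two kinds of extra moves that target the known pathologies of hierarchical
binomial posteriors:

- **Recentering (ancillarity) moves**: shift mass between u_i and its v_is,
  and between α and all u_i, leaving the likelihood invariant; these break
  the strong location correlations.
- **Interweaved non-centered scale moves**: rescale all effects together
  with their scale (holding standardized effects fixed), slice-sampled so
  they need no tuning; these break the funnel between a scale and the
  magnitude of its effects.

Step sizes adapt toward 44% acceptance during warmup only, so the retained
chain is a valid Markov chain.  Defaults: 4 chains, 1000 warmup, 1000
draws.  Split-R̂ and bulk ESS (arviz) are computed for α, σ_net, σ_side;
R̂ > 1.05 or ESS < 400 triggers a warning, never a silent pass.  Identical
seed and settings reproduce draws bit for bit.

Calibration was verified by simulation: across 40 independent synthetic
cohorts (200 nets), the true hyperparameters fell inside their central 95%
credible intervals 37–39 times out of 40.

## Synthetic cohorts

The generator is the model's generative counterpart plus survey structure:
per net, a bivariate-normal logit-scale pair of (mortality, KD) effects with
correlation ρ (default 0.8, giving the strong positive association between
the two endpoints seen in field cohorts), independent side effects, optional
brand and age offsets, and per-cone binomial counts.  Latent truth per net
is the arithmetic mean of its five side probabilities.

Default calibration (logit means 0.40 / 1.60; σ_net 1.5; σ_side 0.5; age
offsets +0.7 / 0 / −0.7 for new / 6-month / 12-month nets) yields broad
mortality and KD distributions straddling both cutoffs — roughly a quarter
of nets valid by mortality, a fifth by KD, and ~30% by the mixed rule —
the regime in which reduced-effort testing is genuinely at risk.  These
defaults are configuration, not ground truth.

What the generator does *not* emulate: distribution-site effects,
insecticide decay or wash-resistance trajectories, cone-level
extra-binomial variation, or resistance genetics.  Passing tests therefore
demonstrate correctness of the machinery and behaviour under the model's
own assumptions, not external validity for any particular field cohort.  One
consequence worth knowing: the default cohort carries about twice as much
latent mass just below the 80% mortality cutoff as just above it, so
reduced-cone surveys show a small *positive* bias in the proportion-valid
indicator (false passes outnumber false fails); cohorts shaped differently
can show the opposite sign.

## Scenario engine

One scenario = (validity rule, k cones per side, n nets per survey).  Per
iteration: sample n nets without replacement; per net, one cone selection
uniform over the C(4,k)⁵ combinations (per-side draws independent);
classify from the selected cones; score against the reference
classification of the *same* sampled nets.  Scoring the sampled subset
(rather than the full cohort) is deliberate: the indicator error then
reflects measurement error only, not subsampling noise in the reference.

Metrics per iteration: sensitivity (pass rate among reference-valid nets),
specificity (fail rate among reference-invalid nets), accuracy, and the
indicator error diff = 100·(observed proportion valid − reference expected
proportion) in pp.  Iterations whose sensitivity or specificity stratum is
empty record the metric as missing, excluded from means with their count
reported.  Intervals are equal-tailed percentile intervals (2.5/97.5 and
0.5/99.5) of diff across iterations.  The minimum sample size is the
smallest grid n from which containment of the 95% interval in ±5 pp holds
at that n *and every larger grid n* (monotone closure); boundary results
are labelled "<=20" / ">160" on the default 20–160 grid.

The engine is vectorized over iterations (chunked to bound memory) and
bit-reproducible from its seed; the grid runner derives one deterministic
subseed per (rule, k, n) cell from the master seed.

## Problem sizes used by the test suite

The suite exercises the full pipeline at sizes chosen to keep a complete
run in the low minutes on one core while leaving every check statistically
meaningful: recovery studies use 20 replicates of 200-net cohorts;
engine-level distributional checks use 1000 iterations (the production
default is 10,000); the exhaustive-enumeration oracle uses a 3-net toy
cohort where all 7776 two-cone combinations per net can be enumerated
exactly; frozen tolerances for stochastic end-to-end checks were derived
from replicate runs before being asserted.

## Known limitations

- The reference model omits brand/age covariates by design; covariate
  effects surface through the net-level random effect.
- Mortality and KD posteriors are paired by draw index across two
  independent fits; a bivariate random-effect model would propagate
  cross-endpoint posterior correlation into the joint failure probability.
- The danger-zone calculator's i.i.d. assumption understates
  misclassification risk for overdispersed nets; it is a design-planning
  floor, not a field guarantee.
- Minimum sample sizes inherit Monte-Carlo noise of percentile endpoints;
  near-boundary verdicts can move by one grid step between seeds at 1000
  iterations (much less at the 10,000 default).
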