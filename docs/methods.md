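# Methods

## Scope and model

The package analyses three kinds of magnitude-judgement data and simulates
observers for all of them.

**Adjustment (reproduction) tasks.** An observer reproduces a standard of
intensity I. The generative model of a reproduction is

    estimate ~ Normal((1 − w)·I + w·anchor + b,  sd(I))

with central-tendency weight w ∈ [0, 1] (estimates regress toward the
anchor, by default the mean of the presented standards), additive response
bias b, and a noise regime: Weber (sd = c·I), constant (sd = σ0), or affine
(sd = σ0 + c·I). The analysis-side JND at each standard is the
within-participant SD of the reproductions (unbiased, n−1 denominator —
standard practice for within-subject spread estimates, though any convention
would cancel in the fraction's intensity profile), and the Weber fraction is
SD divided by the mean reproduction. Under the Weber regime with w = 0 the
fraction is c at every intensity; under the constant regime it is σ0/I.

**2AFC constant-stimuli tasks.** The probability of judging a comparison of
intensity x greater than the standard is

    P(x) = λ/2 + (1 − λ)·Φ((x − PSE)/σ),

a cumulative Gaussian with location PSE, spread σ and lapse rate λ. One
link family serves both the weight-discrimination and the illusion analyses
for internal consistency. Simulated observers use the same equation, with
σ set per standard by a noise law: `weber` (σ = c·standard), `constant`
(σ = σ0), or `weber_perceived` (σ = c·PSE including any brightness shift —
noise scaling with the *perceived* magnitude, which is what a Weber-adherent
observer should show under a weight illusion).

**Brightness-weight illusion.** Lifted brighter objects are judged heavier
than identical darker ones; the signature is PSE(black) < PSE(gray) <
PSE(white) for a physically constant standard. Susceptibility screening
applies exactly that strict, directional ordering (an any-direction variant
is available); participants with a missing or unconverged fit are
*undetermined*, a third status that completes the partition rather than
being folded into "not susceptible". The Weber question is then whether
JNDs scale with each participant's own per-brightness PSE.

## Estimation choices

**Binomial MLE, not least squares.** Psychometric parameters maximise the
binomial log-likelihood; least squares on proportions mishandles cells at
0% or 100%. The classic sum of squared distances between observed
proportions and the fitted curve is still computed (`deviation_`) because
it is the conventional fit-reliability metric, but it is a report, not the
objective — a consequence is that σ-perturbations of the fitted curve can
occasionally score better on the LS metric, and the test suite checks
near-optimality on the likelihood (always) and on LS under location
perturbations (≥95% of realisations).

**Initialisation and multi-start.** A probit-regression start (linear fit
of Φ⁻¹(clipped proportions) on x) plus the best point of a coarse
13×13 (PSE, σ) grid are both polished with L-BFGS-B on (PSE, log σ); the
better optimum wins. σ is bounded within [span/200, 20·span] of the
comparison range. Lapse is fixed at 0 by default and fittable with an upper
bound of 0.2 when enabled; asymptote behaviour at typical trial counts is
not identifiable enough to free it routinely.

**Non-identifiable cells** (responses all 0 or all 1, or fewer than three
comparison levels) raise `FitError`; the per-participant driver records the
cell as a failed fit with NaN parameters and logs the reason. Nothing is
pseudo-corrected.

**JND by inversion.** JND = (x₇₅ − x₂₅)/2 with the quantile points found by
bisection on the *full* fitted curve (tolerance 10⁻⁶), so lapse-enabled
fits remain correct; for λ = 0 this equals Φ⁻¹(0.75)·σ ≈ 0.674490·σ, an
identity the tests verify to 10⁻⁶ relative tolerance.

**Visual angle** uses the exact 2·atan(d/2D); the small-angle approximation
differs at the second decimal already at 2.4°.

## Bias correction and screening

Per participant, corrected_bias(I) = (mean estimate − I) − (perceived grand
mean − physical grand mean). The correction removes the participant's
overall response shift, so corrected biases sum to zero across standards —
an algebraic identity the suite property-tests. Because that identity also
makes the participant-mean of corrected biases useless as a screening
statistic, outlier screening operates on the overall shift itself (the mean
estimation bias), flagging participants below group mean − 2.5·SD
(one-sided; a two-sided switch exists). The reference statistics are
computed leave-one-out: a single extreme participant inflates an inclusive
SD enough to mask itself at realistic group sizes. Screening precedes all
downstream statistics and can be disabled as a sensitivity toggle.

## Group statistics

The mixed ANOVA uses the classical univariate split-plot decomposition on a
complete (subject × level) matrix. With unequal group sizes the between- and
within-subject strata are computed from weighted (per-observation) marginal
means, so SS_total partitions exactly — the suite checks conservation to
10⁻⁹ relative tolerance — while the interaction and both error strata
coincide with the usual least-squares ones because the within factor is
fully balanced. Degrees of freedom are the uncorrected integers
(g−1, N−g) / (L−1, (N−g)(L−1)); Greenhouse–Geisser correction exists behind
a flag but is off by default. Partial η² = SS_effect/(SS_effect +
SS_error-of-stratum). Zero error variance flags the result degenerate
(F = ∞) rather than raising.

Linear trends use centered weights on the level *index* (equally spaced
levels make index and physical spacing identical up to scale, which leaves
F unchanged; a physical-spacing mode exists). The contrast is tested per
group with df (1, n−1); the reported estimate is the mean per-subject
contrast score.

Within-subject CIs follow Cousineau normalisation (subtract the subject
mean, add the grand mean) with the Morey L/(L−1) variance correction —
the prevailing convention for error bars on repeated measures.

Two-sample comparisons default to the pooled-variance Student t
(df = n₁+n₂−2); Welch is a flag.

## Synthetic-data conditions

The default pipeline configurations fix the study conditions:

* **Size reproduction**: standards 25.5/35.5/45.5/55.5 mm, 16 repetitions;
  a Weber group (c = 0.08, w = 0.3) of 20 versus a constant-noise group
  (σ0 = 3.2 mm — c·mean intensity, so the groups match at mid-range —
  w = 0.05) of 26. The central-tendency weights encode the observation that
  the constant-noise population shows the smaller regression-to-the-mean
  bias.
* **Weight discrimination**: standards 300–450 g in 50 g steps, 12
  comparisons in 6 g steps, 12 repetitions; Weber group n = 12 (c = 0.07)
  versus constant group n = 11 (σ0 = 25 g, again matched at mid-range).
* **Illusion**: one 129 g standard at black/gray/white, 11 comparisons in
  7 g steps (centered on the standard — the odd, centered placement is the
  configurable default), 12 repetitions; brightness shifts of ∓6 g (about
  one comparison step, a realistic illusion magnitude at this weight);
  Weber-perceived group (c = 0.1, a typical weight Weber fraction) versus
  constant group (σ0 = 13 g = c·129).

Negative simulated reproductions are truncated at zero with a logged count
(physically impossible sizes); at the default noise levels truncation is
vanishingly rare. Per-participant random streams are spawned sequentially
from the master `SeedSequence`, so enlarging a group never perturbs the
trials of earlier participants. Estimates are treated as continuous (no
pixel quantisation), and presentation details such as the adjustment
cursor's start value are carried as inert design metadata.

What the simulator deliberately does not emulate: session/break structure,
muscle fatigue, the empirically noisier lower half of weight psychometric
functions (no asymmetric noise term), response quantisation, and any
mechanism *behind* the illusion — only its PSE signature. Passing tests on
synthetic data therefore validate the estimators and the pipeline's
bookkeeping, not claims about any particular human population.

## Problem sizes and numerical tolerances

Monte-Carlo checks use sizes chosen to make their targets statistically
sharp at desk scale: SD-law checks at 10⁴ repetitions per standard
(tolerance 3 standard errors of an SD), parameter recovery over 200
simulated observers at the full weight design, regime discrimination over
100 simulated two-group experiments, and the interaction test's type-I
error over 2000 null datasets (expected 5% ± 1.5 points). The dense
grid-search oracle for the MLE uses a 0.25 g mesh. Bisection tolerances are
10⁻⁶; SS-conservation and closed-form identities are asserted at 10⁻⁶–10⁻⁹
relative tolerance.

## Known limitations

* The ANOVA is the classical univariate split-plot; no REML mixed-effects
  modelling, no post-hoc families (planned contrasts only).
* No bootstrap or Bayesian uncertainty on individual psychometric
  parameters — recovery is characterised across simulated seeds instead.
* The screening statistic for adjustment outliers is a design choice (see
  above); with real data whose original screening rule is unknown, results
  should be checked with screening disabled.
* `validate_trial_table` checks schema, ranges and balance, not semantic
  plausibility (e.g. impossible-but-positive weights pass).
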