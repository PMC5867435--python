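# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `carevoice`.

## The collective judgement score

Every eligible feedback item carries a calendar date and an integer star
rating in 1–5 (microblog posts receive theirs from the sentiment model). The
collective judgement score (CJS) of organisation *o* on date *d* is the
unweighted mean of the stars of all items attributed to *o* dated within the
inclusive trailing window [*d* − *w* + 1, *d*], with *w* = 90 days by default.
The score is reported only when the window holds at least `min_items` = 10
items; below that, a handful of comments would dominate and trigger spurious
alerts. Both constants are `CJSConfig` fields.

Window convention: the window *includes* the evaluation date, so feedback on
an inspection's start date counts towards the score paired with that
inspection. The alternative (strictly-before) convention is a one-day shift
of the same computation and is available by evaluating at *d* − 1.

Attribution: hospitals score their own items. Trusts, under the default
`pool_hospitals_and_trust`, pool their own accounts' items with every child
hospital's items — social-media presence sits at either level depending on
the organisation, and pooling is what makes trust-level scores computable at
scale. `trust_accounts_only` restricts to the trust's own accounts.

All items are weighted equally regardless of source. Source weighting is a
plausible refinement but is deliberately not implemented; the unweighted mean
is the baseline everything else would be compared against.

Smoothing for display uses LOESS (tricube-weighted local linear regression,
via statsmodels' `lowess`) with span 0.75 and no robustness iterations;
constant and linear series are reproduced exactly, which the tests assert.

## The ordinal outcome model

Inspection ratings are ordered: Inadequate < Requires improvement < Good <
Outstanding. The model for a rating given the CJS *x* at inspection start is
cumulative-logit with threshold-specific slopes:

P(rating ≤ k | x) = σ(θ_k + β_k x), k = 1..3.

Each of the three thresholds (at-most-Inadequate, at-most-Requires-improvement,
at-most-Good) gets its own intercept θ_k and slope β_k; exp(β_k) is the odds
ratio for a worse-or-equal rating per additional star of CJS. The
`proportional=True` option constrains β_k ≡ β (proportional odds). The
threshold-specific form is the default because the association between
feedback and ratings is empirically stronger at the top of the scale than at
the bottom, and a single β would average that away.

Estimation is maximum likelihood on the multinomial likelihood with cell
probabilities P(k) = σ(θ_{k+1} + β_{k+1}x) − σ(θ_k + β_k x). Numerics:

- **Start values.** The proportional-odds model is fitted first (from
  marginal-logit intercepts and β = 0) and its solution seeds the
  threshold-specific fit. The proportional-odds log-likelihood is concave;
  the threshold-specific one need not be, and a good start matters.
- **Optimisation.** BFGS with the analytic gradient, followed by Newton
  refinement using a finite-difference Hessian of the analytic gradient,
  stopping at gradient sup-norm < 1e-6. Cell probabilities are clipped at
  1e-12 inside the likelihood so line searches can cross transiently
  infeasible regions (where cumulative curves cross).
- **Separation.** If parameter estimates exceed 80 in absolute value, or the
  fitted per-observation probabilities are all above 0.999 (a perfect fit —
  the likelihood plateaus and the gradient check alone would falsely report
  convergence), the fit raises an explicit non-convergence error rather than
  returning boundary estimates.
- **Standard errors** come from the inverse observed information (the Newton
  Hessian at the optimum); Wald intervals on the odds-ratio scale are
  exp(β ± z·SE) with z_{0.975} = 1.959964; p-values are two-sided normal.
- **Empty categories.** A rating category with zero observations at an
  extreme of the scale leaves its boundary threshold without a finite MLE;
  such categories are collapsed (with a warning) and the fit runs over the
  observed range. This happens routinely for "Outstanding" at trust-level
  sample sizes. Empty *middle* categories are retained.
- **Prediction.** Category probabilities are cumulative differences; with
  threshold-specific slopes the curves can cross far outside the data range,
  in which case negative cells are clamped to zero and the vector
  renormalised, with the event logged.

Hospital-level and trust-level inspections are always fitted separately:
trust ratings are aggregates of hospital ratings, so pooling the two levels
in one likelihood would treat dependent outcomes as independent. The fits
here are fixed-effects; grouped random intercepts/slopes would be a natural
extension but the added machinery is not needed for any quantity this
package reports.

## The text pipeline

Microblog posts are mostly not feedback about care quality, so they pass a
five-class relevance classifier (four care-quality classes — patient
experience and effectiveness, environment and facilities, timeliness and
access, safety — plus not-care-quality) before a sentiment model assigns the
surviving posts a 1–5-star score on the same scale the rating sites use.

Both tasks share one training procedure, in this order: (1) hold out 25% of
the labelled corpus, stratified; (2) within each of 5 cross-validation folds
of the training split, oversample every minority class to the majority
class's count by within-class sampling with replacement — *training folds
only*, so validation and holdout items are never duplicated or leaked;
(3) pick the grid point (inverse-regularisation C ∈ {0.1, 1, 10}) with the
best mean cross-validated metric — macro-F1 for relevance, exact accuracy
for sentiment; (4) refit on the full oversampled training split and report
holdout metrics (macro and micro for relevance, since "overall" can mean
either; exact and within-one-star accuracy for sentiment).

The model family is a linear bag-of-words classifier: lowercased tokens,
unigrams + bigrams, minimum document frequency 2, multinomial logistic
regression (scikit-learn). Dictionary-based sentiment is deliberately not
used — generic sentiment lexicons transfer poorly to health-care text — and
the procedure above, not the model family, is what the package specifies.
Texts containing no in-vocabulary token are assigned the training-majority
label and the event logged.

Cohen's κ = (p_o − p_e)/(1 − p_e) is computed from observed agreement and
the product of rater marginals; the degenerate case p_e = 1 raises an
explicit error rather than returning a conventional value. Per-class
precision/recall/F1 flag zero-denominator classes as undefined instead of
silently scoring 0.

## The synthetic-data generator

The generator produces the study conditions every downstream stage is tested
under. Defaults (all `GeneratorConfig` fields):

- **Organisations.** 140 trusts, each with 1–3 hospitals (uniform), ≈ 280
  hospitals — the scale at which a national acute-care regulator operates.
  Latent quality q is standard normal per hospital, split 50/50 between a
  trust-level component and an independent hospital deviation, so sister
  hospitals are correlated.
- **Period.** One year (2016-03-01 to 2017-02-28), the window in which all
  three sources are jointly observable.
- **Sources.** Per-organisation daily rates 0.22 (rating site), 0.21 (social
  reviews), 0.50 (microblog, pre-filtering), Poisson counts, uniform dates.
  Mean stars 3.85 / 4.13 / 4.28 respectively for an average (q = 0)
  organisation. Microblog posts are 30% reposts, 5% organisation-authored
  (both removed by the eligibility filter) and only ~8.8% care-quality
  relevant, mirroring the heavy noise of that channel. Rates are uniform
  across organisations; real feedback volume is heavy-tailed, so the
  generator understates the number of low-volume organisations excluded by
  the 10-item floor.
- **Stars.** Drawn from a discretised latent-logistic distribution: latent
  L ~ Logistic(μ, 1) cut at 1.5/2.5/3.5/4.5, with μ solved numerically so
  E[stars] = mean_stars + quality_effect·q, clamped to [1, 5];
  quality_effect = 0.3. The latent-logistic family matches the downstream
  cumulative-logit model, making parameter recovery a well-posed test; a
  rounded Gaussian would not.
- **Ratings.** One inspection per organisation at a uniform date, rating
  drawn from P(rating ≤ k | q) = σ(θ_k − 2q), with θ solved (Gauss–Hermite
  quadrature + root finding) so the *marginal* class frequencies are 10%
  Inadequate, 61% Requires improvement, 26% Good, 3% Outstanding — the
  heavily imbalanced distribution regulators actually produce. 5% of
  inspections are left unrated.
- **Text.** Synthetic posts are token sequences: a topic block drawn from the
  post's class vocabulary with probability `separation` (else a shared
  vocabulary) and a tone block encoding the star level the same way. The
  leading tokens of each block are fixed anchors, so at separation = 1 every
  class is identifiable from any single post — the corpus is exactly
  Bayes-separable, which is what lets tests assert near-perfect holdout F1
  as a property of the *procedure* rather than of a lucky draw. At
  separation = 0 every class draws from identical distributions (irrelevant
  posts carry generic tone tokens so length alone cannot leak the label) and
  no classifier can beat the majority class in expectation. Default
  separation 0.9. The texts are token soup, not language: results about
  them validate the pipeline's mechanics, not natural-language performance.
- **Change-points.** An optional step drop in mean stars for named
  organisations at a named date, used to demonstrate that the windowed score
  tracks sudden deterioration with at most a window's lag.

All randomness flows from a single integer seed through named
`SeedSequence` children, so equal configurations give byte-identical output
streams.

What passing tests on this generator do *not* show: robustness to gaming or
coordinated review campaigns, demographic bias of individual sources,
temporal confounding by news events, or natural-language understanding —
none of which the generator attempts to emulate.

## Prioritisation evaluation

Given the paired dataset (one row per rated inspection with a defined CJS),
`rank_and_select` takes the *n* lowest-CJS rows, breaking score ties by item
volume (a low score supported by more feedback is more actionable) then by
organisation id, and `evaluate_prioritisation` tabulates selection against
rating. Precision is the share of selected organisations rated Inadequate or
Requires improvement; the chance baseline is the marginal at-risk rate,
which is exactly the expected precision of uniform random selection (a
Monte-Carlo test asserts this). The "burden" counts — Good and Outstanding
organisations selected — measure unnecessary inspections.

## Problem sizes and determinism

Tests run the full pipeline at the default study scale (140 trusts, ≈ 430
organisations, ~150k feedback items, ~1 year) in roughly ten seconds, and the
parameter-recovery study at 200 replicates of n = 5,000 in roughly twelve;
scaled-down configurations (12 trusts, 6 months) cover orchestration
mechanics. Every stochastic test fixes its seed; hypothesis profiles are
derandomised.

## Known limitations

- The ordinal model is fixed-effects; repeated inspections of one
  organisation would be treated as independent rows.
- The sentiment model predicts stars from synthetic tone tokens; its
  near-perfect accuracy on separable corpora is a ceiling property of the
  construction, not a claim about real microblog text.
- The dedup key (org, source, date, text, stars) treats sources as distinct,
  so the same review syndicated across two sources counts twice.
- Calibration constants (per-source means, class imbalance, rating
  marginals) are point estimates wired into defaults; all are overridable
  per `GeneratorConfig`.
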