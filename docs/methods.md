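# Methods

## The statistical setting

A fixed panel of *n* raters independently classifies each of *N* items
into one of *k* categories.  No ground truth is available — the items are
photographs of animals whose species could not be independently verified —
so every quantity here is a statement about *agreement*, not accuracy.
The package treats the item as the sampling unit and the rater panel as
fixed: confidence intervals quantify how the statistics would vary across
a different draw of items, not a different draw of experts.

## Chance-corrected agreement

Fleiss' kappa is computed from the count table *n<sub>ij</sub>*:

    p_j  = (Σ_i n_ij) / (N n)
    P_i  = (Σ_j n_ij² − n) / (n (n − 1))
    P̄   = mean_i P_i
    P̄_e = Σ_j p_j²
    K    = (P̄ − P̄_e) / (1 − P̄_e)

Two conventions matter and are fixed deliberately:

- **The option set defines chance.**  *k* is the panel's declared category
  set even when a sub-panel never uses a category (an unused category
  contributes p_j = 0 to P̄_e).  Agreement is easier when raters choose
  among fewer options, and that property should not silently change when a
  filter happens to drop all "unknown" votes.
- **Degenerate panels are flagged, never silently numeric.**  When every
  classification falls in one category, P̄_e = 1 and K is undefined; the
  result carries `degenerate=True` and `kappa=NaN` rather than a
  0/0-derived value, and the bootstrap refuses such panels.

The per-image proportion of agreement is the P_i statistic by itself: the
fraction of rater pairs agreeing on that image.  Its mean across images is
exactly the P̄ inside kappa (asserted to 1e-12 in the tests), which is why
both are computed from one code path.

### Bootstrap confidence intervals

Percentile intervals from 1,000 resamples by default.  Images are
resampled with replacement and the rater set held fixed — images are the
replicated units of the design; the experts are a panel, not a sample one
could meaningfully resample eight of.  Replicates whose resample is
degenerate are dropped and counted; if more than half are degenerate the
panel is too uniform to bootstrap and an error says so.  The replicate
computation is vectorized over the whole (n_boot × N × k) count stack, so
1,000 replicates on a 259-image panel cost milliseconds.  A 200-replicate
simulation in the test suite checks that the interval covers the
generator's long-run kappa at close to its nominal 95% rate (observed 96%).

## Majority classification and ties

The majority is the unique argmax of the vote counts.  When the maximum is
shared the image has *no* majority — represented as `None`, excluded (and
counted) by every downstream consumer, never resolved by coin flip or
alphabetical order.  This choice is load-bearing: the subset-majority
curve's characteristic sawtooth (lower at even subset sizes) exists only
because split votes are treated as non-matches.

## Subset-majority match probabilities

For an image with votes (n₁, …, n_k) and majority category m, a uniform
random subset of s raters drawn without replacement has category counts
distributed multivariate-hypergeometrically.  The exact match probability
sums Π_j C(n_j, c_j) / C(n, s) over all compositions (c₁, …, c_k) of s
whose unique argmax is m.  Implementation notes:

- Enumeration is recursive over categories with infeasible branches pruned;
  arithmetic is exact integer (`math.comb` + `Fraction`), so there is no
  overflow at C(27, 13) and no floating-point accumulation error.  Results
  are memoized on (votes, majority, size) — panels repeat vote splits
  heavily.
- The tie rule lives in a single predicate shared by the exact and
  Monte-Carlo paths, so the two can never drift apart.
- Monte-Carlo (numpy's multivariate hypergeometric sampler) is retained
  purely as an independent oracle; headline outputs are exact.
- The mean curve averages per-image probabilities over images with a
  defined full-panel majority; majority-less images are excluded and the
  exclusion count reported.  `experts_needed(curve, t)` returns the
  smallest s such that *every* size ≥ s meets t — the suffix condition
  matters because of the even/odd sawtooth.

## Intra-rater consistency

For a rater's two passes over the same images, the default `kappa_self` is
Cohen's kappa over the k × k confusion table (each pass keeps its own
marginals).  The pooled-marginal alternative — Fleiss' kappa of the
2-rater panel formed by stacking the two passes — is also reported as
`kappa_self_pooled`; the two differ when the passes have different
marginals, and the tests verify the pooled variant coincides with the
2-rater Fleiss computation.  A rater who used a single category
identically in both passes has undefined chance-corrected self-agreement
(P_e = 1) and is reported as NaN, excluded from aggregates.

## Misclassification bounds

With "unknown" responses excluded from numerator and denominator (an
abstention is not a misclassification):

- **Lower bound** — assume the reference (by default the majority)
  classification is correct everywhere; the rate is the fraction of
  species classifications that disagree with it.
- **Upper bound** — assume the majority is wrong everywhere.  What counts
  as an error then is a modeling choice, not an observable; the default
  rule (`majority_incorrect_complement`) counts species classifications
  *agreeing* with the majority as errors, and the rule name is always
  carried in the output.  Other rules could be defended; none is claimed
  to reproduce any externally printed figure.

Images whose majority is undefined are excluded and counted.  The exact
partition `disagree + agree = all species classifications` is asserted in
the tests.  `constrained_subset_rate` applies the same counting against an
externally supplied truth mapping (e.g. images from locations where only
one species occurs).

## The synthetic generator

`generate_panel` emulates the study design the analysis assumes: 27 raters
in a 9:8:10 regional split, 15 image categories across five trials (299
images; one category has 19 images because a mistakenly repeated stimulus
was discarded, and the 40 location-provided images are excluded from
headline analyses, leaving the canonical 259), and an optional retest pass
of the first trial's 40 images.

Each image has a true species (bobcat with probability 92/259 by default;
northern-region images are always lynx, where bobcats are absent) and a
difficulty d_i = category penalty + N(0, σ_img).  Each rater has a skill
offset s_r ~ N(0, σ_rater).  Responses are a three-outcome draw:

    p_unknown = expit(logit(u₀) + 0.5 · d_i)
    p_correct = (1 − p_unknown) · expit(logit(a₀) + s_r − d_i)
    p_wrong   = the remainder

Defaults: a₀ = 0.998, u₀ = 0.055, σ_img = 0.8, σ_rater = 0.4, and
covariate penalties ordered as the study found them (summer +1.15 hardest,
forest +0.4, face-only and legs-and-tail views +0.9, daytime +0.15,
knowing the location −0.5).  These were calibrated once, by simulation, so
the default panel reproduces the study's headline regime on the 259-image
subset — kappa ≈ 0.64, ~10% "unknown" responses, mean proportion of
agreement ≈ 0.8 — and then frozen.

What the generator does *not* emulate: correlated errors between raters
(e.g. shared visual heuristics), per-image species-specific bias,
sequence effects within a trial, or learning between trials.  Passing
tests therefore demonstrate that the pipeline recovers the structure this
model generates — orderings, limits, coverage — not that it would
reproduce any particular real panel's values.

The retest pass (`generate_repeat_pass`) repeats each response with
probability `consistency` and otherwise redraws from the same response
distribution, so a redraw can coincide with the original answer and the
realized self-agreement exceeds the nominal consistency parameter.  The
retest is emitted as a separate panel (trial 6, same image ids): counts
are keyed by image id, so pooling both passes in one table would
double-count votes.

## Numerical and interface choices

- Long format (one row per classification) is the canonical on-disk form;
  count matrices are always derived.  Responses are trimmed and lowercased
  before validation; duplicate (image, rater, trial) keys, undeclared
  responses, and images without metadata are hard errors naming the
  offenders.
- Incomplete panels (an image not seen by every rater) are representable
  but rejected by the statistics, which assume a complete design.
- All randomness in the pipeline flows from one seed via
  `numpy.random.SeedSequence.spawn`; a rerun with the same seed reproduces
  the JSON manifest byte-for-byte.
- Rounding for presentation is half-up at 2 decimals, applied only at the
  reporting layer; internal values keep full precision.
- Problem sizes in the test suite are the package's own defaults (259–299
  image panels, 1,000 bootstrap replicates, 200-replicate coverage runs,
  exhaustive subset enumeration up to 12 raters); the full suite runs in
  well under a minute.

## Known limitations

- The bootstrap treats images as exchangeable; images of the same animal
  in different trials are resampled independently.
- `experts_needed` reads a point estimate off the mean curve; it does not
  propagate the curve's CI into the returned panel size.
- The upper misclassification bound is rule-dependent by construction and
  should be read as a labeled scenario, not an estimate.
- Cohen's-kappa consistency treats the two passes as exchangeable in time;
  no drift or learning model is fitted.
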