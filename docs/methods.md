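# Methods

## Problem and pipeline

`infoveil` implements a dictionary-driven surveillance analysis for short
social-media text about cannabis. The question it operationalizes: how much
of the platform conversation that mentions cannabis is *health-related* —
either a health motivation for use or a perceived adverse health effect —
and can a fixed medical vocabulary find it? The pipeline is:

1. **Seed filter.** Keep posts containing at least one of 16 cannabis
   keywords (*blunt, bong, budder, cannabis, cbd, ganja, hash, hemp, indica,
   kush, marijuana, marihuana, reefer, sativa, thc, weed*) as a whole token.
2. **Retweet removal.** Drop records flagged as retweets so each retained
   post is an independent authored observation. Detection uses the record's
   platform metadata flag, never text heuristics ("RT @..." prefixes are
   dialect-dependent and unreliable).
3. **Account hygiene.** Drop posts from deleted accounts first (no bot score
   can exist for them), then posts from accounts whose precomputed
   bot-likelihood score, on a 1–5 scale, is **≥ 4.0** (inclusive). The
   package consumes scores; it never models account features itself.
4. **Rule-based classification.** Assign each post the union of categories
   of every lexicon term occurring in it (17 fixed categories; a post may
   carry several or none). Posts with ≥1 category form the *health subset*
   over which per-category frequencies are tabulated.
5. **Validation.** Draw a stratified random sample of classified posts, have
   two coders label each as `motivation` / `consequence` / `neither`,
   measure agreement with Cohen's kappa, adjudicate disagreements, and
   tabulate labels per stratum. The headline statistic is the health-related
   share, (motivation + consequence) / n sampled.

## Text normalization and matching

One convention is shared by the seed filter and the classifier: Unicode
NFKC, lowercase, split into maximal runs of ASCII alphanumerics. Hashtag
prefixes disappear as a side effect of the boundary split (`#cannabis` →
`cannabis`), and matching is strictly whole-token, so `weed` never fires
inside `seaweed`. Lexicon surface forms are stored tokenized; a multi-word
term matches only as a contiguous token sub-sequence.

Deliberate semantics, each chosen because it is the simplest rule a
brute-force oracle can also implement:

- overlapping matches all count (`heart attack` and `attack` both fire);
  no longest-match suppression;
- a term matching twice in one post contributes its categories once
  (tables count posts, not mentions);
- colloquial entries (informal synonyms carrying a pointer to their
  canonical medical term, e.g. *drunk* → *inebriation*) match with exactly
  the same weight as medical entries.

No stemming, spelling correction, negation handling or proximity
constraint: the matcher is exact by design, and misspelled mentions are
missed. That is a property of the method being studied, not an oversight.

## Lexicon format

UTF-8 TSV with header `surface_form  categories  source  canonical`;
categories pipe-separated; `source` ∈ {medical, colloquial}; `canonical`
required exactly for colloquial rows and must resolve to a medical entry in
the same file. Duplicate surface forms merge by category-set union, so row
order never matters. Category names are compared case-insensitively and
stored in registry casing for stable report headers. The packaged
demonstration lexicon holds the example keywords of the 17 categories
(54 entries, including the colloquial pair *drunk*/*inebriation*); a
production lexicon — e.g. a licensed consumer-health vocabulary mapped to
the same categories — is supplied by the user in the same format. Whether
colloquial terms inherit their canonical term's categories or carry their
own is left to the lexicon author; the format stores explicit per-row
categories either way.

## Agreement and table arithmetic

Cohen's kappa is computed from the 3×3 contingency table:
`κ = (p_o − p_e)/(1 − p_e)` with `p_e` the inner product of the two coders'
marginal label proportions, and `κ = 1` when both agreements are exactly 1.
Because a published agreement *range* implies repeated kappas, the package
computes one kappa per sampling stratum and reports min/max; that is a
documented convention (a per-category double-coding workflow), not an
inference about how any particular study batched its coding.

Percentages round half-up — validation tables to 1 decimal, frequency
tables to 2 — with the division done in exact decimal arithmetic so ties
are genuine. Published tables of this kind occasionally contain cells
inconsistent with any single rounding rule; the implementation follows
round-half-up uniformly and does not chase per-cell discrepancies.

For stratified sampling, a multi-label post must occupy exactly one stratum
(published row totals sum exactly to the sample size). Its stratum is drawn
uniformly at random among its assigned categories, from the same seeded
generator that performs the within-stratum draws, and recorded in the
sample output. Any deterministic priority rule would bias strata toward
whichever categories it favors; the uniform draw is unbiased and logged.

## Synthetic data generator

The generator produces corpora with the statistical structure the analysis
assumes, so every stage is testable offline:

- **Accounts:** posts-per-account is shifted geometric with mean
  `posts_per_account_mean`; bot and deleted status are per-account. Bots
  get scores uniform in [4, 5], non-bots uniform in [1, 4), deleted
  accounts no score.
- **Text:** every post carries one seed keyword (30% of the time as a
  hashtag) plus nonsense filler words generated disjoint from the lexicon
  and seed vocabulary, so no category can match by accident. A post is a
  health candidate with probability `1 − no_health_fraction`; candidates
  carry each category independently with probability
  `category_prevalence[c]`, realized by planting a uniformly chosen lexicon
  term of that category. The marginal rate of category *c* is therefore
  `(1 − no_health_fraction) · category_prevalence[c]`, and tests compare
  against that quantity. An optional ambiguity-injection mode fuses lexicon
  tokens into longer words to exercise boundary handling.
- **Coders:** each coder reproduces the post's true label with probability
  `coder_accuracy`, else errs uniformly over the other two labels,
  independently.

Defaults encode the study conditions the pipeline is meant to emulate:
per-category prevalences are the published corpus shares (Cancer 0.0392 …
Mental health 0.2834 … Weight 0.0167); `no_health_fraction` = 1 −
609,227/16,703,751 ≈ 0.9635 (the share of seed-keyword posts matching no
term); `bot_fraction` = 15,245/261,134 ≈ 0.058 of available accounts;
`deleted_fraction` = 127,140/388,274 ≈ 0.327 of accounts;
`posts_per_account_mean` = 353,353/245,889 ≈ 1.44; true label distribution
(0.204, 0.108, 0.688). Two knobs have no published value and were fixed
once at field-realistic levels: `retweet_fraction` = 0.4 (retweets are
roughly that share of public cannabis-keyword streams) and
`coder_accuracy` = 0.93, whose implied expected kappa under uniform truth,
`κ ≈ (a² + (1−a)²/2 − 1/3)/(2/3) ≈ 0.80`, sits inside the 0.79–0.86 band
reported for trained dual coders on this task.

What the generator does **not** emulate: real language (filler is nonsense
by construction, so classifier precision/recall of 1.0 on synthetic corpora
demonstrates mechanical correctness of the matcher, not performance on real
tweets), topical correlation between categories (co-occurrence is
independent Bernoulli), misspellings, sarcasm/negation, and any temporal or
network structure. Passing synthetic tests therefore validates the
pipeline's bookkeeping and algorithms, never the lexicon's real-world
coverage — which is exactly the question the manual validation stage
exists to answer.

## Reproducibility and numerical choices

All randomness flows from one root seed. The pipeline derives per-stage
generators via `numpy.random.SeedSequence(seed, spawn_key=(stage,))`;
identical config + seed gives byte-identical artifacts. Stratum-membership
derivation for proportional allocation reuses the sampler's own seed so
allocation can never exceed a realized stratum population. Degenerate
inputs are defined, not special-cased: empty token sequences match nothing,
a zero-health corpus produces an empty sample and a clean manifest,
percentages over an empty denominator render 0.0, and kappa is 1 when both
observed and expected agreement are exactly 1.

Test and acceptance problem sizes — synthetic corpora of 5,000 posts,
random-corpus oracle sweeps of 200 corpora up to 500 posts × 100 lexicon
entries, 200 Monte-Carlo kappa replicates of 300 items — were chosen as the
smallest sizes at which binomial 3-standard-error bands and Monte-Carlo
means are informative; the statistical assertions state their tolerance in
standard errors (plus the O(1/n) finite-sample bias of the kappa ratio
estimator where relevant), so they scale with the sizes rather than being
tuned to them.

## Known limitations

- The demonstration lexicon is illustrative (54 entries); substantive
  surveillance needs a full consumer-health vocabulary mapped to the 17
  categories, supplied as input.
- Exact matching misses misspellings, inflections and figurative use; no
  negation or sarcasm handling.
- The seed-keyword filter fixes the substance domain; other substances
  require a different seed list and category prevalences.
- Bot detection quality is inherited entirely from the upstream scorer; the
  threshold semantics here are just "remove at or above 4.0 on 1–5".
- The per-stratum kappa convention yields a range comparable to published
  values but is one of several defensible units of repetition.
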