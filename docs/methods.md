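# Methods

## The detection rule

A token is any maximal non-whitespace run with enclosing punctuation
(quotes, brackets, commas, periods, semicolons, colons, dashes used as
punctuation) stripped from its edges and a trailing possessive `'s`
removed. Internal hyphens and slashes stay: `YST-adjusted` is one
12-character token, `B-AE-D` one 6-character token. Tokens that are pure
punctuation vanish and do not count as words.

A token is an **acronym** when it has at least two characters and its
upper-case letters make up at least half of its characters. Every
character of the stripped token counts in the denominator — letters,
digits, internal hyphens — while only upper-case letters count in the
numerator. This reproduces the canonical boundary cases: `mRNA` (3/4) in,
`N95` (1/3) out, `BRCA1` (4/5) in, `laser` (0/5) out. Unicode letters are
judged by their case property, so upper-case Greek counts as upper case.

Two knobs exist because the rule has genuinely open edges:

- `min_length` (default 2). Single capitals are initials or variable
  names, not acronyms; the analysis universe is length 2+ and the length
  strata reported are 2, 3, 4 and 5+.
- `alnum_denominator` (default off). With it on, only letters and digits
  count toward the denominator, so symbol-heavy tokens like `HC-MVECs`
  are judged on 7 characters rather than 8. The default counts all
  characters; the switch exists because the choice is consequential for
  mixed-symbol tokens and defensible either way.

Acronym *kind* is `letters_only` when every character is alphabetic,
otherwise `letters_and_numbers` (hyphenated forms land in the second
bucket by this definition).

A known limitation, which the audit machinery exists to quantify: forms
with many lower-case letters (`circRNA`) are missed, and words capitalised
for emphasis or personal initials are wrongly included.

## Exclusion filtering

Per (record, field) pair, rules fire in a fixed precedence order —
metadata before content — and the first hit is the recorded reason:
missing date → non-English → before the start year (default 1950) → no
article type (titles only) → no abstract (abstracts only) → empty → one
word → mostly capitals. Precedence makes tallies reproducible and
conserves the record count exactly: per field, included + excluded =
total. Language is trusted from metadata; no text-based detection.

The "mostly capitals" screen excludes a text whose fraction of
all-capital words (words whose alphabetic characters are all upper case)
reaches the threshold, default 0.60 — an all-caps title cannot be
screened for acronyms at all. Both the start year and the threshold are
config values. Duplicated identifiers are removed before filtering,
keeping the first occurrence in input order.

## Trend statistics

Annual density is the **mean of per-paper ratios** (×100), not the pooled
token ratio; the pooled variant is available behind a flag as a
sensitivity check. The CI is the normal approximation
mean ± 1.96·s/√n for the annual mean; a single-paper year reports a
degenerate interval and is flagged. Years with no eligible papers are
omitted, never zero-filled. Stratified series (length 2/3/4/5+, kind)
use the same all-words denominator, so strata sum to the total density.

Rankings count token occurrences, not per-paper presence, pool titles
and abstracts by default, and break ties by descending count then
lexicographic order so output is deterministic. The top-k masking
variant removes the k globally most frequent surfaces from the acronym
counts while leaving them in the word denominator. The frequency
spectrum reports fractions of unique surfaces occurring once, 2–10
times and >10,000 times, plus three-letter coverage out of 26³ = 17,576.

## Re-use survival

The unit is the (surface, journal) pair: first use is the earliest paper
in that journal containing the surface in title or abstract, re-use is
the next distinct paper there containing it, and records without re-use
are censored at the journal's last observed date. Defining first use
per journal (rather than globally) keeps coinages countable in every
journal and standardises by field, reducing collisions between unrelated
meanings of the same letters; a global-first-use variant is exposed
behind a flag. Days convert to years by /365.25; same-day ties break by
paper id. The one-year re-use fraction uses an observable denominator:
records censored before the window are dropped, events after the window
count in the denominator only.

Survival curves come from lifelines' Kaplan–Meier fitter; the confidence
band is Greenwood variance on the complementary log-log scale (stable
near the tails, stays in [0, 1]). t10 is the first time the curve
reaches 0.90, its bounds the first crossings of the band's two limits;
when a cohort's curve never reaches 0.90, t10 is reported missing rather
than extrapolated. The test suite checks the estimator against an
independent brute-force product-limit computation.

## Audit bounds

With x errors in n hand-checked items and a uniform Beta(1, 1) prior,
the posterior on the error rate is Beta(x+1, n−x+1) and the reported
bound is 100 × its 0.95 quantile (closed form 100·(1−0.05^(1/(n+1)))
when x = 0). Averages and bounds are rounded half-up to one decimal for
tables; full precision is kept internally. Title audit rows may pool the
two 300-item title samples into n = 600 while abstract rows use n = 300;
both conventions are supported, and the caller chooses the denominators.
Sampling for hand checks is simple random sampling without replacement,
reproducible under a fixed seed, from the five outcome categories
(excluded titles; titles/abstracts with and without detected acronyms).

## The synthetic corpus

The generator emulates exactly the structure the statistics consume, and
nothing else:

- **Density ramps.** Per-paper acronym counts are binomial over the
  paper's words with the year's ramp value (per 100 words) as per-word
  probability, so the mean-of-ratios estimator is exactly unbiased for
  the ramp. Defaults: titles 0.7 → 2.4, abstracts 0.4 → 4.1 per 100
  words across 1950–2019.
- **Word counts.** 2 + Poisson(mean − 2), keeping the mean on the ramp
  and every text above the one-word filter. Defaults: titles 9.0 → 14.6,
  abstracts 128 → 220 words.
- **Vocabulary.** 2,000 unique upper-case surfaces (15% with a trailing
  digit), lengths mixed 2:25% / 3:40% / 4:20% / 5+:15% so three-letter
  forms are modal, sampled by Zipf rank with exponent 1.5 — heavy-tailed
  enough that a realistic share of surfaces occurs exactly once.
- **Contamination.** Non-English records (16%), all-caps titles (1%) and
  missing abstracts (24%) injected at rates matching the magnitudes seen
  in real bibliographic baselines, each constructed to trip exactly one
  exclusion rule, with injected counts recorded in the ground truth so
  the exclusion tally can be checked exactly. Clean text is kept
  strictly below the 60% capitals screen (a ~10⁻⁵ truncation of the
  binomial, far below any recovered mean's sampling error).
- **Re-use cohorts.** Each cohort year coins fresh surfaces (unique,
  disjoint from the trend vocabulary), one coining paper each, and an
  exponential waiting time at the cohort's hazard decides whether a
  re-use paper lands before the journal-end censoring horizon; a
  surface-free sentinel paper pins every journal's last issue.
- Dates are uniform within the year and journals uniform over 20 —
  no analysis uses within-year or between-journal structure.

Identical config (including seed) yields a byte-identical corpus.

What the generator does *not* model: real language (fillers come from a
~50-word lowercase lexicon), parenthesised definitions, acronym sense
ambiguity, correlated journal styles, and secular changes in metadata
quality. Passing recovery tests therefore demonstrate that the pipeline
measures what it claims on data with the assumed structure — not that
the detection rule is error-free on real prose; that question is what
the audit-sampling machinery addresses.

## Problem sizes and numerical choices

Recovery tests run at 5,000 papers/year over 1950–2019 (350,000 records,
~66M tokens, a few minutes end-to-end) and assert agreement within 3
standard errors of the generator truth; t10 recovery uses 500 coinings
per cohort against the closed-form exponential quantile −ln(0.9)/λ. The
detector is verified exhaustively against a brute-force oracle on all
tokens of length ≤ 4 over a 4-symbol alphabet, and the survival
estimator against a brute-force product-limit computation on randomised
fixtures of ≤ 20 records with ties and censoring. Beta quantiles come
from scipy; a 10⁶-draw Monte-Carlo check keeps them honest to 0.05
percentage points.

Degenerate inputs are values, not errors: empty text has zero words and
density 0, a missing date is a sentinel handled by filtering, a cohort
that never reaches 10% re-use has missing t10, and an empty re-use
denominator reports a missing fraction.
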