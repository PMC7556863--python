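# acrotrend

Acronym detection and trend analysis for bibliographic corpora.

Scientific titles and abstracts have accumulated acronyms for decades, and
most of the acronyms ever coined are used a handful of times and then
abandoned. `acrotrend` is a toolkit for quantifying that process in
MEDLINE/PubMed-scale corpora. It is aimed at meta-researchers and
scientometricians who want to measure acronym density, how it changes over
time, and how often newly coined acronyms are ever picked up again.

## What it computes

**Detection rule.** A token *w* (whitespace-delimited, enclosing punctuation
stripped) is an acronym iff

&nbsp;&nbsp;&nbsp;&nbsp;|w| ≥ 2 and n_upper(w) / |w| ≥ ½,

where |w| counts every character (letters, digits, internal hyphens) and
n_upper counts upper-case letters. So mRNA (3/4) and BRCA1 (4/5) are
acronyms; N95 (1/3) and laser (0/5) are not. The rule covers acronyms
proper, initialisms and capitalised abbreviations without requiring a
parenthesised definition.

**Corpus statistics.** For a field *f* ∈ {title, abstract} and year *t*, the
annual acronym density is the mean over papers of each paper's
per-100-words ratio,
d̄(t) = (100/n_t) Σ_i a_i / w_i, with a normal-approximation 95% CI
d̄ ± 1.96·s/√n. Also: top-N rankings by token count, densities with the
top-k surfaces masked, per-article-type series, the frequency spectrum of
unique surfaces, coverage of the 26³ = 17,576 possible three-letter forms,
and annual mean word counts.

**Re-use survival.** Each (acronym, journal) first use becomes a
time-to-event record: the event is re-use in a *different* paper in the
same journal; never-re-used coinings are right-censored at the journal's
last observed issue. Per coining cohort, the Kaplan–Meier product-limit
estimator Ŝ(t) = Π_{t_j ≤ t} (1 − d_j/n_j) yields t10, the time at which
10% of the cohort's acronyms have been re-used, with a Greenwood /
complementary-log-log confidence band.

**Error audits.** Hand-check summaries (x errors in n sampled items) get a
Bayesian upper bound: 100 × the 0.95 quantile of the Beta(x+1, n−x+1)
posterior under a uniform prior.

**Synthetic corpora.** A generator produces corpora with known ground truth
— linear density and word-count ramps, a Zipf acronym vocabulary, journal
structure, exponential re-use hazards, and contamination (non-English
records, all-caps titles, missing abstracts) — so every pipeline stage is
testable without multi-GB downloads.

## Worked example

`examples/02_trends_synthetic.py` generates a 28,000-record synthetic
corpus (400 papers/year, 1950–2019), filters it, and recovers the
generator's density ramps:

```
title: 23260 records kept
  1950: 0.64 per 100 words (95% CI 0.33-0.94, n=329; generator truth 0.70)
  2019: 2.35 per 100 words (95% CI 1.89-2.81, n=335; generator truth 2.40)

abstract: 16819 records kept
  1950: 0.42 per 100 words (95% CI 0.34-0.49, n=238; generator truth 0.40)
  2019: 3.96 per 100 words (95% CI 3.79-4.13, n=246; generator truth 4.10)
```

Each line is the recovered annual mean density with its 95% CI and the
value the corpus was actually generated with — the truth sits inside the
interval, which is the whole point of the generator. The other examples
cover token classification (`01`), re-use survival and t10 recovery
(`03`), and audit bounds (`04`).

The same machinery is scriptable from the shell:

```bash
acrotrend simulate --seed 3 --papers-per-year 200 --out synth.jsonl
acrotrend filter --in synth.jsonl --out kept.jsonl --report exclusions.tsv
acrotrend trends --in kept.jsonl --field abstract --out trends.tsv
acrotrend run --in synth.jsonl --out report/      # full bundle + manifest
```

`acrotrend parse` converts MEDLINE baseline XML (optionally gzipped) into
the JSON-lines record format the other commands consume.

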