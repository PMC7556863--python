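"""Synthetic corpora with known ground truth.

The generator emulates the statistical structure the analysis relies on,
nothing more: per-year acronym densities that ramp linearly across the
study window, title/abstract lengths that ramp likewise, a Zipf-
distributed acronym vocabulary shared across journals, uniformly
assigned journals and within-year dates, plus contamination (non-English
records, all-capitals titles, missing abstracts) injected at known rates
with its true exclusion reason recorded.  Filler text is drawn from a
small fixed lowercase lexicon — linguistic content is irrelevant to
every statistic computed downstream.

Per-paper acronym counts are binomial over the paper's words with the
year's density (per 100 words) as the per-word probability, so the
expected per-paper density equals the ramp value exactly under the
mean-of-ratios estimator.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
import string
from collections import Counter
from typing import Sequence

import numpy as np

from .records import PaperRecord

_FILLERS = (
    "the of and in to for with on by from study effect analysis results "
    "patients cells treatment clinical model between during after using "
    "increased response growth expression levels role function changes "
    "associated comparison evaluation outcomes human protein gene factors "
    "methods data evidence review case report trial randomised measures "
    "activity system development tissue blood disease risk health primary"
).split()


def _linear_ramp(start: float, end: float, years: np.ndarray,
                 y0: int, y1: int) -> np.ndarray:
    if y1 == y0:
        return np.full(years.shape, float(end))
    return start + (end - start) * (years - y0) / (y1 - y0)


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs of the generated corpus; defaults mirror the observed study
    window: title density 0.7→2.4 and abstract density 0.4→4.1 per 100
    words, title length 9.0→14.6 and abstract length 128→220 words, over
    1950–2019."""

    seed: int = 0
    year_start: int = 1950
    year_end: int = 2019
    n_journals: int = 20
    papers_per_year: int = 200
    title_density_ramp: tuple[float, float] = (0.7, 2.4)
    abstract_density_ramp: tuple[float, float] = (0.4, 4.1)
    title_words_ramp: tuple[float, float] = (9.0, 14.6)
    abstract_words_ramp: tuple[float, float] = (128.0, 220.0)
    vocab_size: int = 2000
    zipf_exponent: float = 1.5
    length_mix: dict = dataclasses.field(
        default_factory=lambda: {2: 0.25, 3: 0.40, 4: 0.20, 5: 0.15})
    frac_letters_and_numbers: float = 0.15
    frac_nonenglish: float = 0.16
    frac_allcaps_titles: float = 0.01
    frac_no_abstract: float = 0.24

    def validate(self) -> None:
        for name in ("frac_nonenglish", "frac_allcaps_titles",
                     "frac_no_abstract", "frac_letters_and_numbers"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("title_density_ramp", "abstract_density_ramp"):
            lo, hi = getattr(self, name)
            if min(lo, hi) < 0 or max(lo, hi) > 100:
                raise ValueError(
                    f"{name} must stay within [0, 100] per 100 words")
        if self.papers_per_year < 0 or self.n_journals < 1:
            raise ValueError("papers_per_year must be >= 0, n_journals >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    years: list
    title_density: dict  # year -> per-100-words density parameter
    abstract_density: dict
    title_words: dict  # year -> mean words parameter
    abstract_words: dict
    vocab_probs: dict  # surface -> sampling probability
    contamination: Counter  # reason label -> count injected
    reuse_hazards: dict = dataclasses.field(default_factory=dict)


def _make_vocabulary(config: SyntheticConfig,
                     rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Zipf-ranked acronym surfaces: unique uppercase forms, heavy tail."""
    lengths = sorted(config.length_mix)
    probs = np.array([config.length_mix[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    letters = np.array(list(string.ascii_uppercase))
    surfaces: list[str] = []
    seen: set[str] = set()
    while len(surfaces) < config.vocab_size:
        length = int(rng.choice(lengths, p=probs))
        chars = rng.choice(letters, size=length)
        surface = "".join(chars)
        if rng.random() < config.frac_letters_and_numbers:
            surface = surface[:-1] + str(rng.integers(0, 10))
        if surface not in seen:
            seen.add(surface)
            surfaces.append(surface)
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    weights = ranks ** (-config.zipf_exponent)
    return surfaces, weights / weights.sum()


def _sample_text(rng: np.random.Generator, n_words: int, p_acr: float,
                 vocab: np.ndarray, vocab_p: np.ndarray) -> str:
    n_acr = rng.binomial(n_words, p_acr)
    # Keep clean text strictly below the 60% all-capitals screen so the
    # only records tripping that rule are the deliberately injected ones.
    # The truncation is ~1e-5 of draws at realistic densities, far below
    # the sampling error of any recovered mean.
    n_acr = min(n_acr, math.ceil(0.6 * n_words) - 1)
    words = list(rng.choice(len(_FILLERS), size=n_words - n_acr))
    tokens = [_FILLERS[i] for i in words]
    if n_acr:
        tokens.extend(vocab[rng.choice(len(vocab), size=n_acr, p=vocab_p)])
        order = rng.permutation(n_words)
        tokens = [tokens[i] for i in order]
    return " ".join(tokens)


def _word_count(rng: np.random.Generator, mean: float) -> int:
    # Poisson shifted to >= 2 words so nothing trips the one-word filter;
    # the mean stays exactly at the ramp value.
    return 2 + int(rng.poisson(max(mean - 2.0, 0.0)))


def generate_corpus(config: SyntheticConfig) -> tuple[list[PaperRecord], GroundTruth]:
    """Generate a corpus plus the ground truth it was drawn from.

    Identical config (including seed) gives a byte-identical corpus.
    Contaminated records are constructed to trip exactly one exclusion
    rule each, so the exclusion tally can be checked against the injected
    counts exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.year_start, config.year_end + 1)
    td = _linear_ramp(*config.title_density_ramp, years,
                      config.year_start, config.year_end)
    ad = _linear_ramp(*config.abstract_density_ramp, years,
                      config.year_start, config.year_end)
    tw = _linear_ramp(*config.title_words_ramp, years,
                      config.year_start, config.year_end)
    aw = _linear_ramp(*config.abstract_words_ramp, years,
                      config.year_start, config.year_end)
    vocab_list, vocab_p = _make_vocabulary(config, rng)
    vocab = np.array(vocab_list, dtype=object)

    truth = GroundTruth(
        years=list(map(int, years)),
        title_density={int(y): float(d) for y, d in zip(years, td)},
        abstract_density={int(y): float(d) for y, d in zip(years, ad)},
        title_words={int(y): float(w) for y, w in zip(years, tw)},
        abstract_words={int(y): float(w) for y, w in zip(years, aw)},
        vocab_probs=dict(zip(vocab_list, map(float, vocab_p))),
        contamination=Counter(),
    )

    records: list[PaperRecord] = []
    pid = 0
    for yi, year in enumerate(years):
        n = config.papers_per_year
        if n == 0:
            continue
        days = rng.integers(0, 365, size=n)
        journals = rng.integers(0, config.n_journals, size=n)
        u = rng.random(size=n)
        for j in range(n):
            pid += 1
            date = _dt.date(int(year), 1, 1) + _dt.timedelta(days=int(days[j]))
            journal = f"J{journals[j]:03d}"
            kind = "clean"
            if u[j] < config.frac_nonenglish:
                kind = "non_english"
            elif u[j] < config.frac_nonenglish + config.frac_allcaps_titles:
                kind = "allcaps_title"
            elif u[j] < (config.frac_nonenglish + config.frac_allcaps_titles
                         + config.frac_no_abstract):
                kind = "no_abstract"
            title = _sample_text(rng, _word_count(rng, tw[yi]),
                                 td[yi] / 100.0, vocab, vocab_p)
            abstract = _sample_text(rng, _word_count(rng, aw[yi]),
                                    ad[yi] / 100.0, vocab, vocab_p)
            language = "eng"
            if kind == "non_english":
                language = "fre"
                truth.contamination["non_english"] += 1
            elif kind == "allcaps_title":
                title = title.upper()
                truth.contamination["mostly_capitals_title"] += 1
            elif kind == "no_abstract":
                abstract = None
                truth.contamination["no_abstract"] += 1
            records.append(PaperRecord(
                paper_id=f"S{pid:08d}",
                year=int(year),
                pub_date=date,
                journal_id=journal,
                title=title,
                abstract=abstract,
                language=language,
                article_types=("Journal Article",),
            ))
    return records, truth


# ---------------------------------------------------------------------------
# Re-use cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReuseCohortConfig:
    """Cohorts of newly coined surfaces with exponential re-use times.

    ``hazard_by_cohort`` maps cohort year to the exponential re-use rate
    (events per acronym-year); each cohort coins ``n_per_cohort`` fresh
    surfaces, spread uniformly over journals, and every journal's record
    ends at ``journal_end`` (the censoring horizon).
    """

    seed: int = 0
    hazard_by_cohort: dict = dataclasses.field(
        default_factory=lambda: {2000: 0.105})
    n_per_cohort: int = 500
    n_journals: int = 10
    journal_end: _dt.date = _dt.date(2030, 12, 31)


def _cohort_surface(cohort: int, i: int) -> str:
    """Unique all-caps surface, disjoint from the Zipf vocabulary space
    by construction (always begins with 'Q' + base-26 payload of >= 5)."""
    payload = []
    x = cohort * 100000 + i
    while x:
        payload.append(string.ascii_uppercase[x % 26])
        x //= 26
    return "Q" + "".join(reversed(payload)).rjust(5, "A")


def generate_reuse_cohorts(config: ReuseCohortConfig) -> tuple[list[PaperRecord], GroundTruth]:
    """Papers realising per-cohort exponential re-use processes.

    For each cohort year and each coined surface: one coining paper at a
    uniform date in that year, and — when the exponential waiting time
    lands before the journal end — one re-use paper in the same journal.
    A surface-free sentinel paper pins every journal's last issue at the
    censoring horizon so the downstream builder censors correctly.
    """
    for year, lam in config.hazard_by_cohort.items():
        if lam <= 0:
            raise ValueError(f"hazard for cohort {year} must be positive")
    rng = np.random.default_rng(config.seed)
    records: list[PaperRecord] = []
    truth = GroundTruth(years=sorted(config.hazard_by_cohort), title_density={},
                        abstract_density={}, title_words={}, abstract_words={},
                        vocab_probs={}, contamination=Counter(),
                        reuse_hazards=dict(config.hazard_by_cohort))
    pid = 0
    for cohort in sorted(config.hazard_by_cohort):
        lam = config.hazard_by_cohort[cohort]
        days = rng.integers(0, 365, size=config.n_per_cohort)
        journals = rng.integers(0, config.n_journals, size=config.n_per_cohort)
        waits = rng.exponential(1.0 / lam, size=config.n_per_cohort)
        for i in range(config.n_per_cohort):
            surface = _cohort_surface(cohort, i)
            coin_date = _dt.date(cohort, 1, 1) + _dt.timedelta(days=int(days[i]))
            journal = f"J{journals[i]:03d}"
            pid += 1
            records.append(PaperRecord(
                paper_id=f"R{pid:08d}", year=cohort, pub_date=coin_date,
                journal_id=journal,
                title=f"first appearance of {surface} in context",
                abstract=None, language="eng",
                article_types=("Journal Article",),
            ))
            reuse_date = coin_date + _dt.timedelta(
                days=int(round(waits[i] * 365.25)))
            if reuse_date <= config.journal_end:
                pid += 1
                records.append(PaperRecord(
                    paper_id=f"R{pid:08d}", year=reuse_date.year,
                    pub_date=reuse_date, journal_id=journal,
                    title=f"further work using {surface} again",
                    abstract=None, language="eng",
                    article_types=("Journal Article",),
                ))
    for j in range(config.n_journals):
        pid += 1
        records.append(PaperRecord(
            paper_id=f"R{pid:08d}", year=config.journal_end.year,
            pub_date=config.journal_end, journal_id=f"J{j:03d}",
            title="closing issue editorial note",
            abstract=None, language="eng",
            article_types=("Editorial",),
        ))
    records.sort(key=lambda r: (r.pub_date, r.paper_id))
    return records, truth
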