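"""Corpus-level acronym statistics: annual trends, rankings, spectra.

The central estimand is the acronym *density* of a field: acronym tokens
per 100 words.  Annual series are means over papers of the per-paper
ratio — not pooled token ratios — with a normal-approximation 95%
interval for the annual mean; at corpus scale the interval collapses
onto the mean, which is why it is reported but rarely plotted.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import (DEFAULT_CONFIG, AcronymKind, DetectorConfig,
                     count_acronyms, length_stratum)
from .records import PaperRecord

logger = logging.getLogger(__name__)

#: Number of distinct three-letter strings over the upper-case alphabet.
N_POSSIBLE_THREE_LETTER = 26 ** 3  # 17,576

LENGTH_STRATA = (2, 3, 4, "5+")


@dataclasses.dataclass
class AnnualTrend:
    """Mean acronym density (per 100 words) in one field for one year."""

    year: int
    field: str
    mean_density: float
    ci_low: float
    ci_high: float
    n_papers: int
    mean_words: float
    strata: dict = dataclasses.field(default_factory=dict)
    degenerate_ci: bool = False  # single-paper year: sd undefined


@dataclasses.dataclass
class FrequencySpectrum:
    """How often each unique acronym occurs, corpus-wide."""

    total_unique: int
    frac_once: float
    frac_2_to_10: float
    frac_gt_10000: float
    three_letter_coverage: float
    possible_three_letter: int = N_POSSIBLE_THREE_LETTER


def _mean_ci(values: np.ndarray) -> tuple[float, float, float, bool]:
    mean = float(values.mean())
    if values.size < 2:
        return mean, mean, mean, True
    sem = float(values.std(ddof=1)) / math.sqrt(values.size)
    return mean, mean - 1.96 * sem, mean + 1.96 * sem, False


def annual_trends(records: Iterable[PaperRecord], field: str,
                  stratify: bool = False,
                  config: DetectorConfig = DEFAULT_CONFIG,
                  exclude_surfaces: frozenset | set | None = None,
                  pooled: bool = False) -> list[AnnualTrend]:
    """One :class:`AnnualTrend` per calendar year with at least one record.

    ``exclude_surfaces`` masks a set of acronym surfaces: masked tokens
    stop counting as acronyms but still count as words (the sensitivity
    analysis behind "remove the top 100").  ``pooled=True`` switches to
    the pooled token ratio (total acronyms / total words per year) as a
    sensitivity variant; the default is the mean of per-paper ratios.
    Years with no eligible records are omitted, never zero-filled.
    """
    mask = exclude_surfaces or frozenset()
    per_year: dict[int, list] = defaultdict(list)
    for rec in records:
        text = rec.field_text(field)
        if text is None or rec.year is None:
            continue
        s = count_acronyms(text, config)
        if s.n_words == 0:
            continue
        if mask:
            n_masked = sum(1 for surf in s.surfaces if surf in mask)
        else:
            n_masked = 0
        n_acr = s.n_acronym_tokens - n_masked
        entry = [s.n_words, n_acr, None]
        if stratify:
            strata = Counter()
            for surf in s.surfaces:
                if surf in mask:
                    continue
                strata[("length", length_stratum(len(surf)))] += 1
                kind = (AcronymKind.LETTERS_ONLY if surf.isalpha()
                        else AcronymKind.LETTERS_AND_NUMBERS)
                strata[("kind", kind.value)] += 1
            entry[2] = strata
        per_year[rec.year].append(entry)

    out = []
    for year in sorted(per_year):
        entries = per_year[year]
        words = np.array([e[0] for e in entries], dtype=float)
        acrs = np.array([e[1] for e in entries], dtype=float)
        if pooled:
            mean = 100.0 * acrs.sum() / words.sum()
            lo = hi = mean
            degen = True
        else:
            mean, lo, hi, degen = _mean_ci(100.0 * acrs / words)
        trend = AnnualTrend(
            year=year, field=field, mean_density=mean,
            ci_low=lo, ci_high=hi, n_papers=len(entries),
            mean_words=float(words.mean()), degenerate_ci=degen,
        )
        if stratify:
            strata_means: dict = {}
            for key in set().union(*(e[2].keys() for e in entries)):
                dens = np.array([100.0 * e[2].get(key, 0) / e[0] for e in entries])
                strata_means[key] = float(dens.mean())
            trend.strata = strata_means
        out.append(trend)
    return out


def trends_to_frame(trends: Sequence[AnnualTrend]) -> pd.DataFrame:
    """Tidy DataFrame (year, field, stratum, mean, ci_low, ci_high, n)."""
    rows = []
    for t in trends:
        rows.append({"year": t.year, "field": t.field, "stratum": "all",
                     "mean_density": t.mean_density, "ci_low": t.ci_low,
                     "ci_high": t.ci_high, "n_papers": t.n_papers,
                     "mean_words": t.mean_words})
        for (dim, key), mean in sorted(t.strata.items(), key=str):
            rows.append({"year": t.year, "field": t.field,
                         "stratum": f"{dim}={key}", "mean_density": mean,
                         "ci_low": float("nan"), "ci_high": float("nan"),
                         "n_papers": t.n_papers, "mean_words": t.mean_words})
    return pd.DataFrame(rows)


def _count_tokens(records: Iterable[PaperRecord], field: str,
                  config: DetectorConfig, year: int | None = None) -> Counter:
    counts: Counter = Counter()
    fields = ("title", "abstract") if field == "both" else (field,)
    for rec in records:
        if year is not None and rec.year != year:
            continue
        for f in fields:
            text = rec.field_text(f)
            if text:
                counts.update(count_acronyms(text, config).surfaces)
    return counts


def top_acronyms(records: Sequence[PaperRecord], field: str = "both",
                 year: int | None = None, n: int = 20,
                 config: DetectorConfig = DEFAULT_CONFIG) -> list[tuple[str, int]]:
    """Top-``n`` acronym surfaces by token occurrence count.

    Counts are token occurrences (a surface appearing twice in one
    abstract counts twice); surfaces are case-sensitive exact strings, so
    "mRNA" and "MRNA" rank separately.  Ties break lexicographically for
    deterministic output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    counts = _count_tokens(records, field, config, year)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def top_acronyms_per_year(records: Sequence[PaperRecord], field: str = "title",
                          n: int = 10,
                          config: DetectorConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-year top-``n`` table (year, rank, surface, count)."""
    years = sorted({r.year for r in records if r.year is not None})
    rows = []
    for year in years:
        for rank, (surface, count) in enumerate(
                top_acronyms(records, field, year, n, config), start=1):
            rows.append({"year": year, "rank": rank,
                         "surface": surface, "count": count})
    return pd.DataFrame(rows, columns=["year", "rank", "surface", "count"])


def trends_excluding_top(records: Sequence[PaperRecord], field: str, k: int,
                         config: DetectorConfig = DEFAULT_CONFIG,
                         **kwargs) -> list[AnnualTrend]:
    """Annual trends with the ``k`` globally most frequent surfaces masked.

    Masked surfaces stop counting as acronyms but remain in the word
    denominator.  ``k=0`` reproduces :func:`annual_trends` exactly.  The
    global ranking pools titles and abstracts.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return annual_trends(records, field, config=config, **kwargs)
    top = top_acronyms(records, "both",
                       n=max(k, 1), config=config)[:k]
    mask = frozenset(surface for surface, _count in top)
    return annual_trends(records, field, config=config,
                         exclude_surfaces=mask, **kwargs)


def trends_by_article_type(records: Sequence[PaperRecord], field: str,
                           types: Sequence[str],
                           config: DetectorConfig = DEFAULT_CONFIG,
                           **kwargs) -> dict[str, list[AnnualTrend]]:
    """Annual trends restricted to each listed article type.

    A record carrying several of the listed types contributes to each of
    their series.  An unknown type yields an empty series with a logged
    warning rather than an error.
    """
    present = set()
    for rec in records:
        present.update(rec.article_types)
    out = {}
    for t in types:
        if t not in present:
            logger.warning("article type %r not present in corpus", t)
            out[t] = []
            continue
        subset = [r for r in records if t in r.article_types]
        out[t] = annual_trends(subset, field, config=config, **kwargs)
    return out


def frequency_spectrum(records: Sequence[PaperRecord],
                       config: DetectorConfig = DEFAULT_CONFIG) -> FrequencySpectrum:
    """Distribution of per-surface occurrence counts across titles+abstracts.

    Reports the fractions of unique surfaces occurring exactly once,
    2–10 times and more than 10,000 times, plus the share of the 17,576
    possible three-letter upper-case forms observed at least once.
    """
    counts = _count_tokens(records, "both", config)
    total = len(counts)
    if total == 0:
        return FrequencySpectrum(0, 0.0, 0.0, 0.0, 0.0)
    once = sum(1 for c in counts.values() if c == 1)
    two_ten = sum(1 for c in counts.values() if 2 <= c <= 10)
    big = sum(1 for c in counts.values() if c > 10000)
    three_letter = sum(
        1 for s in counts
        if len(s) == 3 and s.isalpha() and s.isupper()
    )
    return FrequencySpectrum(
        total_unique=total,
        frac_once=once / total,
        frac_2_to_10=two_ten / total,
        frac_gt_10000=big / total,
        three_letter_coverage=three_letter / N_POSSIBLE_THREE_LETTER,
    )


def annual_word_counts(records: Iterable[PaperRecord],
                       field: str) -> list[tuple[int, float]]:
    """Mean words per paper per year, years with no records omitted."""
    per_year: dict[int, list[int]] = defaultdict(list)
    for rec in records:
        text = rec.field_text(field)
        if text is None or rec.year is None:
            continue
        n = count_acronyms(text).n_words
        per_year[rec.year].append(n)
    return [(year, float(np.mean(per_year[year]))) for year in sorted(per_year)]
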