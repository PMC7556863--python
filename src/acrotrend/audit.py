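"""Audit machinery for hand-checking the detector.

The detector is validated by drawing random samples of titles and
abstracts from each outcome category (excluded, no acronym found, at
least one acronym found), hand-checking them, and summarising the x
errors observed in n checks with a Bayesian upper bound: the 95th
percentile of the Beta(x + 1, n − x + 1) posterior under a uniform
prior.  Zero observed errors therefore still yield a positive bound —
about 1.0% at n = 300 — which is the point: styles vary enough across
journals that a zero error rate is implausible.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import beta as _beta

from .detect import DEFAULT_CONFIG, DetectorConfig, count_acronyms
from .filters import DEFAULT_FILTER_CONFIG, FilterConfig, filter_record

AUDIT_CATEGORIES = (
    "excluded_title",
    "title_no_acronym",
    "title_with_acronym",
    "abstract_no_acronym",
    "abstract_with_acronym",
)


@dataclasses.dataclass(frozen=True)
class ErrorAudit:
    """One audit row: x errors in n checks, with the posterior bound."""

    category: str
    n_checked: int
    x_errors: int
    avg_pct: float
    upper95_pct: float

    def rounded(self) -> tuple[float, float]:
        """(average %, upper bound %) rounded half-up to 1 decimal for tables."""
        return _round_half_up(self.avg_pct), _round_half_up(self.upper95_pct)


def _round_half_up(value: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return np.floor(value * factor + 0.5) / factor


def beta_upper_bound(x: int, n: int, q: float = 0.95) -> float:
    """Upper credible bound (in percent) on an error rate.

    Returns 100 times the ``q`` quantile of Beta(x + 1, n − x + 1), the
    posterior for a binomial rate under a uniform prior after observing
    ``x`` errors in ``n`` checks.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return 100.0 * float(_beta.ppf(q, x + 1, n - x + 1))


def audit_summary(categories: Iterable[tuple[str, int, int]],
                  q: float = 0.95) -> list[ErrorAudit]:
    """Summarise (category, n_checked, x_errors) rows into :class:`ErrorAudit`.

    Full precision is retained internally; use :meth:`ErrorAudit.rounded`
    for one-decimal presentation.
    """
    out = []
    for category, n, x in categories:
        out.append(ErrorAudit(
            category=category,
            n_checked=n,
            x_errors=x,
            avg_pct=100.0 * x / n,
            upper95_pct=beta_upper_bound(x, n, q),
        ))
    return out


def categorize_records(records: Sequence, *,
                       filter_config: FilterConfig = DEFAULT_FILTER_CONFIG,
                       detector_config: DetectorConfig = DEFAULT_CONFIG) -> dict:
    """Partition paper ids into the five audit categories.

    A title is "excluded" when any exclusion rule fires for the title
    field; otherwise it lands in with/without-acronym by the detector.
    Abstracts that are excluded (absent, non-English record, ...) belong
    to no abstract category — only screenable abstracts are auditable.
    """
    pops: dict[str, list[str]] = {c: [] for c in AUDIT_CATEGORIES}
    for rec in records:
        if filter_record(rec, "title", filter_config) is not None:
            pops["excluded_title"].append(rec.paper_id)
        else:
            key = "title_with_acronym" \
                if count_acronyms(rec.title, detector_config).n_acronym_tokens \
                else "title_no_acronym"
            pops[key].append(rec.paper_id)
        if filter_record(rec, "abstract", filter_config) is None:
            key = "abstract_with_acronym" \
                if count_acronyms(rec.abstract, detector_config).n_acronym_tokens \
                else "abstract_no_acronym"
            pops[key].append(rec.paper_id)
    return pops


def sample_for_check(records: Sequence, category: str, n: int = 300,
                     seed: int = 0, **kwargs) -> list[str]:
    """Draw a reproducible simple random sample of paper ids to hand-check.

    Samples without replacement from the requested category population;
    if the population is smaller than ``n`` the whole population is
    returned (a warning is logged).  The same seed always yields the same
    sample.
    """
    if category not in AUDIT_CATEGORIES:
        raise ValueError(f"unknown audit category {category!r}; "
                         f"expected one of {AUDIT_CATEGORIES}")
    population = categorize_records(records, **kwargs)[category]
    if not population:
        raise ValueError(f"audit category {category!r} has an empty population")
    rng = np.random.default_rng(seed)
    if len(population) <= n:
        import logging
        logging.getLogger(__name__).warning(
            "population for %s has only %d items (< %d); returning all",
            category, len(population), n)
        return list(population)
    idx = rng.choice(len(population), size=n, replace=False)
    return [population[i] for i in sorted(idx)]
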