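"""Record-level exclusion rules and their accounting.

A title or abstract enters the trend analysis only if its record has a
resolvable date, is in English, falls inside the study window (1950
onward by default), carries at least one article type (titles), and the
text itself exists, has more than one word and is not mostly capitals.
Each excluded (record, field) pair gets exactly one reason, assigned in a
fixed precedence order — metadata problems before content problems — so
tallies are reproducible and conserve the record count exactly.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter
from typing import Iterable

import pandas as pd

from .detect import fraction_capital_words, tokenize_surfaces
from .records import PaperRecord

FIELDS = ("title", "abstract")


class ExclusionReason(enum.Enum):
    MISSING_DATE = "missing_date"
    NON_ENGLISH = "non_english"
    PRE_START_YEAR = "pre_start_year"
    NO_ARTICLE_TYPE = "no_article_type"
    NO_ABSTRACT = "no_abstract"
    EMPTY = "empty"
    ONE_WORD = "one_word"
    MOSTLY_CAPITALS = "mostly_capitals"
    DUPLICATE_ID = "duplicate_id"  # reported by dedupe, kept here for the tally table


#: Evaluation order.  DUPLICATE_ID never fires here: duplicates are removed
#: upstream by records.dedupe and only enter the tally as a reported count.
PRECEDENCE = (
    ExclusionReason.MISSING_DATE,
    ExclusionReason.NON_ENGLISH,
    ExclusionReason.PRE_START_YEAR,
    ExclusionReason.NO_ARTICLE_TYPE,
    ExclusionReason.NO_ABSTRACT,
    ExclusionReason.EMPTY,
    ExclusionReason.ONE_WORD,
    ExclusionReason.MOSTLY_CAPITALS,
)


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the exclusion rules.

    start_year
        First calendar year included; 1950 by default (acronym use surged
        after the Second World War and earlier coverage is sparse).
    caps_threshold
        A text whose fraction of all-capital words reaches this value is
        excluded as unscreenable; 0.60 by default.
    english_codes
        Language metadata values accepted as English.  Language is taken
        verbatim from the record metadata; no text-based detection.
    """

    start_year: int = 1950
    caps_threshold: float = 0.60
    english_codes: frozenset = frozenset({"eng"})
    require_article_type_for_title: bool = True


DEFAULT_FILTER_CONFIG = FilterConfig()


def filter_record(record: PaperRecord, field: str,
                  config: FilterConfig = DEFAULT_FILTER_CONFIG) -> ExclusionReason | None:
    """Return ``None`` if the field is included, else the first firing reason.

    ``field`` is ``"title"`` or ``"abstract"``.  The article-type rule
    applies to titles only and the no-abstract rule to abstracts only,
    mirroring how the two fields are screened.
    """
    if field not in FIELDS:
        raise ValueError(f"unknown field {field!r}")
    if record.pub_date is None or record.year is None:
        return ExclusionReason.MISSING_DATE
    if record.language not in config.english_codes:
        return ExclusionReason.NON_ENGLISH
    if record.year < config.start_year:
        return ExclusionReason.PRE_START_YEAR
    if (field == "title" and config.require_article_type_for_title
            and not record.article_types):
        return ExclusionReason.NO_ARTICLE_TYPE
    text = record.field_text(field)
    if field == "abstract" and text is None:
        return ExclusionReason.NO_ABSTRACT
    if text is None or not text.strip():
        return ExclusionReason.EMPTY
    n_words = len(tokenize_surfaces(text))
    if n_words == 0:
        return ExclusionReason.EMPTY
    if n_words == 1:
        return ExclusionReason.ONE_WORD
    if fraction_capital_words(text) >= config.caps_threshold:
        return ExclusionReason.MOSTLY_CAPITALS
    return None


def filter_records(records: Iterable[PaperRecord], field: str,
                   config: FilterConfig = DEFAULT_FILTER_CONFIG) -> list[PaperRecord]:
    """Records whose ``field`` passes every exclusion rule."""
    return [r for r in records if filter_record(r, field, config) is None]


def tally_exclusions(records: Iterable[PaperRecord],
                     config: FilterConfig = DEFAULT_FILTER_CONFIG,
                     n_duplicates: int = 0) -> pd.DataFrame:
    """Reason-by-field exclusion table plus included totals.

    Every record contributes exactly one cell per field, so per-field
    column sums equal the number of records (duplicate rows, passed in
    from the dedupe step, are additional bookkeeping lines).  Returned as
    a DataFrame indexed by reason with columns ``title`` and ``abstract``,
    ending with ``included`` and ``total`` rows.
    """
    counts = {f: Counter() for f in FIELDS}
    included = {f: 0 for f in FIELDS}
    total = 0
    for rec in records:
        total += 1
        for f in FIELDS:
            reason = filter_record(rec, f, config)
            if reason is None:
                included[f] += 1
            else:
                counts[f][reason] += 1
    rows = {}
    for reason in PRECEDENCE:
        rows[reason.value] = {f: counts[f].get(reason, 0) for f in FIELDS}
    rows[ExclusionReason.DUPLICATE_ID.value] = {f: n_duplicates for f in FIELDS}
    rows["total_excluded"] = {
        f: sum(counts[f].values()) + n_duplicates for f in FIELDS
    }
    rows["included"] = dict(included)
    rows["total"] = {f: total for f in FIELDS}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "reason"
    return df
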