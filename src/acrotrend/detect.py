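"""Tokenisation and the character-based acronym rule.

An acronym here is any token of two or more characters in which at least
half of the characters are upper-case letters.  The character count is the
whole stripped token — letters, digits and internal punctuation alike — so
"mRNA" qualifies (3 upper of 4), "BRCA1" qualifies (4 of 5) and "N95" does
not (1 of 3).  This deliberately broad rule covers acronyms proper (AIDS),
initialisms (WHO) and capitalised abbreviations (BRCA) without requiring a
parenthesised definition, while leaving lexicalised forms like "laser"
untouched.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter
from typing import Iterable

#: Punctuation stripped from token edges.  Hyphens and slashes are *not*
#: stripped: they are word-internal ("B-AE-D", "HC-MVECs") and removing
#: them would change the character denominator.
#: (em/en dashes and the minus sign are punctuation, not word-internal
#: hyphens, so they are stripped too)
_STRIP_CHARS = "\"'“”‘’«»()[]{}<>,.;:!?…*†‡—–−"

#: Grammatical possessive suffixes removed before counting characters.
_POSSESSIVES = ("'s", "’s")


class AcronymKind(enum.Enum):
    LETTERS_ONLY = "letters_only"
    LETTERS_AND_NUMBERS = "letters_and_numbers"


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """Tunable knobs of the character rule.

    min_length
        Shortest token that can be an acronym.  Single capitals are
        initials or variable names, never acronyms; the default is 2.
    alnum_denominator
        When true, only letters and digits count toward the character
        denominator (so "HC-MVECs" is judged on 7 characters, not 8).
        The default counts every character of the stripped token.
    """

    min_length: int = 2
    upper_fraction: float = 0.5
    alnum_denominator: bool = False


DEFAULT_CONFIG = DetectorConfig()


@dataclasses.dataclass(frozen=True)
class Token:
    """A whitespace-delimited word with enclosing punctuation stripped."""

    surface: str

    @property
    def n_chars(self) -> int:
        return len(self.surface)

    @property
    def n_upper(self) -> int:
        return sum(1 for c in self.surface if c.isupper())

    @property
    def has_digit(self) -> bool:
        return any(c.isdigit() for c in self.surface)

    @property
    def has_lower(self) -> bool:
        return any(c.islower() for c in self.surface)


@dataclasses.dataclass(frozen=True)
class AcronymToken:
    surface: str
    length: int
    kind: AcronymKind


@dataclasses.dataclass
class AcronymSummary:
    """Per-text acronym counts with length and kind strata."""

    n_words: int = 0
    n_acronym_tokens: int = 0
    by_length: Counter = dataclasses.field(default_factory=Counter)  # keys 2,3,4,"5+"
    by_kind: Counter = dataclasses.field(default_factory=Counter)    # AcronymKind keys
    surfaces: list = dataclasses.field(default_factory=list)

    @property
    def density_per_100_words(self) -> float:
        """Acronym tokens per 100 words; 0 for empty text."""
        return 100.0 * self.n_acronym_tokens / self.n_words if self.n_words else 0.0


def _strip_surface(raw: str) -> str:
    s = raw.strip(_STRIP_CHARS)
    for suffix in _POSSESSIVES:
        if s.endswith(suffix):
            s = s[: -len(suffix)]
            break
    return s


def tokenize_surfaces(text: str) -> list[str]:
    """Token surfaces of ``text``: whitespace runs, edges stripped.

    Tokens that are pure punctuation vanish entirely and do not count as
    words.  Hyphenated forms stay whole ("YST-adjusted" is one 12-character
    token); splitting them would inflate word counts.
    """
    if not text:
        return []
    out = []
    for raw in text.split():
        s = _strip_surface(raw)
        if s:
            out.append(s)
    return out


def tokenize(text: str) -> list[Token]:
    """Like :func:`tokenize_surfaces` but wrapped in :class:`Token`."""
    return [Token(s) for s in tokenize_surfaces(text)]


def is_acronym(token: Token | str, config: DetectorConfig = DEFAULT_CONFIG) -> bool:
    """Apply the half-or-more-upper-case rule to one token.

    True iff the token has at least ``config.min_length`` characters and
    its upper-case letters make up at least half (``config.upper_fraction``)
    of its characters.  Digits count in the denominator ("N95" fails at
    1/3) but never in the numerator.
    """
    surface = token.surface if isinstance(token, Token) else token
    if config.alnum_denominator:
        denom = sum(1 for c in surface if c.isalnum())
    else:
        denom = len(surface)
    if denom < config.min_length:
        return False
    n_upper = sum(1 for c in surface if c.isupper())
    return n_upper >= config.upper_fraction * denom


def classify(token: Token | str,
             config: DetectorConfig = DEFAULT_CONFIG) -> AcronymToken | None:
    """Return an :class:`AcronymToken` for acronym tokens, else ``None``."""
    surface = token.surface if isinstance(token, Token) else token
    if not is_acronym(surface, config):
        return None
    kind = AcronymKind.LETTERS_ONLY if surface.isalpha() \
        else AcronymKind.LETTERS_AND_NUMBERS
    return AcronymToken(surface=surface, length=len(surface), kind=kind)


def length_stratum(length: int):
    """Bucket an acronym length into the reported strata 2, 3, 4, "5+"."""
    return length if length <= 4 else "5+"


def count_acronyms(text: str, config: DetectorConfig = DEFAULT_CONFIG) -> AcronymSummary:
    """Tokenise ``text`` and tally acronyms overall and by stratum.

    The summary's stratum counters always sum to ``n_acronym_tokens``;
    surfaces are listed in order of appearance with duplicates retained.
    """
    summary = AcronymSummary()
    if not text:
        return summary
    # Fast path: pure-lowercase words (the overwhelming majority of text)
    # are rejected with one C-level call before the per-character count.
    default_rule = (config == DEFAULT_CONFIG)
    for raw in text.split():
        s = _strip_surface(raw)
        if not s:
            continue
        summary.n_words += 1
        if default_rule:
            if s.islower():
                continue
            if len(s) < 2:
                continue
            if not (s.isupper() and s.isalpha()):
                if not is_acronym(s, config):
                    continue
        elif not is_acronym(s, config):
            continue
        summary.n_acronym_tokens += 1
        summary.by_length[length_stratum(len(s))] += 1
        kind = AcronymKind.LETTERS_ONLY if s.isalpha() else AcronymKind.LETTERS_AND_NUMBERS
        summary.by_kind[kind] += 1
        summary.surfaces.append(s)
    return summary


def acronym_surfaces(text: str, config: DetectorConfig = DEFAULT_CONFIG) -> list[str]:
    """Just the acronym surfaces of ``text``, in order, duplicates kept."""
    return count_acronyms(text, config).surfaces


def fraction_capital_words(text: str) -> float:
    """Fraction of words whose alphabetic characters are all upper case.

    Words with no alphabetic character are ignored in both numerator and
    denominator; empty text gives 0.  This is the statistic behind the
    all-capitals exclusion rule: a title like "EXPERIMENTAL STUDIES OF
    TUBERCULOSIS" scores 1.0 and cannot be screened for acronyms.
    """
    n_alpha_words = 0
    n_caps_words = 0
    for s in tokenize_surfaces(text):
        alpha = [c for c in s if c.isalpha()]
        if not alpha:
            continue
        n_alpha_words += 1
        if all(c.isupper() for c in alpha):
            n_caps_words += 1
    return n_caps_words / n_alpha_words if n_alpha_words else 0.0


def iter_field_acronyms(records: Iterable, field: str,
                        config: DetectorConfig = DEFAULT_CONFIG):
    """Yield ``(record, AcronymSummary)`` for one field across records.

    Records whose field is absent are skipped (not yielded at all), so
    callers never see a summary for text that does not exist.
    """
    for rec in records:
        text = rec.field_text(field)
        if text is None:
            continue
        yield rec, count_acronyms(text, config)
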