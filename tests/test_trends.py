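"""Annual densities, rankings, masking, spectra, word counts."""

import numpy as np
import pytest

from acrotrend import (N_POSSIBLE_THREE_LETTER, SyntheticConfig,
                       annual_trends, annual_word_counts, frequency_spectrum,
                       generate_corpus, top_acronyms, trends_by_article_type,
                       trends_excluding_top)
from acrotrend.detect import count_acronyms
from acrotrend.trends import top_acronyms_per_year

from conftest import make_record


class TestAnnualTrends:
    def test_mean_of_ratios(self):
        recs = [
            make_record(paper_id="1", year=1990, title="no acronyms here at"),
            make_record(paper_id="2", year=1990, title="the DNA study is"),
        ]
        (t,) = annual_trends(recs, "title")
        assert t.mean_density == pytest.approx(12.5)
        assert t.n_papers == 2
        assert t.mean_words == pytest.approx(4.0)
        assert t.ci_low <= t.mean_density <= t.ci_high

    def test_single_paper_year_degenerate_ci(self):
        recs = [make_record(paper_id="1", year=1990, title="the DNA study is")]
        (t,) = annual_trends(recs, "title")
        assert t.degenerate_ci
        assert t.ci_low == t.ci_high == t.mean_density

    def test_empty_year_omitted(self):
        recs = [make_record(paper_id="1", year=1990),
                make_record(paper_id="2", year=1992)]
        years = [t.year for t in annual_trends(recs, "title")]
        assert years == [1990, 1992]

    def test_pooled_variant_differs(self):
        recs = [
            make_record(paper_id="1", year=1990, title="DNA is"),
            make_record(paper_id="2", year=1990,
                        title="a much longer title with no acronyms inside it"),
        ]
        (mean_of_ratios,) = annual_trends(recs, "title")
        (pooled,) = annual_trends(recs, "title", pooled=True)
        assert mean_of_ratios.mean_density == pytest.approx(25.0)
        assert pooled.mean_density == pytest.approx(100 / 11)

    def test_strata_sum_to_total(self):
        recs = [make_record(paper_id=str(i), year=2000,
                            title=f"the DNA and CD4 study BRCA1 PCR {i}")
                for i in range(5)]
        trends = annual_trends(recs, "title", stratify=True)
        for t in trends:
            length_total = sum(v for (dim, _k), v in t.strata.items()
                               if dim == "length")
            kind_total = sum(v for (dim, _k), v in t.strata.items()
                             if dim == "kind")
            assert length_total == pytest.approx(t.mean_density)
            assert kind_total == pytest.approx(t.mean_density)

    def test_oracle_equivalence_small_corpus(self):
        """annual_trends equals an independent per-paper loop on a
        generated corpus of <= 50 papers."""
        records, _ = generate_corpus(SyntheticConfig(
            seed=11, year_start=2000, year_end=2004, papers_per_year=10))
        trends = {t.year: t for t in annual_trends(records, "abstract")}
        by_year = {}
        for rec in records:
            if rec.abstract is None:
                continue
            s = count_acronyms(rec.abstract)
            by_year.setdefault(rec.year, []).append(
                100.0 * s.n_acronym_tokens / s.n_words)
        for year, densities in by_year.items():
            assert trends[year].mean_density == pytest.approx(
                sum(densities) / len(densities))
            assert trends[year].n_papers == len(densities)


class TestTopAcronyms:
    CORPUS = [
        make_record(paper_id="1", year=1990, title="DNA and RNA"),
        make_record(paper_id="2", year=1990, title="DNA here"),
        make_record(paper_id="3", year=1991, title="CI DNA"),
    ]

    def test_ranking_and_ties(self):
        top = top_acronyms(self.CORPUS, "title", n=2)
        assert top == [("DNA", 3), ("CI", 1)]  # CI < RNA lexicographically
        full = top_acronyms(self.CORPUS, "title", n=10)
        assert full == [("DNA", 3), ("CI", 1), ("RNA", 1)]

    def test_year_restriction(self):
        assert top_acronyms(self.CORPUS, "title", year=1991, n=5) == \
            [("CI", 1), ("DNA", 1)]

    def test_empty_year(self):
        assert top_acronyms(self.CORPUS, "title", year=1890, n=5) == []

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_acronyms(self.CORPUS, "title", n=0)

    def test_case_sensitive_surfaces(self):
        recs = [make_record(paper_id="1", title="mRNA versus MRNA tests")]
        assert dict(top_acronyms(recs, "title", n=5)) == {"mRNA": 1, "MRNA": 1}

    def test_token_occurrences_not_presence(self):
        recs = [make_record(paper_id="1", title="DNA DNA DNA")]
        assert top_acronyms(recs, "title", n=1) == [("DNA", 3)]

    def test_per_year_table(self):
        df = top_acronyms_per_year(self.CORPUS, field="title", n=2)
        assert list(df.columns) == ["year", "rank", "surface", "count"]
        assert df[df.year == 1990].iloc[0].surface == "DNA"


class TestMasking:
    def test_k0_is_identity(self):
        recs = [make_record(paper_id=str(i), year=2000,
                            title=f"the DNA study number {i}")
                for i in range(4)]
        assert [t.mean_density for t in trends_excluding_top(recs, "title", 0)] == \
            [t.mean_density for t in annual_trends(recs, "title")]

    def test_single_dominant_surface(self):
        recs = [make_record(paper_id=str(i), year=2000,
                            title="the DNA study here") for i in range(3)]
        (t,) = trends_excluding_top(recs, "title", 1)
        assert t.mean_density == 0.0
        assert t.mean_words == pytest.approx(4.0)  # masked token still a word

    def test_masking_monotone_in_k(self):
        records, _ = generate_corpus(SyntheticConfig(
            seed=5, year_start=1995, year_end=2000, papers_per_year=40))
        base = annual_trends(records, "abstract")
        prev = {t.year: t.mean_density for t in base}
        for k in (1, 5, 20):
            cur = {t.year: t.mean_density
                   for t in trends_excluding_top(records, "abstract", k)}
            for year in cur:
                assert cur[year] <= prev[year] + 1e-12
            prev = cur


class TestByArticleType:
    def test_multi_typed_record_in_both_series(self):
        rec = make_record(paper_id="1", year=2000, title="the DNA study is",
                          article_types=("Journal Article", "Editorial"))
        out = trends_by_article_type([rec], "title",
                                     ["Journal Article", "Editorial"])
        assert out["Journal Article"][0].mean_density == \
            out["Editorial"][0].mean_density == pytest.approx(25.0)

    def test_unknown_type_yields_empty_series(self):
        rec = make_record(paper_id="1", year=2000)
        out = trends_by_article_type([rec], "title", ["Letter"])
        assert out["Letter"] == []


class TestFrequencySpectrum:
    def test_counts(self):
        recs = [
            make_record(paper_id="1", title="AB and CD study"),
            make_record(paper_id="2", title="EF and EF again",
                        abstract="more of EF here"),
        ]
        spec = frequency_spectrum(recs)
        assert spec.total_unique == 3
        assert spec.frac_once == pytest.approx(2 / 3)
        assert spec.frac_2_to_10 == pytest.approx(1 / 3)
        assert spec.frac_gt_10000 == 0.0

    def test_possible_three_letter_constant(self):
        assert N_POSSIBLE_THREE_LETTER == 26 ** 3 == 17576

    def test_full_three_letter_coverage(self):
        import itertools
        import string
        surfaces = ["".join(c) for c in
                    itertools.product(string.ascii_uppercase, repeat=3)]
        # pack the whole combinatorial space into titles, 500 per record
        recs = [make_record(paper_id=str(i),
                            title=" ".join(surfaces[i * 500:(i + 1) * 500]))
                for i in range(36)]
        spec = frequency_spectrum(recs)
        assert spec.three_letter_coverage == 1.0
        assert spec.total_unique == 17576

    def test_three_letter_requires_letters_only(self):
        recs = [make_record(paper_id="1", title="CD4 study of AB1 and XYZ")]
        spec = frequency_spectrum(recs)
        assert spec.three_letter_coverage == pytest.approx(1 / 17576)

    def test_empty(self):
        spec = frequency_spectrum([])
        assert spec.total_unique == 0
        assert spec.three_letter_coverage == 0.0


class TestAnnualWordCounts:
    def test_mean(self):
        recs = [make_record(paper_id="1", year=1990, title="one two three"),
                make_record(paper_id="2", year=1990,
                            title="one two three four five")]
        assert annual_word_counts(recs, "title") == [(1990, 4.0)]

    def test_empty_year_omitted(self):
        recs = [make_record(paper_id="1", year=1990),
                make_record(paper_id="2", year=1993)]
        assert [y for y, _ in annual_word_counts(recs, "title")] == [1990, 1993]
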