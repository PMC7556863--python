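import datetime as dt

import pytest

from acrotrend import PaperRecord

MEDLINE_XML = """<?xml version="1.0" encoding="utf-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>100001</PMID>
      <MedlineJournalInfo><NlmUniqueID>J-ALPHA</NlmUniqueID></MedlineJournalInfo>
      <Article>
        <Journal>
          <ISSN>0001-0001</ISSN>
          <JournalIssue><PubDate><Year>1990</Year><Month>Jul</Month></PubDate></JournalIssue>
          <Title>Journal Alpha</Title>
        </Journal>
        <ArticleTitle>The DNA study</ArticleTitle>
        <Abstract><AbstractText>We measured mRNA levels in the CELL nucleus.</AbstractText></Abstract>
        <Language>eng</Language>
        <PublicationTypeList><PublicationType>Journal Article</PublicationType></PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>100002</PMID>
      <MedlineJournalInfo><NlmUniqueID>J-BETA</NlmUniqueID></MedlineJournalInfo>
      <Article>
        <Journal>
          <JournalIssue><PubDate><MedlineDate>1999 Jan-Feb</MedlineDate></PubDate></JournalIssue>
          <Title>Journal Beta</Title>
        </Journal>
        <ArticleTitle>Étude générale sans résumé</ArticleTitle>
        <Language>fre</Language>
        <PublicationTypeList><PublicationType>Review</PublicationType></PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>100001</PMID>
      <MedlineJournalInfo><NlmUniqueID>J-ALPHA</NlmUniqueID></MedlineJournalInfo>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>1990</Year></PubDate></JournalIssue>
          <Title>Journal Alpha</Title>
        </Journal>
        <ArticleTitle>The DNA study</ArticleTitle>
        <Language>eng</Language>
        <PublicationTypeList><PublicationType>Journal Article</PublicationType></PublicationTypeList>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID></PMID>
      <Article>
        <ArticleTitle>Orphan citation with no identifier</ArticleTitle>
        <Language>eng</Language>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def medline_xml(tmp_path):
    path = tmp_path / "baseline.xml"
    path.write_text(MEDLINE_XML, encoding="utf-8")
    return path


def make_record(paper_id="P1", year=2000, month=1, day=1, journal="J1",
                title="A plain title about science", abstract=None,
                language="eng", article_types=("Journal Article",)):
    return PaperRecord(
        paper_id=paper_id, year=year,
        pub_date=dt.date(year, month, day) if year else None,
        journal_id=journal, title=title, abstract=abstract,
        language=language, article_types=tuple(article_types),
    )


@pytest.fixture
def record_factory():
    return make_record
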