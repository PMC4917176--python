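"""Article parsing, captions, partitioning and round-trips."""

import pytest

from resmine.corpus_io import (
    Article,
    ArticleParseError,
    CorpusPartition,
    JournalCatalog,
    corpus_summary,
    extract_captions,
    parse_article,
    partition_corpus,
    serialize_article,
)


class TestParseArticle:
    def test_jats_fixture_fields(self, jats_fixture):
        a = parse_article(jats_fixture)
        assert a.doc_id == "fx001"
        assert a.journal == "Journal of Computational Genomics"
        assert a.year == 2009
        assert [h[0] for h in a.heading_spans] == ["Introduction", "Methods"]
        assert len(a.captions) == 1
        # heading offsets index into the stripped body
        for text, start, end in a.heading_spans:
            assert a.body[start:end] == text
        assert "ClustalW software (version 2.0)" in a.body

    def test_caption_text_not_in_body(self, jats_fixture):
        a = parse_article(jats_fixture)
        assert "Figure 1" not in a.body
        assert a.captions[0].startswith("Figure 1.")

    def test_plain_text_has_no_structure(self):
        a = parse_article("Just a paragraph of text.", format="plain_text")
        assert a.body == "Just a paragraph of text."
        assert a.heading_spans == [] and a.captions == []

    def test_empty_body_article(self):
        a = parse_article("<article><body></body></article>")
        assert a.body == "" and a.heading_spans == []

    def test_malformed_xml_raises(self):
        with pytest.raises(ArticleParseError):
            parse_article("<article><body>")

    def test_missing_year_flagged_not_fatal(self):
        a = parse_article("<article><body><sec><p>x</p></sec></body></article>")
        assert a.year_missing

    def test_empty_document_raises(self):
        with pytest.raises(ArticleParseError):
            parse_article("")


class TestCaptions:
    def test_two_captions_in_order(self):
        xml = ("<article><body><sec><p>t</p></sec>"
               "<fig><caption><p>first</p></caption></fig>"
               "<fig><caption><p>second</p></caption></fig></body></article>")
        assert extract_captions(xml) == ["first", "second"]

    def test_no_captions(self):
        assert extract_captions("<article><body><sec><p>t</p></sec></body></article>") == []

    def test_nested_markup_stripped(self):
        xml = ("<article><body><fig><caption><p>uses <italic>R</italic> heavily"
               "</p></caption></fig></body></article>")
        assert extract_captions(xml) == ["uses R heavily"]


class TestRoundTrip:
    def test_serialize_parse_lossless_on_synthetic(self, small_corpus):
        for a in small_corpus.articles[:20]:
            b = parse_article(serialize_article(a), doc_id=a.doc_id)
            assert b.body == a.body
            assert b.captions == a.captions
            assert b.heading_spans == a.heading_spans
            assert (b.journal, b.year) == (a.journal, a.year)


CATALOG = JournalCatalog(codes={
    "Med Weekly": {"H02.403.100"},
    "Bio Letters": {"H01.158.273.900"},
    "In Silico J": {"H01.158.273.180"},
})


def _art(doc_id, journal):
    return Article(doc_id=doc_id, journal=journal, year=2010, body="x")


class TestPartitioning:
    def test_three_journal_fixture(self):
        arts = [_art("d1", "Med Weekly"), _art("d2", "Bio Letters"),
                _art("d3", "In Silico J")]
        parts = {p.name: p for p in partition_corpus(arts, CATALOG)}
        assert len(parts["full"]) == 3
        assert parts["medicine"].doc_ids == {"d1"}
        assert parts["biology"].doc_ids == {"d2", "d3"}
        assert parts["bioinformatics"].doc_ids == {"d3"}

    def test_bioinformatics_is_subset_of_biology(self, small_corpus):
        parts = {p.name: p for p in small_corpus.partitions()}
        assert parts["bioinformatics"].doc_ids <= parts["biology"].doc_ids
        assert parts["biology"].doc_ids <= parts["full"].doc_ids
        assert parts["medicine"].doc_ids <= parts["full"].doc_ids

    def test_uncatalogued_journal_goes_to_full_only(self):
        arts = [_art("d9", "Obscure Gazette")]
        parts = {p.name: p for p in partition_corpus(arts, CATALOG)}
        assert parts["full"].doc_ids == {"d9"}
        assert all(len(parts[n]) == 0 for n in ("medicine", "biology", "bioinformatics"))

    def test_exact_code_matches_its_partition(self):
        # a journal carrying the bioinformatics code belongs to biology too
        arts = [_art("d3", "In Silico J")]
        parts = {p.name: p for p in partition_corpus(arts, CATALOG)}
        assert "d3" in parts["bioinformatics"].doc_ids
        assert "d3" in parts["biology"].doc_ids


class TestCatalogAndDirectory:
    def test_catalog_tsv_round_trip(self, tmp_path):
        p = tmp_path / "catalog.tsv"
        p.write_text("# journal\tcodes\nMed Weekly\tH02.403.100\n"
                     "Hybrid J\tH02.403\tH01.158.273\n")
        cat = JournalCatalog.from_tsv(p)
        assert cat.codes["Med Weekly"] == {"H02.403.100"}
        assert cat.codes["Hybrid J"] == {"H02.403", "H01.158.273"}

    def test_journal_with_multiple_codes_joins_all_partitions(self, tmp_path):
        p = tmp_path / "catalog.tsv"
        p.write_text("Hybrid J\tH02.403\tH01.158.273\n")
        cat = JournalCatalog.from_tsv(p)
        parts = {p.name: p for p in partition_corpus([_art("d1", "Hybrid J")], cat)}
        assert "d1" in parts["medicine"].doc_ids
        assert "d1" in parts["biology"].doc_ids

    def test_bad_documents_skipped_and_counted(self, tmp_path, jats_fixture):
        from resmine.corpus_io import read_corpus_dir
        (tmp_path / "good.xml").write_text(jats_fixture)
        (tmp_path / "bad.xml").write_text("<article><body>")
        articles, failed = read_corpus_dir(tmp_path)
        assert len(articles) == 1 and failed == 1


class TestCorpusSummary:
    def test_empty_partition(self):
        assert corpus_summary(CorpusPartition(name="full")) == (0, 0)

    def test_counts(self):
        p = CorpusPartition(name="full", journal_names={"A", "B"},
                            doc_ids={f"d{i}" for i in range(5)})
        assert corpus_summary(p) == (2, 5)

    def test_full_is_union_of_docs(self, small_corpus):
        parts = {p.name: p for p in small_corpus.partitions()}
        union = set().union(*(parts[n].doc_ids for n in
                              ("medicine", "biology", "bioinformatics")))
        assert union <= parts["full"].doc_ids
        assert len(parts["full"]) == len(small_corpus.articles)
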