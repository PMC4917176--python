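"""Shared fixtures: small synthetic corpora and hand-built articles."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from resmine.synthetic import GeneratorConfig, generate_corpus

JATS_FIXTURE = """<article>
  <front>
    <journal-meta><journal-title>Journal of Computational Genomics</journal-title></journal-meta>
    <article-meta>
      <article-id>fx001</article-id>
      <title-group><article-title>A worked example</article-title></title-group>
      <pub-date><year>2009</year></pub-date>
    </article-meta>
  </front>
  <body>
    <sec><title>Introduction</title>
      <p>Sequence analysis has a long history.</p>
    </sec>
    <sec><title>Methods</title>
      <p>Sequences were aligned with the ClustalW software (version 2.0).</p>
    </sec>
    <fig><caption><p>Figure 1. Alignment produced with <italic>ClustalW</italic>.</p></caption></fig>
  </body>
</article>
"""


@dataclass
class StubMention:
    """Minimal mention record for analytics-level tests."""

    doc_id: str
    span: tuple[int, int]
    surface: str
    canonical: str | None = None
    stream: str = "body"
    section: str | None = None


@pytest.fixture(scope="session")
def small_corpus():
    """100 synthetic articles with gold annotations (fixed seed)."""
    return generate_corpus(GeneratorConfig(seed=101, n_articles=100))


@pytest.fixture(scope="session")
def default_corpus():
    """The generator's default study conditions (500 articles)."""
    return generate_corpus(GeneratorConfig(seed=202))


@pytest.fixture()
def jats_fixture() -> str:
    return JATS_FIXTURE
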