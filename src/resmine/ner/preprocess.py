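"""Deterministic shallow preprocessing.

Full statistical dependency parsing is deliberately replaced by a cheap,
reproducible shallow parse: regex sentence splitting and tokenisation, a
closed-class + suffix part-of-speech tagger, and a nearest-head heuristic
that links every token inside a noun-phrase run to the run's final noun.
The downstream rules only need noun-phrase heads and adjacency, for which
this approximation is sufficient and byte-stable across runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# coarse tagset
DET, ADJ, NOUN, PROPN, VERB, NUM, PUNCT, URL, REF, OTHER = (
    "DET", "ADJ", "NOUN", "PROPN", "VERB", "NUM", "PUNCT", "URL", "REF", "OTHER")

_DETERMINERS = {"a", "an", "the", "this", "that", "these", "those", "our",
                "its", "their", "each", "every", "all", "some", "any", "no",
                "several", "both", "many", "most", "few", "other", "another", "such"}
_PREP_CONJ = {"of", "in", "on", "for", "with", "within", "by", "to", "from",
              "as", "at", "into", "through", "between", "and", "or", "but",
              "nor", "than", "via", "per", "during", "after", "before",
              "against", "using", "including", "is", "are", "was", "were",
              "be", "been", "has", "have", "had", "can", "could", "may",
              "might", "will", "would", "not", "we", "it", "they", "which",
              "that", "then", "also", "here", "thus", "however", "e.g.", "i.e."}
_VERB_SUFFIXES = ("ed", "ing", "ise", "ize", "ises", "izes")
_COMMON_VERBS = {"use", "used", "using", "uses", "run", "ran", "perform",
                 "performed", "align", "aligned", "analyse", "analysed",
                 "analyze", "analyzed", "compute", "computed", "implement",
                 "implemented", "develop", "developed", "apply", "applied",
                 "generate", "generated", "obtain", "obtained", "compare",
                 "compared", "download", "downloaded", "visualise",
                 "visualised", "visualize", "visualized", "provide",
                 "provides", "provided", "show", "shows", "showed",
                 "describe", "described", "calculate", "calculated"}
_ADJ_SUFFIXES = ("al", "ive", "ous", "ary", "ic", "able", "ible", "novel", "new")

_ABBREVS = ("e.g.", "i.e.", "et al.", "vs.", "Fig.", "fig.", "ca.", "approx.",
            "no.", "vol.", "cf.", "v.", "ver.")

_TOKEN_RE = re.compile(
    r"https?://[^\s)\]>,;]+"          # URLs
    r"|www\.[^\s)\]>,;]+"
    r"|\[\d+(?:[,–-]\s*\d+)*\]"  # bracketed citation markers [3], [1-4]
    # words, with internal hyphens and internal dots ("ClinicalTrials.gov")
    # but never a trailing dot (sentence-final periods stay separate)
    r"|[A-Za-z][\w+'’-]*(?:\.[A-Za-z][\w+'’-]*)*"
    r"|\d+(?:\.\d+)*"                 # numbers / versions
    r"|[^\w\s]"                       # single punctuation
)
_AUTHOR_YEAR = re.compile(r"^\(?[A-Z][a-z]+(?:\s+et\s+al\.?)?,?\s+(19|20)\d\d\)?$")


@dataclass
class Token:
    text: str
    start: int
    end: int
    tag: str = OTHER
    head: int | None = None  # index within sentence; None = root


@dataclass
class Sentence:
    tokens: list[Token] = field(default_factory=list)
    start: int = 0
    end: int = 0

    def __len__(self) -> int:
        return len(self.tokens)


def _split_sentences(text: str) -> list[tuple[int, int]]:
    """Offset ranges of sentences; protects common abbreviations/versions."""
    spans = []
    n = len(text)
    start = 0
    i = 0
    while i < n:
        c = text[i]
        if c in ".!?":
            # do not split inside version numbers (2.0) or abbreviations
            prev_ok = True
            for ab in _ABBREVS:
                if text[max(0, i - len(ab) + 1):i + 1] == ab:
                    prev_ok = False
                    break
            if c == "." and i + 1 < n and text[i + 1].isdigit():
                prev_ok = False
            if c == "." and i > 0 and text[i - 1].isdigit() and i + 1 < n and text[i + 1].isdigit():
                prev_ok = False
            if prev_ok:
                j = i + 1
                while j < n and text[j] in '")]’':
                    j += 1
                if j >= n or text[j] in " \n\t":
                    spans.append((start, j))
                    while j < n and text[j] in " \n\t":
                        j += 1
                    start = j
                    i = j
                    continue
        elif c == "\n":
            if i > start:
                spans.append((start, i))
            start = i + 1
        i += 1
    if start < n:
        spans.append((start, n))
    return [(s, e) for s, e in spans if e > s]


def _tag(word: str, is_sent_initial: bool) -> str:
    low = word.lower()
    if word.startswith(("http://", "https://", "www.")):
        return URL
    if word.startswith("[") or _AUTHOR_YEAR.match(word):
        return REF
    if re.fullmatch(r"\d+(?:\.\d+)*", word):
        return NUM
    if not any(ch.isalnum() for ch in word):
        return PUNCT
    if low in _DETERMINERS:
        return DET
    if low in _COMMON_VERBS:
        return VERB
    if low in _PREP_CONJ:
        return OTHER
    if word[0].isupper() or word.isupper():
        # capitalised mid-sentence (or all-caps anywhere) -> proper noun
        if not is_sent_initial or word.isupper() or (len(word) > 1 and any(c.isupper() for c in word[1:])):
            return PROPN
        return NOUN
    if low.endswith(_VERB_SUFFIXES) and len(low) > 4:
        return VERB
    if low.endswith(_ADJ_SUFFIXES) and len(low) > 4:
        return ADJ
    return NOUN

_NP_TAGS = {DET, ADJ, NOUN, PROPN, NUM}


def _link_heads(tokens: list[Token]) -> None:
    """Nearest-head heuristic.

    Tokens inside a maximal noun-phrase run (DET/ADJ/NOUN/PROPN/NUM) point to
    the run's last noun-ish token; that head points to the sentence root (the
    first verb, else the first token).  Every sentence has exactly one root.
    """
    if not tokens:
        return
    root = next((i for i, t in enumerate(tokens) if t.tag == VERB), 0)
    tokens[root].head = None
    runs = []
    i = 0
    while i < len(tokens):
        if tokens[i].tag in _NP_TAGS:
            j = i
            while j + 1 < len(tokens) and tokens[j + 1].tag in _NP_TAGS:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    for i, j in runs:
        head = j
        while head > i and tokens[head].tag not in (NOUN, PROPN):
            head -= 1
        for k in range(i, j + 1):
            if k != head and k != root:
                tokens[k].head = head
        if head != root:
            tokens[head].head = root
    for k, t in enumerate(tokens):
        if t.head is None and k != root:
            t.head = root


def preprocess(body: str) -> list[Sentence]:
    """Sentence-split, tokenise, tag, and head-link a body string.

    Total and deterministic: degenerate text still yields tagged tokens with
    one root per sentence; an empty string yields no sentences.
    """
    sentences = []
    for s_start, s_end in _split_sentences(body):
        toks = []
        for m in _TOKEN_RE.finditer(body, s_start, s_end):
            toks.append(Token(text=m.group(), start=m.start(), end=m.end()))
        if not toks:
            continue
        for i, t in enumerate(toks):
            t.tag = _tag(t.text, is_sent_initial=(i == 0))
        _link_heads(toks)
        sentences.append(Sentence(tokens=toks, start=s_start, end=s_end))
    return sentences
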