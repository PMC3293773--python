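"""HTML corpus parsing, tokenization and the inverted index.

Documents are split into five tag zones (title, heading, anchor, table,
body). Two of the four relevance components live here: the TF-IDF keyword
score PP and the tag-field score PT.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import lxml.html

log = logging.getLogger(__name__)

ZONES = ("title", "heading", "anchor", "table", "body")

#: Default per-zone weights for the tag-field score PT.
DEFAULT_ZONE_WEIGHTS: dict[str, float] = {
    "title": 4.0,
    "heading": 3.0,
    "anchor": 2.0,
    "table": 1.0,
    "body": 1.0,
}

# A word is a maximal run of letters/digits, optionally joined by single
# internal periods (covers accession-style tokens like Hs.654481).
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:\.[a-z0-9]+)*")
_DNA_RE = re.compile(r"[acgtn]+\Z")
_DIGITS_RE = re.compile(r"[0-9]+\Z")


class Token(NamedTuple):
    text: str
    is_low_complexity: bool


def is_low_complexity(word: str) -> bool:
    """Flag sequence-like and degenerate words.

    Pure DNA-alphabet words of length >= 4, pure digit runs of length >= 4,
    and single-character runs are low complexity; such words never enter a
    descriptive lexicon (they are still indexed for search).
    """
    if len(set(word)) == 1:
        return True
    if len(word) >= 4 and (_DNA_RE.fullmatch(word) or _DIGITS_RE.fullmatch(word)):
        return True
    return False


def tokenize(text: str) -> list[Token]:
    """Case-folded word tokens of a text. Total: any input yields a list."""
    return [
        Token(w, is_low_complexity(w)) for w in _TOKEN_RE.findall(text.lower())
    ]


@dataclass
class Document:
    """A parsed HTML page, the unit of ranking and clustering."""

    doc_id: str
    url: str = ""
    source: str = ""
    zones: dict[str, list[Token]] = field(default_factory=dict)
    links: list[str] = field(default_factory=list)
    raw_html: str = ""

    def __post_init__(self) -> None:
        for zone in ZONES:
            self.zones.setdefault(zone, [])

    @property
    def raw_length(self) -> int:
        return sum(len(toks) for toks in self.zones.values())

    def term_frequency(self, term: str, zone: str | None = None) -> int:
        term = term.lower()
        zones = [zone] if zone else ZONES
        return sum(
            1 for z in zones for tok in self.zones[z] if tok.text == term
        )

    def all_tokens(self) -> list[Token]:
        return [tok for z in ZONES for tok in self.zones[z]]

    def contains(self, term: str) -> bool:
        return self.term_frequency(term) > 0


# zone priority when elements nest (e.g. an anchor inside a table cell)
_ZONE_OF_TAG = {
    "title": "title",
    "h1": "heading",
    "h2": "heading",
    "h3": "heading",
    "h4": "heading",
    "h5": "heading",
    "h6": "heading",
    "a": "anchor",
    "table": "table",
}
_ZONE_PRIORITY = {"title": 0, "heading": 1, "anchor": 2, "table": 3, "body": 4}
_SKIP_TAGS = {"script", "style"}


def parse_html_document(html: str, url: str = "", source: str = "",
                        doc_id: str = "") -> Document:
    """Parse lenient HTML into tag zones.

    Every text token lands in exactly one zone; the zone of nested elements
    is the highest-priority enclosing tag (title > heading > anchor > table),
    with everything else in the body. Scripts and styles are dropped.
    """
    doc = Document(doc_id=doc_id or url or "doc", url=url, source=source,
                   raw_html=html)
    try:
        root = lxml.html.fromstring(html) if html.strip() else None
    except Exception:  # pragma: no cover - lxml is extremely lenient
        log.warning("unparseable HTML for %s; treating as plain text", doc.doc_id)
        doc.zones["body"].extend(tokenize(html))
        return doc
    if root is None:
        return doc

    def walk(el, zone: str) -> None:
        if not isinstance(el.tag, str):  # comments, processing instructions
            return
        tag = el.tag
        if tag in _SKIP_TAGS:
            return
        here = zone
        mapped = _ZONE_OF_TAG.get(tag)
        if mapped and _ZONE_PRIORITY[mapped] < _ZONE_PRIORITY[here]:
            here = mapped
        if tag == "a":
            href = el.get("href")
            if href:
                doc.links.append(href)
        if el.text:
            doc.zones[here].extend(tokenize(el.text))
        for child in el:
            walk(child, here)
            # tail text belongs to the enclosing element's zone
            if child.tail:
                doc.zones[here].extend(tokenize(child.tail))

    walk(root, "body")
    return doc


def load_corpus(manifest_path) -> list[Document]:
    """Read a corpus directory via its TSV manifest.

    The manifest has columns ``doc_id, url, source, path`` with paths
    relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    docs: list[Document] = []
    with open(manifest_path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            html = (manifest_path.parent / row["path"]).read_text(encoding="utf-8")
            docs.append(
                parse_html_document(html, url=row["url"], source=row["source"],
                                    doc_id=row["doc_id"])
            )
    return docs


@dataclass
class InvertedIndex:
    """Word -> per-document, per-zone posting counts."""

    postings: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    doc_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def doc_count(self) -> int:
        return len(self.doc_lengths)

    @classmethod
    def build(cls, documents: Iterable[Document]) -> "InvertedIndex":
        index = cls()
        for doc in documents:
            index.add(doc)
        return index

    def add(self, doc: Document) -> None:
        if doc.doc_id in self.doc_lengths:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        self._max_raw_cache: dict[str, float] = {}
        self.doc_lengths[doc.doc_id] = doc.raw_length
        for zone in ZONES:
            for word, n in Counter(t.text for t in doc.zones[zone]).items():
                self.postings.setdefault(word, {}).setdefault(doc.doc_id, {})[zone] = n

    def tf(self, term: str, doc_id: str) -> int:
        return sum(self.postings.get(term.lower(), {}).get(doc_id, {}).values())

    def df(self, term: str) -> int:
        return len(self.postings.get(term.lower(), {}))

    def idf(self, term: str) -> float:
        return 1.0 + math.log(self.doc_count / (self.df(term) + 1))

    def raw_keyword_score(self, term: str, doc_id: str) -> float:
        """Classic practical TF-IDF: sqrt(tf) * idf^2 * length norm."""
        tf = self.tf(term, doc_id)
        if tf == 0:
            return 0.0
        length = max(1, self.doc_lengths[doc_id])
        return math.sqrt(tf) * self.idf(term) ** 2 / math.sqrt(length)

    def keyword_score(self, term: str, doc_id: str) -> float:
        """The PP component: raw TF-IDF normalized by the corpus maximum
        for the term, so PP is in [0, 1] (0 if the term is absent
        everywhere)."""
        term = term.lower()
        raw = self.raw_keyword_score(term, doc_id)
        if raw == 0.0:
            return 0.0
        cache = getattr(self, "_max_raw_cache", None)
        if cache is None:
            cache = self._max_raw_cache = {}
        best = cache.get(term)
        if best is None:
            best = cache[term] = max(
                self.raw_keyword_score(term, d) for d in self.postings[term]
            )
        return raw / best

    # -- persistence -----------------------------------------------------

    def dump(self, path) -> None:
        """Persist as versioned JSON-lines."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"format": "ontoseek-index", "version": 1}) + "\n")
            for doc_id in sorted(self.doc_lengths):
                fh.write(json.dumps({"doc": doc_id, "len": self.doc_lengths[doc_id]}) + "\n")
            for word in sorted(self.postings):
                fh.write(json.dumps({"word": word, "postings": self.postings[word]},
                                    sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "InvertedIndex":
        index = cls()
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "ontoseek-index":
                raise ValueError(f"{path}: not an index file")
            for line in fh:
                rec = json.loads(line)
                if "doc" in rec:
                    index.doc_lengths[rec["doc"]] = rec["len"]
                else:
                    index.postings[rec["word"]] = rec["postings"]
        return index


def tag_field_score(doc: Document, term: str,
                    zone_weights: dict[str, float] | None = None) -> float:
    """The PT component: weighted relative frequency of a term across the
    five tag zones, capped at 1.

    PT_raw = sum_z w_z * tf(term, z) / max(1, |z|); PT = min(1, PT_raw / sum_z w_z).
    """
    weights = DEFAULT_ZONE_WEIGHTS if zone_weights is None else zone_weights
    missing = [z for z in ZONES if z not in weights]
    if missing:
        raise ValueError(f"zone weights missing for {missing}")
    raw = sum(
        weights[z] * doc.term_frequency(term, z) / max(1, len(doc.zones[z]))
        for z in ZONES
    )
    return min(1.0, raw / sum(weights[z] for z in ZONES))
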