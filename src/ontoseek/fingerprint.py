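"""Fuzzy digital signatures and similarity clustering of documents.

Each document is summarized as a binary vector over a *descriptive word
set*: bit i is set when the relative frequency of word i in the document
exceeds a per-word threshold b(i). Signatures with three or fewer set bits
are excluded from clustering. Similarity between two signatures is the
normalized Levenshtein distance over their bit strings; two documents are
deemed similar when it does not exceed 10%, and clusters are the connected
components of the similarity relation within each data source.
"""

from __future__ import annotations

import json
import logging
import math
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx

from .corpus import Document

log = logging.getLogger(__name__)

#: Minimum number of set bits for a signature to take part in clustering.
MIN_SET_BITS = 4


class EmptyLexiconError(ValueError):
    """No descriptive words could be selected from the corpus."""


@dataclass
class DescriptiveLexicon:
    """The ordered descriptive word set with per-word thresholds.

    ``words[i]`` has relative-frequency cutoff ``thresholds[i]`` (in (0, 1])
    and stability score ``quality[i]``; low-complexity words never appear.
    """

    words: list[str]
    thresholds: list[float]
    quality: list[float]

    def __len__(self) -> int:
        return len(self.words)

    def dump(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tb\tquality\n")
            for w, b, q in zip(self.words, self.thresholds, self.quality):
                fh.write(f"{w}\t{b!r}\t{q!r}\n")

    @classmethod
    def load(cls, path) -> "DescriptiveLexicon":
        words, thresholds, quality = [], [], []
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                w, b, q = line.rstrip("\n").split("\t")
                words.append(w)
                thresholds.append(float(b))
                quality.append(float(q))
        return cls(words, thresholds, quality)


@dataclass
class Signature:
    """Binary fingerprint of one document over the lexicon."""

    doc_id: str
    bits: tuple[int, ...]

    @property
    def n_set(self) -> int:
        return sum(self.bits)

    @property
    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


@dataclass
class DocumentCluster:
    source: str
    members: list[str]


def _relative_frequencies(doc: Document) -> dict[str, float]:
    length = doc.raw_length
    if length == 0:
        return {}
    counts: dict[str, int] = defaultdict(int)
    for tok in doc.all_tokens():
        counts[tok.text] += 1
    return {w: n / length for w, n in counts.items()}


def _bit(rel_freq: Mapping[str, float], word: str, b: float) -> int:
    return 1 if rel_freq.get(word, 0.0) > b else 0


def _word_stats(documents: Sequence[Document]):
    """Per-word positive relative frequencies and candidate vocabulary."""
    rel = [_relative_frequencies(d) for d in documents]
    vocab: set[str] = set()
    for doc in documents:
        for tok in doc.all_tokens():
            if not tok.is_low_complexity:
                vocab.add(tok.text)
    return rel, sorted(vocab)


def _just_below(value: float) -> float:
    # the signature rule is strictly "rel freq > b(i)"; nudging b(i) one ulp
    # below the percentile value lets the document sitting exactly at the
    # percentile set its bit
    return math.nextafter(value, 0.0)


def _thresholds_at(rel, vocab, percentile: float) -> dict[str, float]:
    """b(i) just below a given percentile of the positive relative
    frequencies."""
    out = {}
    for w in vocab:
        pos = sorted(r[w] for r in rel if w in r)
        if not pos:
            continue
        idx = min(len(pos) - 1, int(percentile * len(pos)))
        out[w] = _just_below(pos[idx])
    return out


def _median_positive(rel, vocab) -> dict[str, float]:
    out = {}
    for w in vocab:
        pos = [r[w] for r in rel if w in r]
        if pos:
            out[w] = _just_below(statistics.median(pos))
    return out


def select_descriptive_words(documents: Sequence[Document],
                             coverage_target: float = 0.95,
                             max_n: int = 512) -> DescriptiveLexicon:
    """Build the descriptive word set by quality-weighted greedy coverage.

    b(i) is the median of word i's positive relative frequencies across
    documents (so roughly half the documents containing the word set its
    bit). Word quality is the stability of that bit within data sources:
    1 minus the mean within-source variance. Words are added greedily by
    (newly covered documents x quality) until ``coverage_target`` of
    documents carry at least one set bit or ``max_n`` words are chosen;
    ties break lexicographically. If the median thresholds cannot reach the
    coverage target, b(i) is relaxed to the 25th percentile and the
    selection redone.
    """
    docs = list(documents)
    if not docs:
        raise EmptyLexiconError("empty corpus")
    rel, vocab = _word_stats(docs)
    if not vocab:
        raise EmptyLexiconError(
            "corpus contains only low-complexity words; no lexicon possible"
        )

    def build(thresholds: dict[str, float]):
        # bit matrix: word -> set of doc indices with the bit set
        bit_docs = {
            w: {i for i, r in enumerate(rel) if _bit(r, w, b)}
            for w, b in thresholds.items()
        }
        # quality: 1 - mean within-source variance of the bit
        by_source: dict[str, list[int]] = defaultdict(list)
        for i, doc in enumerate(docs):
            by_source[doc.source].append(i)
        quality = {}
        for w, covered in bit_docs.items():
            variances = []
            for idxs in by_source.values():
                bits = [1 if i in covered else 0 for i in idxs]
                variances.append(statistics.pvariance(bits) if len(bits) > 1 else 0.0)
            quality[w] = 1.0 - (sum(variances) / len(variances))
        # greedy max coverage
        chosen: list[str] = []
        covered_docs: set[int] = set()
        remaining = dict(bit_docs)
        target = coverage_target * len(docs)
        while remaining and len(chosen) < max_n and len(covered_docs) < target:
            best_word, best_score = None, -1.0
            for w in sorted(remaining):
                score = len(remaining[w] - covered_docs) * quality[w]
                if score > best_score:
                    best_word, best_score = w, score
            if best_word is None or best_score <= 0.0:
                break
            chosen.append(best_word)
            covered_docs |= remaining.pop(best_word)
        return chosen, covered_docs, quality

    thresholds = _median_positive(rel, vocab)
    chosen, covered, quality = build(thresholds)
    if len(covered) < coverage_target * len(docs):
        log.info(
            "median thresholds cover %d/%d documents; relaxing b(i) to the "
            "25th percentile", len(covered), len(docs),
        )
        thresholds = _thresholds_at(rel, vocab, 0.25)
        chosen, covered, quality = build(thresholds)
    if not chosen:
        raise EmptyLexiconError("greedy selection produced an empty lexicon")
    return DescriptiveLexicon(
        words=chosen,
        thresholds=[thresholds[w] for w in chosen],
        quality=[quality[w] for w in chosen],
    )


def compute_signature(lexicon: DescriptiveLexicon, doc: Document) -> Signature | None:
    """Binary signature of a document, or ``None`` when excluded.

    Bit i is set iff the relative frequency of word i exceeds b(i).
    Signatures with three or fewer set bits are excluded from clustering.
    """
    rel = _relative_frequencies(doc)
    bits = tuple(
        _bit(rel, w, b) for w, b in zip(lexicon.words, lexicon.thresholds)
    )
    sig = Signature(doc.doc_id, bits)
    if sig.n_set < MIN_SET_BITS:
        return None
    return sig


def normalized_levenshtein(a: Sequence | str, b: Sequence | str) -> float:
    """Unit-cost edit distance divided by the longer length; in [0, 1].

    Accepts strings or 0/1 bit sequences.
    """
    sa = _as_string(a)
    sb = _as_string(b)
    if not sa or not sb:
        raise ValueError("normalized_levenshtein requires non-empty sequences")
    dist = edlib.align(sa, sb, task="distance")["editDistance"]
    return dist / max(len(sa), len(sb))


def _as_string(seq) -> str:
    if isinstance(seq, str):
        return seq
    if isinstance(seq, Signature):
        return seq.bitstring
    return "".join("1" if int(x) else "0" for x in seq)


def cluster_documents(signatures: Mapping[str, Signature | None],
                      sources: Mapping[str, str],
                      threshold: float = 0.10,
                      rl: Mapping[str, float] | None = None,
                      ) -> list[DocumentCluster]:
    """Group documents by source, then by signature similarity.

    Within each source, documents whose signatures differ by at most
    ``threshold`` (normalized Levenshtein, boundary inclusive) are linked;
    clusters are the connected components. Excluded documents (``None``
    signatures) become singleton clusters appended at the end. Clusters are
    ordered by their best member's relevance (when ``rl`` is given),
    members likewise; without relevance scores the order falls back to
    doc_id.
    """
    rl = rl or {}

    def doc_key(doc_id: str):
        return (-rl.get(doc_id, 0.0), doc_id)

    retained = {d: s for d, s in signatures.items() if s is not None}
    by_source: dict[str, list[str]] = defaultdict(list)
    for doc_id in retained:
        by_source[sources[doc_id]].append(doc_id)

    clusters: list[DocumentCluster] = []
    for source in sorted(by_source):
        ids = sorted(by_source[source])
        g = nx.Graph()
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if normalized_levenshtein(retained[a], retained[b]) <= threshold:
                    g.add_edge(a, b)
        for comp in nx.connected_components(g):
            members = sorted(comp, key=doc_key)
            clusters.append(DocumentCluster(source, members))
    clusters.sort(key=lambda c: doc_key(c.members[0]))

    excluded = sorted(
        (d for d, s in signatures.items() if s is None), key=doc_key
    )
    clusters.extend(DocumentCluster(sources[d], [d]) for d in excluded)
    return clusters


def export_clusters(clusters: Iterable[DocumentCluster], path) -> None:
    """Persist clusters as JSON-lines (source, member doc_ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in clusters:
            fh.write(json.dumps({"source": c.source, "members": c.members}) + "\n")
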