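"""Relevance fusion and the query path.

The relevance of document X to ontology term A is the weighted sum

    RL(X, A) = K1*PO(A) + K2*PP(X) + K3*PT(X) + K4*PR(X)

with empirical coefficients K1=0.2, K2=0.5, K3=0.4, K4=0.8. PO is the
term's frequency within its source ontology, PP the corpus-normalized
TF-IDF keyword score, PT the weighted tag-field score, and PR the
normalized PageRank of the document. Each component lies in [0, 1], so RL
with default weights lies in [0, 1.9].

A query is first mapped to ontology terms; every document containing a
token of a matched term is scored against each such term and ranked by its
best RL. Retrieval is capped at the top 1000 documents and batch search at
1000 genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
from urllib.parse import urlparse

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import XSD

from .config import EngineConfig
from .corpus import Document, InvertedIndex, tag_field_score, tokenize
from .linkgraph import LinkGraph, PageRankResult, build_link_graph, pagerank
from .ontology import OntologyGraph, OntologyTerm

log = logging.getLogger(__name__)

ONTOSEEK_NS = Namespace("https://ontoseek.dev/ns#")


@dataclass(frozen=True)
class ScoreWeights:
    """The four empirical fusion coefficients."""

    k1: float = 0.2
    k2: float = 0.5
    k3: float = 0.4
    k4: float = 0.8

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")

    @classmethod
    def from_config(cls, config: EngineConfig) -> "ScoreWeights":
        return cls(config.k1, config.k2, config.k3, config.k4)


@dataclass(frozen=True)
class ComponentScores:
    """Unit-interval component scores (PO, PP, PT, PR)."""

    po: float
    pp: float
    pt: float
    pr: float

    def __post_init__(self) -> None:
        for name in ("po", "pp", "pt", "pr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"component {name}={v} outside [0, 1]")


def relevance_score(weights: ScoreWeights, c: ComponentScores) -> float:
    """RL(X, A): the exact weighted sum of the four components."""
    return weights.k1 * c.po + weights.k2 * c.pp + weights.k3 * c.pt + weights.k4 * c.pr


@dataclass
class SearchResult:
    doc_id: str
    url: str
    term_id: str
    rl: float
    components: ComponentScores
    group: str | None = None  # "exact" | "relevant", set by group_results


class SearchEngine:
    """Index + link graph + ontology wired together for querying."""

    def __init__(self, documents: Sequence[Document], ontology: OntologyGraph,
                 config: EngineConfig | None = None):
        self.config = config or EngineConfig()
        self.documents = {d.doc_id: d for d in documents}
        if len(self.documents) != len(documents):
            raise ValueError("duplicate doc_ids in corpus")
        self.ontology = ontology
        self.index = InvertedIndex.build(documents)
        self.link_graph: LinkGraph = build_link_graph(documents)
        self.pagerank: PageRankResult = pagerank(
            self.link_graph, damping=self.config.damping
        )
        self.weights = ScoreWeights.from_config(self.config)

    # -- scoring ---------------------------------------------------------

    def _term_words(self, term: OntologyTerm) -> list[str]:
        return [t.text for t in tokenize(term.label)]

    def score_document(self, doc: Document, term: OntologyTerm) -> ComponentScores:
        """Component scores of one (document, term) pair. Multi-word term
        labels score as the mean over their word tokens."""
        words = self._term_words(term)
        po = self.ontology.term_frequency(term.term_id)
        pp = sum(self.index.keyword_score(w, doc.doc_id) for w in words) / len(words)
        pt = sum(
            tag_field_score(doc, w, self.config.zone_weights) for w in words
        ) / len(words)
        pr = self.pagerank.normalized[doc.doc_id]
        return ComponentScores(po, pp, pt, pr)

    # -- querying --------------------------------------------------------

    def execute_query(self, query: str, k: int | None = None) -> list[SearchResult]:
        """Rank documents for a free-text query.

        The query maps to ontology terms; a document qualifies if it
        contains at least one word of a matched term and is scored by its
        best term. Results are sorted by RL descending (ties by doc_id) and
        capped at ``k`` (default: the configured top-1000).
        """
        if not query.strip():
            raise ValueError("empty query")
        k = self.config.top_k if k is None else k
        terms = self.ontology.map_query_to_terms(query)
        if not terms:
            return []
        best_by_doc: dict[str, SearchResult] = {}
        for term in terms:
            candidates: set[str] = set()
            for w in self._term_words(term):
                candidates.update(self.index.postings.get(w, ()))
            for doc_id in candidates:
                doc = self.documents[doc_id]
                c = self.score_document(doc, term)
                rl = relevance_score(self.weights, c)
                best = best_by_doc.get(doc_id)
                if best is None or rl > best.rl:
                    best_by_doc[doc_id] = SearchResult(
                        doc.doc_id, doc.url, term.term_id, rl, c
                    )
        results = list(best_by_doc.values())
        results.sort(key=lambda r: (-r.rl, r.doc_id))
        return results[:k]

    def batch_query(self, gene_list: Sequence[str],
                    limit: int | None = None) -> dict[str, list[SearchResult]]:
        """Per-gene retrieval for a list of identifiers.

        The list is deduplicated preserving order; deduplicated lists longer
        than the limit (default 1000) are rejected outright rather than
        truncated.
        """
        limit = self.config.batch_limit if limit is None else limit
        genes = list(dict.fromkeys(g.strip() for g in gene_list if g.strip()))
        if not genes:
            raise ValueError("empty gene list")
        if len(genes) > limit:
            raise ValueError(
                f"batch search is limited to {limit} genes; got {len(genes)}"
            )
        return {g: self.execute_query(g) for g in genes}


def parse_gene_list(text: str) -> list[str]:
    """One identifier per line; blank lines ignored; order preserved."""
    return [line.strip() for line in text.splitlines() if line.strip()]


def group_results(results: Iterable[SearchResult], query: str,
                  cooccurrence: Mapping[str, Sequence[str]],
                  synonyms: Mapping[str, Sequence[str]] | None = None,
                  ) -> list[SearchResult]:
    """Split results into "exact" and "relevant" groups.

    A result is *exact* when an entity of its document has a name or
    synonym containing the query term (case-insensitive substring), and
    *relevant* when its document's record merely co-occurs with the query
    term (other entities present). Documents with no associated entities
    are omitted. Exact results are listed before relevant ones, preserving
    rank order within each group.
    """
    q = query.strip().lower()
    synonyms = synonyms or {}
    exact: list[SearchResult] = []
    relevant: list[SearchResult] = []
    for res in results:
        entities = cooccurrence.get(res.doc_id, ())
        if not entities:
            continue
        names: list[str] = []
        for ent in entities:
            names.append(ent)
            names.extend(synonyms.get(ent, ()))
        if any(q in name.lower() for name in names):
            res.group = "exact"
            exact.append(res)
        else:
            res.group = "relevant"
            relevant.append(res)
    return exact + relevant


def _valid_iri(url: str) -> bool:
    parsed = urlparse(url)
    return bool(parsed.scheme) and bool(parsed.netloc) and " " not in url


def export_results_rdf(results: Sequence[SearchResult]) -> str:
    """Serialize results as N-Triples, one subject per result document.

    Three predicates per subject: relevance score (typed double literal),
    matched ontology term, and group label (or "ungrouped"). Triples are
    emitted in sorted order for determinism.
    """
    if not results:
        raise ValueError("no results to export")
    g = Graph()
    for res in results:
        if not _valid_iri(res.url):
            log.warning("skipping result %s: invalid IRI %r", res.doc_id, res.url)
            continue
        subject = URIRef(res.url)
        g.add((subject, ONTOSEEK_NS.relevanceScore,
               Literal(res.rl, datatype=XSD.double)))
        g.add((subject, ONTOSEEK_NS.matchedTerm, Literal(res.term_id)))
        g.add((subject, ONTOSEEK_NS.resultGroup, Literal(res.group or "ungrouped")))
    lines = g.serialize(format="nt").splitlines()
    return "\n".join(sorted(line for line in lines if line.strip())) + "\n"
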