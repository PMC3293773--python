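"""Ontology store: a DAG of terms with typed relations.

Terms carry a label, synonyms and a source-ontology tag. The graph supports
three relation kinds (``is-a``, ``has-a``, ``part-of``), term-frequency
scoring within a source ontology (the PO component of the relevance score),
and mapping of free-text queries to the most closely connected terms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx

log = logging.getLogger(__name__)

#: Allowed relation kinds, in tie-breaking priority order (highest first).
RELATIONS = ("is-a", "part-of", "has-a")

_RELATION_RANK = {rel: i for i, rel in enumerate(RELATIONS)}

_WORD_RE = re.compile(r"[a-z0-9]+(?:\.[a-z0-9]+)*")


class OntologyError(ValueError):
    """Malformed ontology input (parse failure, cycle, bad relation)."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    Parameters
    ----------
    term_id:
        Opaque identifier, unique within a graph.
    label:
        Human-readable name; must be non-empty.
    synonyms:
        Alternative names, e.g. gene aliases.
    ontology_source:
        Which source ontology the term belongs to; term frequency is
        computed within this scope.
    """

    term_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    ontology_source: str = "default"

    def __post_init__(self) -> None:
        if not self.label:
            raise OntologyError(f"term {self.term_id!r} has an empty label")

    def name_tokens(self) -> frozenset[str]:
        """Lower-cased word tokens of the label and all synonyms."""
        words: set[str] = set()
        for text in (self.label, *self.synonyms):
            words.update(_WORD_RE.findall(text.lower()))
        return frozenset(words)


@dataclass
class OntologyGraph:
    """Directed acyclic graph of :class:`OntologyTerm` nodes.

    Edges point child -> parent and carry one of the three relation kinds.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_term(self, term: OntologyTerm) -> None:
        if term.term_id in self.terms:
            raise OntologyError(f"duplicate term id {term.term_id!r}")
        self.terms[term.term_id] = term
        self.graph.add_node(term.term_id)

    def add_edge(self, child_id: str, parent_id: str, relation: str) -> None:
        if relation not in _RELATION_RANK:
            raise OntologyError(f"unknown relation {relation!r}")
        for tid in (child_id, parent_id):
            if tid not in self.terms:
                raise OntologyError(f"edge endpoint {tid!r} is not a known term")
        self.graph.add_edge(child_id, parent_id, relation=relation)

    def validate(self) -> None:
        """Reject cyclic graphs, naming one offending edge."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            u, v = cycle[0][0], cycle[0][1]
            raise OntologyError(f"ontology contains a cycle through edge {u!r} -> {v!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, d["relation"]) for u, v, d in self.graph.edges(data=True)]

    # -- scoring ---------------------------------------------------------

    def term_frequency(self, term_id: str) -> float:
        """Frequency PO of a term within its source ontology.

        The fraction of terms in the same source whose label or synonyms
        contain this term's label (case-insensitive substring). Always in
        (0, 1]: the term matches itself.
        """
        if term_id not in self.terms:
            raise KeyError(f"term {term_id!r} not in graph")
        term = self.terms[term_id]
        needle = term.label.lower()
        peers = [t for t in self.terms.values() if t.ontology_source == term.ontology_source]
        hits = sum(
            1
            for t in peers
            if any(needle in text.lower() for text in (t.label, *t.synonyms))
        )
        return hits / len(peers)

    # -- query mapping ---------------------------------------------------

    def matches_query(self, term_id: str, query: str) -> bool:
        """Whole-token containment: every query word occurs among the
        term's label+synonym tokens (case-insensitive)."""
        words = _WORD_RE.findall(query.lower())
        if not words:
            return False
        tokens = self.terms[term_id].name_tokens()
        return all(w in tokens for w in words)

    def map_query_to_terms(self, query: str, max_hops: int = 2) -> list[OntologyTerm]:
        """Rank the ontology nodes most closely connected with a query.

        Exact label/synonym matches come first (hop 0); the neighbourhood
        within ``max_hops`` undirected edges follows. Within a hop, ties
        break by relation priority (is-a > part-of > has-a, using the best
        edge on a shortest path), then PO descending, then term id.
        """
        if not query.strip():
            raise ValueError("query is empty")
        seeds = sorted(tid for tid in self.terms if self.matches_query(tid, query))
        if not seeds:
            return []

        undirected = self.graph.to_undirected(as_view=True)
        hop = {tid: 0 for tid in seeds}
        best_rel = {tid: -1 for tid in seeds}  # -1: matched directly, outranks any edge
        frontier = list(seeds)
        for h in range(1, max_hops + 1):
            nxt: list[str] = []
            for tid in frontier:
                for nbr in undirected.neighbors(tid):
                    rel = _RELATION_RANK[undirected.edges[tid, nbr]["relation"]]
                    if nbr not in hop:
                        hop[nbr] = h
                        best_rel[nbr] = rel
                        nxt.append(nbr)
                    elif hop[nbr] == h and rel < best_rel[nbr]:
                        best_rel[nbr] = rel
            frontier = nxt

        po = {tid: self.term_frequency(tid) for tid in hop}
        ranked = sorted(hop, key=lambda t: (hop[t], best_rel[t], -po[t], t))
        return [self.terms[t] for t in ranked]


# -- loading -------------------------------------------------------------

_SYNONYM_QUOTED_RE = re.compile(r'^"(.*)"')


def _parse_obo_flat(lines: list[str]) -> OntologyGraph:
    graph = OntologyGraph()
    edges: list[tuple[str, str, str, int]] = []
    stanza: dict[str, list[str]] | None = None
    stanza_line = 0

    def flush() -> None:
        if stanza is None:
            return
        if "id" not in stanza or "name" not in stanza:
            raise OntologyError(
                f"[Term] stanza starting at line {stanza_line} lacks id: or name:"
            )
        tid = stanza["id"][0]
        synonyms = []
        for raw in stanza.get("synonym", []):
            m = _SYNONYM_QUOTED_RE.match(raw)
            synonyms.append(m.group(1) if m else raw)
        source = stanza.get("ontology", ["default"])[0]
        graph.add_term(
            OntologyTerm(tid, stanza["name"][0], tuple(synonyms), source)
        )
        for parent in stanza.get("is_a", []):
            edges.append((tid, parent.split("!")[0].strip(), "is-a", stanza_line))
        for raw in stanza.get("relationship", []):
            parts = raw.split()
            if len(parts) < 2:
                raise OntologyError(
                    f"malformed relationship line in stanza at line {stanza_line}: {raw!r}"
                )
            rel = parts[0].replace("_", "-")
            edges.append((tid, parts[1], rel, stanza_line))

    for lineno, raw in enumerate(lines, 1):
        line = raw.split("!")[0].strip() if not raw.lstrip().startswith("!") else ""
        if not line:
            continue
        if line == "[Term]":
            flush()
            stanza = {}
            stanza_line = lineno
            continue
        if line.startswith("["):  # non-Term stanza: skip until next [Term]
            flush()
            stanza = None
            continue
        if ":" not in line:
            raise OntologyError(f"line {lineno}: expected 'key: value', got {line!r}")
        if stanza is None:  # header line outside any [Term] stanza
            continue
        key, _, value = line.partition(":")
        stanza.setdefault(key.strip(), []).append(value.strip())
    flush()

    for child, parent, rel, lineno in edges:
        try:
            graph.add_edge(child, parent, rel)
        except OntologyError as exc:
            raise OntologyError(f"stanza at line {lineno}: {exc}") from exc
    return graph


def _parse_edge_tsv(lines: list[str]) -> OntologyGraph:
    graph = OntologyGraph()
    edges: list[tuple[str, str, str, int]] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise OntologyError(
                f"line {lineno}: expected child<TAB>relation<TAB>parent, got {line!r}"
            )
        child, rel, parent = parts
        for tid in (child, parent):
            if tid not in graph:
                graph.add_term(OntologyTerm(tid, tid))
        edges.append((child, parent, rel, lineno))
    for child, parent, rel, lineno in edges:
        try:
            graph.add_edge(child, parent, rel)
        except OntologyError as exc:
            raise OntologyError(f"line {lineno}: {exc}") from exc
    return graph


def load_ontology(path, format: str = "obo-flat") -> OntologyGraph:
    """Load an ontology from disk and validate it.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"obo-flat"`` ([Term] stanzas with id/name/synonym/is_a/relationship
        lines) or ``"edge-tsv"`` (child<TAB>relation<TAB>parent rows).
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if format == "obo-flat":
        graph = _parse_obo_flat(lines)
    elif format == "edge-tsv":
        graph = _parse_edge_tsv(lines)
    else:
        raise ValueError(f"unknown ontology format {format!r}")
    if len(graph) == 0:
        log.warning("ontology file %s contains no terms", path)
    graph.validate()
    return graph
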