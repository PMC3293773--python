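"""Hyperlink graph of a corpus and its PageRank scores (the PR component).

PageRank is computed by power iteration with uniform teleportation and
uniform redistribution of dangling-node mass, converging when the L1 change
between iterations drops below ``tol``. Scores sum to one; the normalized
PR used in relevance fusion divides by the corpus maximum so PR is in
(0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .corpus import Document

log = logging.getLogger(__name__)


@dataclass
class LinkGraph:
    nodes: list[str] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def add_node(self, doc_id: str) -> None:
        if doc_id not in self._index:
            self._index[doc_id] = len(self.nodes)
            self.nodes.append(doc_id)

    def add_edge(self, src: str, dst: str) -> None:
        if src not in self._index or dst not in self._index:
            raise ValueError(f"edge ({src!r}, {dst!r}) references an unknown node")
        if src == dst:
            return  # self-links carry no endorsement
        self.edges.add((src, dst))

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def out_degree(self, doc_id: str) -> int:
        return sum(1 for s, _ in self.edges if s == doc_id)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for src, dst in sorted(self.edges):
                fh.write(f"{src}\t{dst}\n")


def build_link_graph(documents: Iterable[Document]) -> LinkGraph:
    """One node per document, one edge per hyperlink whose target URL
    resolves to a document in the corpus; external links are dropped
    (counted in the log)."""
    docs = list(documents)
    graph = LinkGraph()
    url_to_id = {}
    for doc in docs:
        graph.add_node(doc.doc_id)
        if doc.url:
            url_to_id[doc.url] = doc.doc_id
    external = 0
    for doc in docs:
        for href in doc.links:
            target = url_to_id.get(href)
            if target is None:
                external += 1
            else:
                graph.add_edge(doc.doc_id, target)
    if external:
        log.info("dropped %d unresolvable/external links", external)
    return graph


@dataclass
class PageRankResult:
    scores: dict[str, float]        # stationary distribution, sums to 1
    normalized: dict[str, float]    # scores / max(scores), the PR component
    converged: bool
    n_iter: int


def pagerank(graph: LinkGraph, damping: float = 0.85, tol: float = 1e-9,
             max_iter: int = 200) -> PageRankResult:
    if not graph.nodes:
        raise ValueError("link graph is empty")
    n = len(graph.nodes)
    index = {node: i for i, node in enumerate(graph.nodes)}

    out_links: list[list[int]] = [[] for _ in range(n)]
    for src, dst in graph.edges:
        out_links[index[src]].append(index[dst])

    x = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nxt = np.zeros(n)
        dangling_mass = 0.0
        for i, targets in enumerate(out_links):
            if targets:
                share = x[i] / len(targets)
                for j in targets:
                    nxt[j] += share
            else:
                dangling_mass += x[i]
        nxt = damping * (nxt + dangling_mass / n) + (1.0 - damping) / n
        if np.abs(nxt - x).sum() < tol:
            x = nxt
            converged = True
            break
        x = nxt
    if not converged:
        log.warning("pagerank did not converge in %d iterations", max_iter)
    scores = {node: float(x[index[node]]) for node in graph.nodes}
    top = max(scores.values())
    normalized = {node: s / top for node, s in scores.items()}
    return PageRankResult(scores, normalized, converged, it)
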