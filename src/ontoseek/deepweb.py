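"""Iterative form-probing keyword expansion over an abstract page provider.

Content behind web forms cannot be reached by following hyperlinks; instead
a form endpoint is probed with candidate keywords. Keywords found on each
retrieved page (by matching page tokens against ontology term labels and
synonyms) are queued and probed in turn, breadth-first, until no new
keywords or pages appear. No network code lives here: a provider is any
deterministic callable from keyword to page text, and a file-system-backed
provider ships for demos.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .corpus import tokenize
from .ontology import OntologyGraph

log = logging.getLogger(__name__)


@dataclass
class FormEndpoint:
    """A single-slot form URL template plus its page provider.

    ``provider(keyword)`` returns the page text for a keyword, or the empty
    string when the form yields no result; it must be deterministic.
    """

    url_pattern: str
    provider: Callable[[str], str]

    def url_for(self, keyword: str) -> str:
        return self.url_pattern.format(keyword=keyword)


def filesystem_provider(directory) -> Callable[[str], str]:
    """Serve pages from a directory of ``<keyword>.txt`` files (a fixture
    web site); unknown keywords yield an empty page."""
    directory = Path(directory)

    def provider(keyword: str) -> str:
        page = directory / f"{keyword.lower()}.txt"
        return page.read_text(encoding="utf-8") if page.exists() else ""

    return provider


@dataclass
class CrawlState:
    tried: set[str] = field(default_factory=set)
    pending: deque[str] = field(default_factory=deque)
    retrieved: dict[str, str] = field(default_factory=dict)
    rounds: int = 0
    log_records: list[dict] = field(default_factory=list)

    def report(self, path) -> None:
        """Crawl report as JSON-lines (keyword, round, outcome)."""
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.log_records:
                fh.write(json.dumps(rec) + "\n")


def extract_candidate_keywords(page: str, ontology: OntologyGraph) -> set[str]:
    """Page tokens that match an ontology term label or synonym
    (case-insensitive), deduplicated and lower-cased."""
    names: set[str] = set()
    for term in ontology.terms.values():
        names.add(term.label.lower())
        names.update(s.lower() for s in term.synonyms)
    return {tok.text for tok in tokenize(page) if tok.text in names}


def form_returns_valid_results(endpoint: FormEndpoint, keyword: str,
                               ontology: OntologyGraph) -> bool:
    """The initial form test: a probe is valid when it returns a non-empty
    page containing at least one ontology keyword."""
    page = endpoint.provider(keyword)
    return bool(page.strip()) and bool(extract_candidate_keywords(page, ontology))


def crawl_to_fixpoint(endpoint: FormEndpoint, seeds: Iterable[str],
                      ontology: OntologyGraph, max_rounds: int = 100
                      ) -> CrawlState:
    """Breadth-first keyword expansion until no new pages or keywords.

    Each keyword is probed exactly once; non-empty pages are stored and
    their unseen candidate keywords enqueued (lexicographic order within a
    round). Stops when the queue empties or after ``max_rounds`` rounds.
    """
    seed_list = sorted({s.strip().lower() for s in seeds if s.strip()})
    if not seed_list:
        raise ValueError("crawl requires at least one seed keyword")
    state = CrawlState(pending=deque(seed_list))
    queued = set(seed_list)
    while state.pending and state.rounds < max_rounds:
        state.rounds += 1
        frontier = list(state.pending)
        state.pending.clear()
        new_keywords: set[str] = set()
        for keyword in frontier:
            state.tried.add(keyword)
            page = endpoint.provider(keyword)
            if not page.strip():
                state.log_records.append(
                    {"keyword": keyword, "round": state.rounds, "outcome": "empty"}
                )
                continue
            state.retrieved[keyword] = page
            found = extract_candidate_keywords(page, ontology)
            new_keywords |= {k for k in found if k not in queued}
            state.log_records.append(
                {"keyword": keyword, "round": state.rounds, "outcome": "page",
                 "extracted": sorted(found)}
            )
        for k in sorted(new_keywords):
            state.pending.append(k)
            queued.add(k)
    if state.pending:
        log.warning("crawl stopped at max_rounds=%d with %d keywords pending",
                    max_rounds, len(state.pending))
    return state
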