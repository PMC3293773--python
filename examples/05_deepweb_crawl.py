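"""Iterative form-probing keyword expansion on a fixture site.

Content behind a search form is reached by probing it with keywords and
mining each returned page for new ontology terms to probe next. The
fixture below is a five-keyword site whose pages mention one another;
starting from one seed, the crawl reaches the closure of the mention
graph and stops when no new keywords or pages appear.
"""

from ontoseek import FormEndpoint, crawl_to_fixpoint
from ontoseek.ontology import OntologyGraph, OntologyTerm

keywords = ["tp53", "mdm2", "brca1", "egfr", "kras"]
ontology = OntologyGraph()
for kw in keywords:
    ontology.add_term(OntologyTerm(kw.upper(), kw))

pages = {
    "tp53": "tp53 interacts with mdm2 and regulates brca1",
    "mdm2": "mdm2 ubiquitinates tp53",
    "brca1": "brca1 repair complex, binds egfr in this assay",
    "kras": "kras signaling page (never reached: nothing mentions kras)",
}
endpoint = FormEndpoint("https://db.example.org/gene/?term={keyword}",
                        lambda k: pages.get(k, ""))

state = crawl_to_fixpoint(endpoint, seeds={"tp53"}, ontology=ontology)
print(f"seed: tp53; probe URL example: {endpoint.url_for('tp53')}")
print(f"rounds: {state.rounds}")
print(f"probed keywords: {sorted(state.tried)}")
print(f"retrieved pages: {sorted(state.retrieved)}")
print("\n'egfr' was probed (the ontology knows it) but returned no page;"
      "\n'kras' has a page but is never mentioned, so it is never probed —"
      "\nthe crawl retrieves exactly the mention-graph closure of the seed.")
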