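"""Seeded generators for every input the engine consumes.

Each generator is a pure function of a :class:`FixtureSpec`: the same spec
yields byte-identical outputs, and every generator records the ground truth
needed to score its module (planted term placements, hyperlinks, table
labels, promoter coordinates, the correlated expression block). One global
seed fans out to independent per-generator streams, so modules can
regenerate their inputs without consuming each other's randomness.

Defaults are desk-scale: a 50-term ontology, a 100-document corpus, a
20-gene genome with one 30-bp promoter planted upstream of every gene, and
20 expression experiments of 50 samples with a 5-gene block correlated with
the query gene at r = 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Document, parse_html_document
from .coexpression import ExpressionExperiment
from .ontology import OntologyGraph, OntologyTerm, RELATIONS
from .tables import GeneModel, GenomeStore

# stream ids for per-generator rng fan-out
_STREAMS = {"ontology": 1, "corpus": 2, "genome": 3, "expression": 4}

_HEAD_WORDS = (
    "kinase receptor ligase channel transporter phosphatase protease helicase "
    "polymerase synthase reductase oxidase transferase hydrolase isomerase "
    "cyclase esterase peptidase nuclease integrase"
).split()
_TAIL_WORDS = (
    "alpha beta gamma delta epsilon membrane nuclear cytosolic mitochondrial "
    "ribosomal signaling binding regulatory catalytic inducible conserved"
).split()
_FILLER_WORDS = (
    "protein gene cell pathway expression tumor tissue factor complex domain "
    "binding assay response growth signal receptor variant function motif "
    "promoter enhancer transcript exon intron splice sequence genome clone "
    "marker antibody plasma serum liver brain kidney muscle heart lung "
    "patient cohort control treatment dose inhibitor activator mutation"
).split()
_TISSUES = (
    "breast brain bone marrow fibroblast astrocyte liver lung kidney skin "
    "colon prostate ovary pancreas thymus spleen retina muscle heart"
).split()
_CONDITIONS = (
    "cancer carcinoma lymphoma sarcoma hypoxia inflammation infection "
    "diabetes ischemia fibrosis senescence differentiation proliferation "
    "apoptosis starvation stimulation knockdown overexpression"
).split()


@dataclass
class FixtureSpec:
    """Sizes, planted-structure parameters and the master seed."""

    seed: int = 0
    n_terms: int = 50
    n_documents: int = 100
    n_genes: int = 20
    n_experiments: int = 20
    n_samples: int = 50
    n_planted: int = 5
    n_independent: int = 15
    r_true: float = 0.9
    probe_noise_sd: float = 0.1
    promoter_len: int = 30
    max_promoter_offset: int = 500
    gene_len: int = 1000
    intergenic: int = 2000
    relational_fraction: float = 0.2
    decoy_fraction: float = 0.1
    mean_out_links: float = 2.0
    scale: float = 1.0

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def scaled(self, n: int) -> int:
        return max(1, int(round(n * self.scale)))


# -- ontology --------------------------------------------------------------


def gen_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, str, list[tuple[str, str, str]]]:
    """Random layered DAG of terms; returns (graph, OBO-flat text, truth edges).

    Terms get an is-a parent in an earlier layer plus occasional part-of /
    has-a cross edges, so the graph is acyclic by construction.
    """
    rng = spec.rng("ontology")
    n = spec.scaled(spec.n_terms)
    labels: list[str] = []
    seen: set[str] = set()
    for i in range(n):
        head = _HEAD_WORDS[rng.integers(len(_HEAD_WORDS))]
        tail = _TAIL_WORDS[rng.integers(len(_TAIL_WORDS))]
        label = f"{head} {tail}"
        if label in seen:
            label = f"{label} {i}"
        seen.add(label)
        labels.append(label)

    graph = OntologyGraph()
    truth: list[tuple[str, str, str]] = []
    for i, label in enumerate(labels):
        syns = ()
        if rng.random() < 0.3:
            syns = (f"syn.{i}",)
        graph.add_term(OntologyTerm(f"T{i:04d}", label, syns, "synth"))
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        graph.add_edge(f"T{i:04d}", f"T{parent:04d}", "is-a")
        truth.append((f"T{i:04d}", "is-a", f"T{parent:04d}"))
        if i >= 2 and rng.random() < 0.25:
            other = int(rng.integers(0, i))
            rel = RELATIONS[1 + int(rng.integers(2))]  # part-of or has-a
            if other != parent:
                graph.add_edge(f"T{i:04d}", f"T{other:04d}", rel)
                truth.append((f"T{i:04d}", rel, f"T{other:04d}"))
    graph.validate()

    lines: list[str] = []
    for i, label in enumerate(labels):
        tid = f"T{i:04d}"
        term = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {label}")
        for s in term.synonyms:
            lines.append(f'synonym: "{s}" EXACT []')
        for child, rel, parent in truth:
            if child == tid:
                if rel == "is-a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel.replace('-', '_')} {parent}")
        lines.append(f"ontology: synth")
        lines.append("")
    return graph, "\n".join(lines), truth


# -- corpus ----------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def gen_corpus(spec: FixtureSpec, ontology: OntologyGraph
               ) -> tuple[list[Document], list[dict], dict]:
    """Synthetic HTML corpus with recorded ground truth.

    Each document plants 1-3 ontology term labels into chosen zones with
    controlled counts, carries hyperlinks drawn from a random topology, and
    a stated fraction of documents embeds a relational gene/promoter table
    (or a decoy layout table). Returns (documents, manifest rows, truth).
    """
    rng = spec.rng("corpus")
    n_docs = spec.scaled(spec.n_documents)
    term_ids = sorted(ontology.terms)
    sources = ["alpha.example.org", "beta.example.org", "gamma.example.org"]
    gene_names = [f"GENE{i + 1}" for i in range(spec.n_genes)]

    # link topology: for each doc, ~Poisson(mean_out_links) targets
    links: dict[int, list[int]] = {}
    for i in range(n_docs):
        k = int(rng.poisson(spec.mean_out_links))
        targets = sorted(set(int(t) for t in rng.integers(0, n_docs, size=k)) - {i})
        links[i] = targets

    truth: dict = {"placements": {}, "links": [], "tables": {}}
    documents: list[Document] = []
    manifest: list[dict] = []
    for i in range(n_docs):
        doc_id = f"D{i:04d}"
        url = f"https://{sources[i % len(sources)]}/page/{i}"
        n_terms_here = 1 + int(rng.integers(0, 3))
        planted = [term_ids[int(j)] for j in
                   rng.choice(len(term_ids), size=n_terms_here, replace=False)]
        placements: dict[str, dict[str, int]] = {}
        title_words = [ontology.terms[planted[0]].label]
        placements[planted[0]] = {"title": 1}
        body_parts: list[str] = []
        for tid in planted:
            reps = 1 + int(rng.integers(0, 4))
            body_parts.extend([ontology.terms[tid].label] * reps)
            placements.setdefault(tid, {})
            placements[tid]["body"] = reps
        filler = [
            _FILLER_WORDS[int(j)]
            for j in rng.integers(0, len(_FILLER_WORDS), size=40 + int(rng.integers(0, 40)))
        ]
        rng.shuffle(body_parts)
        body = " ".join(body_parts + filler)

        anchor_html = "".join(
            f'<a href="https://{sources[t % len(sources)]}/page/{t}">related {t}</a> '
            for t in links[i]
        )

        table_html = ""
        roll = rng.random()
        if roll < spec.relational_fraction:
            rows = "".join(
                f"<tr><td>{gene_names[int(g)]}</td><td>{_random_dna(rng, 20)}</td></tr>"
                for g in rng.choice(spec.n_genes, size=4, replace=False)
            )
            table_html = (
                "<table><tr><th>gene</th><th>promoter</th></tr>" + rows + "</table>"
            )
            truth["tables"][doc_id] = "relational"
        elif roll < spec.relational_fraction + spec.decoy_fraction:
            table_html = (
                "<table><tr><td>welcome to the resource</td></tr>"
                "<tr><td>browse the navigation menu</td></tr></table>"
            )
            truth["tables"][doc_id] = "decoy"

        html = (
            f"<html><head><title>{' '.join(title_words)}</title></head><body>"
            f"<h1>{ontology.terms[planted[0]].label} overview</h1>"
            f"<p>{body}</p>{anchor_html}{table_html}</body></html>"
        )
        doc = parse_html_document(html, url=url, source=sources[i % len(sources)],
                                  doc_id=doc_id)
        documents.append(doc)
        manifest.append({"doc_id": doc_id, "url": url,
                         "source": sources[i % len(sources)],
                         "path": f"{doc_id}.html", "html": html})
        truth["placements"][doc_id] = placements
        truth["links"].extend(
            [doc_id, f"D{t:04d}"] for t in links[i]
        )
    return documents, manifest, truth


def write_corpus(manifest: list[dict], outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for row in manifest:
        (outdir / row["path"]).write_text(row["html"], encoding="utf-8")
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\turl\tsource\tpath\n")
        for row in manifest:
            fh.write(f"{row['doc_id']}\t{row['url']}\t{row['source']}\t{row['path']}\n")
    return manifest_path


# -- genome ----------------------------------------------------------------


@dataclass
class PromoterTruth:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    upstream_offset: int


def gen_genome(spec: FixtureSpec
               ) -> tuple[GenomeStore, dict[str, GeneModel], list[PromoterTruth]]:
    """Random genome with genes on both strands and planted promoters.

    Every gene gets one promoter: the genuine genomic subsequence at a
    recorded offset upstream of its transcription start site, so an exact
    upstream scan must recover the recorded coordinates.
    """
    rng = spec.rng("genome")
    n_genes = spec.n_genes
    chrom_len = n_genes * (spec.gene_len + spec.intergenic) + spec.intergenic
    chrom = "chr1"
    sequence = _random_dna(rng, chrom_len)
    genome = GenomeStore({chrom: sequence})

    genes: dict[str, GeneModel] = {}
    truth: list[PromoterTruth] = []
    pos = spec.intergenic
    for i in range(n_genes):
        gene_id = f"GENE{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        start, end = pos, pos + spec.gene_len
        gene = GeneModel(gene_id, chrom, start, end, strand)
        genes[gene_id.lower()] = gene

        offset = int(rng.integers(50, spec.max_promoter_offset))
        plen = spec.promoter_len
        if strand == "+":
            p_start = start - offset - plen
            p_end = p_start + plen
        else:
            p_start = end + offset
            p_end = p_start + plen
        promoter = genome.fetch(chrom, p_start, p_end, strand)
        truth.append(PromoterTruth(gene_id, chrom, p_start, p_end, strand,
                                   promoter, offset))
        pos = end + spec.intergenic
    return genome, genes, truth


def write_genome(genome: GenomeStore, genes: dict[str, GeneModel],
                 truth: list[PromoterTruth], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w", encoding="utf-8") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(outdir / "genes.bed", "w", encoding="utf-8") as fh:
        for gene in genes.values():
            fh.write(f"{gene.chrom}\t{gene.start}\t{gene.end}\t"
                     f"{gene.gene_id}\t0\t{gene.strand}\n")
    with open(outdir / "promoter_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tsequence\tupstream_offset\n")
        for t in truth:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                     f"{t.sequence}\t{t.upstream_offset}\n")


def promoter_table_html(truth: list[PromoterTruth]) -> str:
    """The worked-example input: a two-column gene/promoter HTML table."""
    rows = "".join(
        f"<tr><td>{t.gene_id}</td><td>{t.sequence}</td></tr>" for t in truth
    )
    return ("<html><body><table><tr><th>gene</th><th>promoter</th></tr>"
            + rows + "</table></body></html>")


# -- expression ------------------------------------------------------------


def gen_expression(spec: FixtureSpec
                   ) -> tuple[list[ExpressionExperiment], dict]:
    """Expression experiments with a planted co-expressed block.

    In every experiment the query gene is standard normal; planted genes are
    r_true-correlated with it (plus independent noise); the remaining genes
    are independent noise. Each gene is measured by 1-2 probes with additive
    probe noise. Returns (experiments, truth) where truth names the query,
    planted and independent genes and r_true.
    """
    rng = spec.rng("expression")
    n_exp = spec.scaled(spec.n_experiments)
    query = "QUERY1"
    planted = [f"COEX{i + 1}" for i in range(spec.n_planted)]
    independent = [f"RAND{i + 1}" for i in range(spec.n_independent)]
    r = spec.r_true
    experiments: list[ExpressionExperiment] = []
    for e in range(n_exp):
        n = spec.n_samples
        values: dict[str, np.ndarray] = {}
        q = rng.standard_normal(n)
        values[query] = q
        for g in planted:
            values[g] = r * q + np.sqrt(1 - r * r) * rng.standard_normal(n)
        for g in independent:
            values[g] = rng.standard_normal(n)

        probe_rows: dict[str, np.ndarray] = {}
        probe_to_gene: dict[str, str] = {}
        for g, v in values.items():
            n_probes = 1 + int(rng.integers(0, 2))
            for p in range(n_probes):
                probe = f"{g}_p{p + 1}"
                probe_rows[probe] = v + spec.probe_noise_sd * rng.standard_normal(n)
                probe_to_gene[probe] = g
        df = pd.DataFrame(
            probe_rows, index=[f"s{j + 1}" for j in range(n)]
        ).T
        tissue = _TISSUES[int(rng.integers(len(_TISSUES)))]
        condition = _CONDITIONS[int(rng.integers(len(_CONDITIONS)))]
        description = f"{tissue} {condition} expression profiling"
        experiments.append(
            ExpressionExperiment(f"E{e + 1:03d}", description, df, probe_to_gene)
        )
    truth = {"query": query, "planted": planted, "independent": independent,
             "r_true": r}
    return experiments, truth


def write_expression(experiments: list[ExpressionExperiment], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for exp in experiments:
        exp.values.to_csv(outdir / f"{exp.experiment_id}.tsv", sep="\t",
                          index_label="probe")
        mapping = pd.DataFrame(
            {"gene": pd.Series(exp.probe_to_gene)}
        )
        mapping.to_csv(outdir / f"{exp.experiment_id}.genes.tsv", sep="\t",
                       index_label="probe")
        (outdir / f"{exp.experiment_id}.txt").write_text(
            exp.description + "\n", encoding="utf-8"
        )


# -- everything ------------------------------------------------------------


def write_fixtures(spec: FixtureSpec, outdir) -> None:
    """Generate and persist the full fixture set under a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ontology, obo_text, edges = gen_ontology(spec)
    (outdir / "ontology.obo").write_text(obo_text, encoding="utf-8")
    with open(outdir / "ontology_edges.tsv", "w", encoding="utf-8") as fh:
        for child, rel, parent in edges:
            fh.write(f"{child}\t{rel}\t{parent}\n")
    _docs, manifest, corpus_truth = gen_corpus(spec, ontology)
    write_corpus(manifest, outdir / "corpus")
    (outdir / "corpus_truth.json").write_text(
        json.dumps(corpus_truth, indent=1), encoding="utf-8"
    )
    genome, genes, promoter_truth = gen_genome(spec)
    write_genome(genome, genes, promoter_truth, outdir)
    (outdir / "promoter_table.html").write_text(
        promoter_table_html(promoter_truth), encoding="utf-8"
    )
    experiments, expr_truth = gen_expression(spec)
    write_expression(experiments, outdir / "expression")
    (outdir / "expression_truth.json").write_text(
        json.dumps(expr_truth, indent=1), encoding="utf-8"
    )
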