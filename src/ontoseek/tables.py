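"""HTML table harvesting: relational-table detection and gene attributes.

Pages are scanned for ``<table>`` elements; a table is *relational* when
some column is densely populated with recognizable biological object
identifiers (gene names and synonyms). Relational tables are parsed into
typed (gene, attribute) records. A column headed "promoter" whose cells are
DNA sequences triggers a scan of each gene's upstream region: an exact
match assigns the sequence as a ``promoter_sequence`` attribute with global
genomic coordinates (0-based, half-open, on the + reference strand);
otherwise the cell is kept as a plain ``sequence`` attribute.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import lxml.html
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: A DNA-sequence cell: at least 10 ACGTN characters and nothing else.
DNA_CELL_RE = re.compile(r"[ACGTN]{10,}\Z", re.IGNORECASE)


@dataclass
class HtmlTable:
    doc_id: str
    rows: list[list[str]]  # rectangular; first row is the header row

    @property
    def header(self) -> list[str]:
        return self.rows[0] if self.rows else []

    @property
    def data_rows(self) -> list[list[str]]:
        return self.rows[1:]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class ColumnProfile:
    index: int
    id_fraction: float
    inferred_type: str  # identifier | dna_sequence | protein_sequence | number | text


@dataclass
class GeneModel:
    """A gene locus; coordinates are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GeneAttribute:
    gene_id: str
    attr_type: str  # promoter_sequence | sequence | named
    name: str
    value: str
    coordinates: tuple[str, int, int, str] | None = None  # chrom, start, end, strand

    def __post_init__(self) -> None:
        if self.attr_type == "promoter_sequence" and self.coordinates is None:
            raise ValueError("promoter_sequence attributes require coordinates")


def _cell_text(el) -> str:
    return " ".join(el.text_content().split())


def extract_tables(html: str, doc_id: str = "") -> list[HtmlTable]:
    """All tables of a page, nested tables flattened depth-first.

    Cells of a nested table belong to that table only, not to its parent.
    Ragged rows are padded with empty cells; empty tables are dropped.
    """
    if not html.strip():
        return []
    root = lxml.html.fromstring(html)
    tables: list[HtmlTable] = []

    def harvest(table_el) -> None:
        rows: list[list[str]] = []
        for tr in table_el.iter("tr"):
            # skip rows that belong to a nested table
            anc = tr.getparent()
            while anc is not None and anc.tag != "table":
                anc = anc.getparent()
            if anc is not table_el:
                continue
            cells = []
            for cell in tr.iter("td", "th"):
                anc = cell.getparent()
                while anc is not None and anc.tag != "tr":
                    anc = anc.getparent()
                if anc is tr and not any(
                    True for _ in cell.iterdescendants("table")
                ):
                    cells.append(_cell_text(cell))
                elif anc is tr:
                    # cell hosting a nested table: keep its own text only
                    texts = [cell.text or ""]
                    cells.append(" ".join(" ".join(texts).split()))
            if cells:
                rows.append(cells)
        if rows:
            width = max(len(r) for r in rows)
            rows = [r + [""] * (width - len(r)) for r in rows]
            if any(any(c for c in r) for r in rows):
                tables.append(HtmlTable(doc_id=doc_id, rows=rows))

    for table_el in root.iterdescendants("table"):
        harvest(table_el)
    if root.tag == "table":
        harvest(root)
    return tables


def _norm_id(text: str) -> str:
    return text.strip().lower()


def profile_column(table: HtmlTable, col: int, known_ids: frozenset[str] | set[str]
                   ) -> ColumnProfile:
    cells = [r[col] for r in table.data_rows if r[col].strip()]
    if not cells:
        return ColumnProfile(col, 0.0, "text")
    hits = sum(1 for c in cells if _norm_id(c) in known_ids)
    id_fraction = hits / len(cells)
    if id_fraction >= 0.5:
        inferred = "identifier"
    elif all(DNA_CELL_RE.fullmatch(c.strip()) for c in cells):
        inferred = "dna_sequence"
    elif all(re.fullmatch(r"[A-Z]{10,}", c.strip()) for c in cells):
        inferred = "protein_sequence"
    elif all(re.fullmatch(r"[-+]?\d+(\.\d+)?([eE][-+]?\d+)?", c.strip()) for c in cells):
        inferred = "number"
    else:
        inferred = "text"
    return ColumnProfile(col, id_fraction, inferred)


def classify_relational(table: HtmlTable, known_ids, min_id_fraction: float = 0.5
                        ) -> tuple[bool, int | None]:
    """Relational iff the table has >= 2 columns, >= 2 data rows, and some
    column's identifier fraction reaches ``min_id_fraction`` (inclusive).
    Returns (is_relational, key column index or None); ties on the fraction
    go to the leftmost column."""
    ids = frozenset(_norm_id(i) for i in known_ids)
    if table.n_cols < 2 or len(table.data_rows) < 2:
        return False, None
    profiles = [profile_column(table, c, ids) for c in range(table.n_cols)]
    best = max(profiles, key=lambda p: p.id_fraction)
    if best.id_fraction >= min_id_fraction:
        return True, best.index
    return False, None


class GenomeStore:
    """In-memory FASTA genome with strand-aware upstream extraction."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeStore":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.sequences[chrom][start:end]
        return str(Seq(seq).reverse_complement()) if strand == "-" else seq

    def upstream_window(self, gene: GeneModel, upstream_bp: int
                        ) -> tuple[str, int, int]:
        """(5'->3' upstream sequence, window start, window end) in + coords.

        Windows at a chromosome edge are truncated.
        """
        length = self.chrom_length(gene.chrom)
        if gene.strand == "+":
            start, end = max(0, gene.start - upstream_bp), gene.start
        else:
            start, end = gene.end, min(length, gene.end + upstream_bp)
        if end - start < upstream_bp:
            log.info("gene %s: upstream window truncated to %d bp",
                     gene.gene_id, end - start)
        return self.fetch(gene.chrom, start, end, gene.strand), start, end


def load_gene_models(bed_path) -> dict[str, GeneModel]:
    """Gene models from a BED6 file, keyed by (lower-cased) name."""
    genes: dict[str, GeneModel] = {}
    with open(bed_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            genes[_norm_id(name)] = GeneModel(name, chrom, int(start), int(end), strand)
    return genes


def assign_promoter_attribute(gene: GeneModel, seq: str, genome: GenomeStore,
                              upstream_bp: int = 10000,
                              column_name: str = "promoter") -> GeneAttribute:
    """Locate a harvested promoter sequence in a gene's upstream region.

    The upstream window covers ``upstream_bp`` bases 5' of the transcription
    start site on the gene's strand (reverse-complemented for - genes). An
    exact substring hit yields a ``promoter_sequence`` attribute with
    0-based half-open coordinates on the + reference strand; a miss keeps
    the raw sequence as a plain ``sequence`` attribute without coordinates.
    """
    if not seq or not DNA_CELL_RE.fullmatch(seq.strip()):
        raise ValueError(f"gene {gene.gene_id}: not a DNA sequence cell: {seq[:30]!r}")
    if gene.chrom not in genome:
        raise KeyError(f"gene {gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    seq = seq.strip().upper()
    window, win_start, win_end = genome.upstream_window(gene, upstream_bp)
    offset = window.find(seq)
    if offset < 0:
        return GeneAttribute(gene.gene_id, "sequence", column_name, seq)
    if gene.strand == "+":
        g_start = win_start + offset
    else:
        # window is reverse-complemented: oriented offset counts from win_end
        g_start = win_end - offset - len(seq)
    coords = (gene.chrom, g_start, g_start + len(seq), gene.strand)
    return GeneAttribute(gene.gene_id, "promoter_sequence", column_name, seq, coords)


def parse_relational_table(table: HtmlTable, key_col: int,
                           gene_models: Mapping[str, GeneModel] | None = None,
                           genome: GenomeStore | None = None,
                           upstream_bp: int = 10000) -> list[GeneAttribute]:
    """Emit (gene, attribute) records from a relational table.

    Header labels name the attributes; columns without a header label are
    dropped. DNA-sequence cells under a header containing "promoter" are
    routed through the upstream scan when a genome and gene models are
    available. Rows whose key cell resolves to no known gene are skipped.
    """
    attributes: list[GeneAttribute] = []
    header = table.header
    gene_models = gene_models or {}
    for row in table.data_rows:
        gene_name = row[key_col].strip()
        if not gene_name:
            continue
        gene = gene_models.get(_norm_id(gene_name))
        if gene_models and gene is None:
            log.info("key cell %r resolves to no gene model; row skipped", gene_name)
            continue
        gene_id = gene.gene_id if gene is not None else gene_name
        for col in range(table.n_cols):
            if col == key_col:
                continue
            label = header[col].strip()
            if not label:
                continue
            value = row[col].strip()
            if not value:
                continue
            is_dna = bool(DNA_CELL_RE.fullmatch(value))
            if is_dna and "promoter" in label.lower():
                if gene is not None and genome is not None:
                    attributes.append(
                        assign_promoter_attribute(gene, value, genome,
                                                  upstream_bp, label)
                    )
                else:
                    continue  # promoter cell but no gene/genome: skip row cell
            elif is_dna:
                attributes.append(GeneAttribute(gene_id, "sequence", label, value))
            else:
                attributes.append(GeneAttribute(gene_id, "named", label, value))
    return attributes


def export_attributes(attributes: Sequence[GeneAttribute], path) -> None:
    """TSV export: gene_id, attr_type, name, value, chrom, start, end, strand."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["gene_id", "attr_type", "name", "value", "chrom", "start", "end", "strand"]
        )
        for a in attributes:
            chrom, start, end, strand = a.coordinates or ("", "", "", "")
            writer.writerow([a.gene_id, a.attr_type, a.name, a.value,
                             chrom, start, end, strand])
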