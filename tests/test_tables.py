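"""Table extraction, relational classification, promoter assignment."""

import pytest

from ontoseek.fixtures import promoter_table_html
from ontoseek.tables import (GeneModel, GenomeStore, assign_promoter_attribute,
                             classify_relational, extract_tables,
                             load_gene_models, parse_relational_table)

GENES = ["tp53", "mdm2", "brca1", "egfr"]


def two_col_table(rows, header=("gene", "promoter")):
    body = "".join(
        "<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in rows
    )
    head = "<tr>" + "".join(f"<th>{h}</th>" for h in header) + "</tr>"
    return f"<div><table>{head}{body}</table></div>"


class TestExtractTables:
    def test_two_tables_found(self):
        html = two_col_table([("a", "b")]) + "<table><tr><td>x</td></tr></table>"
        assert len(extract_tables(html)) == 2

    def test_no_tables(self):
        assert extract_tables("<p>just prose</p>") == []
        assert extract_tables("") == []

    def test_ragged_rows_padded_rectangular(self):
        html = ("<table><tr><td>a</td><td>b</td></tr>"
                "<tr><td>c</td><td>d</td><td>e</td></tr>"
                "<tr><td>f</td></tr></table>")
        (table,) = extract_tables(html)
        assert [len(r) for r in table.rows] == [3, 3, 3]
        assert table.rows[2] == ["f", "", ""]

    def test_nested_tables_flattened_depth_first(self):
        html = ("<table><tr><td>outer"
                "<table><tr><td>inner</td><td>cell</td></tr></table>"
                "</td><td>right</td></tr>"
                "<tr><td>below</td><td>row</td></tr></table>")
        tables = extract_tables(html)
        assert len(tables) == 2
        flat = [c for t in tables for r in t.rows for c in r if c]
        # every cell text appears exactly once across the flattened tables
        assert sorted(flat) == ["below", "cell", "inner", "outer", "right", "row"]

    def test_empty_table_dropped(self):
        assert extract_tables("<table><tr><td> </td></tr></table>") == []


class TestClassifyRelational:
    def test_gene_promoter_table_is_relational_with_gene_key(self):
        html = two_col_table([("TP53", "ACGTACGTACGTACGT"),
                              ("MDM2", "TTTTACGTACGTACGT")])
        (table,) = extract_tables(html)
        relational, key = classify_relational(table, GENES)
        assert relational and key == 0

    def test_prose_layout_table_is_non_relational(self):
        html = two_col_table([("welcome to the site", "main menu"),
                              ("browse categories", "contact us")])
        (table,) = extract_tables(html)
        relational, key = classify_relational(table, GENES)
        assert not relational and key is None

    def test_single_column_or_single_row_rejected(self):
        one_col = "<table><tr><th>gene</th></tr><tr><td>tp53</td></tr><tr><td>mdm2</td></tr></table>"
        (table,) = extract_tables(one_col)
        assert classify_relational(table, GENES) == (False, None)
        one_row = two_col_table([("TP53", "ACGTACGTACGT")])
        (table,) = extract_tables(one_row)
        assert classify_relational(table, GENES) == (False, None)

    @pytest.mark.parametrize("n_ids,expected", [
        (4, False),   # 4/10 = 0.4 < 0.5
        (5, True),    # 5/10 = 0.5, inclusive boundary
        (6, True),
    ])
    def test_id_fraction_boundary_inclusive(self, n_ids, expected):
        ids = [f"gene{i}" for i in range(10)]
        rows = [(f"gene{i}" if i < n_ids else f"junk{i}", f"value{i}")
                for i in range(10)]
        (table,) = extract_tables(two_col_table(rows, header=("name", "attr")))
        relational, key = classify_relational(table, ids, min_id_fraction=0.5)
        assert relational is expected
        if expected:
            assert key == 0

    def test_key_is_highest_fraction_leftmost_on_tie(self):
        rows = [("x1", "tp53"), ("x2", "mdm2")]
        (table,) = extract_tables(two_col_table(rows, header=("a", "b")))
        _, key = classify_relational(table, GENES)
        assert key == 1


@pytest.fixture(scope="module")
def toy_genome():
    # 400 bp chromosome, + strand gene at [200, 300), - strand gene at [50, 150)
    import numpy as np
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    genome = GenomeStore({"chr1": seq})
    plus = GeneModel("plusg", "chr1", 200, 300, "+")
    minus = GeneModel("minusg", "chr1", 50, 150, "-")
    return genome, plus, minus


class TestAssignPromoter:
    def test_plus_strand_planted_promoter_found_at_exact_coordinates(self, toy_genome):
        genome, plus, _ = toy_genome
        seq = genome.fetch("chr1", 160, 190)  # 30 bp planted 10 bp upstream
        attr = assign_promoter_attribute(plus, seq, genome, upstream_bp=100)
        assert attr.attr_type == "promoter_sequence"
        assert attr.coordinates == ("chr1", 160, 190, "+")

    def test_minus_strand_found_after_reverse_complement(self, toy_genome):
        genome, _, minus = toy_genome
        # upstream of a - gene lies downstream in + coordinates
        seq = genome.fetch("chr1", 180, 210, strand="-")
        attr = assign_promoter_attribute(minus, seq, genome, upstream_bp=100)
        assert attr.attr_type == "promoter_sequence"
        assert attr.coordinates == ("chr1", 180, 210, "-")

    def test_coordinate_round_trip(self, toy_genome):
        genome, plus, minus = toy_genome
        for gene, window in ((plus, (150, 180)), (minus, (160, 190))):
            seq = genome.fetch("chr1", *window, strand=gene.strand)
            attr = assign_promoter_attribute(gene, seq, genome, upstream_bp=100)
            chrom, start, end, strand = attr.coordinates
            assert genome.fetch(chrom, start, end, strand) == seq

    def test_absent_sequence_kept_as_plain_sequence(self, toy_genome):
        genome, plus, _ = toy_genome
        attr = assign_promoter_attribute(plus, "A" * 30, genome, upstream_bp=100,
                                         column_name="promoter")
        assert attr.attr_type == "sequence"
        assert attr.coordinates is None
        assert attr.name == "promoter"

    def test_chromosome_edge_truncates_window(self, toy_genome):
        genome, _, _ = toy_genome
        edge_gene = GeneModel("edge", "chr1", 20, 120, "+")
        seq = genome.fetch("chr1", 0, 15)
        attr = assign_promoter_attribute(edge_gene, seq, genome, upstream_bp=100)
        assert attr.attr_type == "promoter_sequence"
        assert attr.coordinates == ("chr1", 0, 15, "+")

    def test_non_dna_cell_rejected(self, toy_genome):
        genome, plus, _ = toy_genome
        with pytest.raises(ValueError):
            assign_promoter_attribute(plus, "not dna", genome)


class TestParseRelationalTable:
    def test_promoter_column_routes_through_upstream_scan(self, genome_fixture):
        genome, genes, truth = genome_fixture
        (table,) = extract_tables(promoter_table_html(truth))
        relational, key = classify_relational(table, [t.gene_id for t in truth])
        assert relational and key == 0
        attrs = parse_relational_table(table, key, genes, genome)
        assert len(attrs) == len(truth)
        by_gene = {a.gene_id: a for a in attrs}
        for t in truth:
            attr = by_gene[t.gene_id]
            assert attr.attr_type == "promoter_sequence"
            assert attr.coordinates == (t.chrom, t.start, t.end, t.strand)

    def test_unlabeled_column_dropped(self):
        html = two_col_table([("tp53", "42"), ("mdm2", "17")], header=("gene", ""))
        (table,) = extract_tables(html)
        attrs = parse_relational_table(table, 0)
        assert attrs == []

    def test_labeled_numeric_column_becomes_named_attribute(self):
        html = two_col_table([("tp53", "4.2"), ("mdm2", "1.7")],
                             header=("gene", "expression"))
        (table,) = extract_tables(html)
        attrs = parse_relational_table(table, 0)
        assert [(a.gene_id, a.attr_type, a.name, a.value) for a in attrs] == [
            ("tp53", "named", "expression", "4.2"),
            ("mdm2", "named", "expression", "1.7"),
        ]

    def test_unresolvable_key_row_skipped(self, genome_fixture):
        genome, genes, truth = genome_fixture
        html = two_col_table([("GENE1", "4.2"), ("UNKNOWN", "1.7")],
                             header=("gene", "expression"))
        (table,) = extract_tables(html)
        attrs = parse_relational_table(table, 0, gene_models=genes)
        assert [a.gene_id for a in attrs] == ["GENE1"]

    def test_dna_cell_without_promoter_header_is_sequence(self):
        html = two_col_table([("tp53", "ACGTACGTACGTACGT")],
                             header=("gene", "motif"))
        (table,) = extract_tables(html)
        attrs = parse_relational_table(table, 0)
        assert attrs[0].attr_type == "sequence"
        assert attrs[0].name == "motif"


class TestBedRoundTrip:
    def test_load_gene_models(self, tmp_path, genome_fixture):
        from ontoseek.fixtures import FixtureSpec, gen_genome, write_genome
        genome, genes, truth = genome_fixture
        write_genome(genome, genes, truth, tmp_path)
        loaded = load_gene_models(tmp_path / "genes.bed")
        assert loaded.keys() == genes.keys()
        for k in genes:
            assert loaded[k] == genes[k]
        reloaded_genome = GenomeStore.from_fasta(tmp_path / "genome.fa")
        assert reloaded_genome.sequences == genome.sequences
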