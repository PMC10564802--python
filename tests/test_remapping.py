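"""Gene-name remapping: header parsing, the five modes, gap-filling."""

import pytest

from proteoharm.data_model import IdGroup, Reason, StudyRow, StudyTable
from proteoharm.provider import GeneRecord, MappingProvider, ProteinRecord
from proteoharm.remapping import (
    RemapConfig,
    parse_fasta_header,
    remap_gene_names,
)


@pytest.mark.parametrize(
    "header,expected",
    [
        (">sp|P12345|X_HUMAN desc OS=Homo sapiens GN=ABC1 PE=1", ("P12345", "ABC1")),
        (">tr|Q99999|Q_HUMAN something OS=x", ("Q99999", None)),
        (">sp|P12345|X_HUMAN desc GN=ABC1\n", ("P12345", "ABC1")),
        (">nodialect header", (None, None)),
    ],
)
def test_parse_fasta_header(header, expected):
    assert parse_fasta_header(header) == expected


def test_parse_fasta_header_requires_marker():
    with pytest.raises(ValueError):
        parse_fasta_header("sp|P1|X")


def _table(cells, gene_cells=None, organism="human"):
    gene_cells = gene_cells or [""] * len(cells)
    rows = [
        StudyRow(
            row_id=i,
            id_group=IdGroup.from_cell(ids),
            gene_group=IdGroup.from_cell(genes),
        )
        for i, (ids, genes) in enumerate(zip(cells, gene_cells))
    ]
    return StudyTable(
        "t", organism, rows, ("Protein IDs", "Gene names"),
        id_column="Protein IDs", gene_column="Gene names",
    )


@pytest.fixture()
def toy_provider():
    return MappingProvider(
        proteins=[
            ProteinRecord("P1", "human", True, primary_gene_name="A",
                          gene_name_synonyms=("A2",)),
            ProteinRecord("P2", "human", True, primary_gene_name="A"),
            ProteinRecord("P3", "human", True, primary_gene_name="B"),
            ProteinRecord("P4", "human", True),  # no gene name
            ProteinRecord("P5", "human", True, primary_gene_name="C",
                          gene_name_synonyms=("Cx",)),
        ],
        genes=[
            GeneRecord("A", "human", "ENSG1", "A", in_hgnc=True),
            GeneRecord("A2", "human", "ENSG1", "A", in_hgnc=True),
            GeneRecord("B", "human", "ENSG2", "B", in_hgnc=True),
            GeneRecord("C", "human", "ENSG3", "C", in_hgnc=True),
            GeneRecord("Cx", "human", "ENSG3", "C", in_hgnc=False),
        ],
    )


def test_uniprot_one_picks_most_frequent_primary(toy_provider):
    # primary names across the group: A, A, B -> frequency oracle picks A
    table = _table(["P1;P2;P3"])
    out, overview, _ = remap_gene_names(
        table, toy_provider, RemapConfig(mode="uniprot_one")
    )
    assert out.rows[0].gene_group.ids == ("A",)
    assert overview[0].n_added == 1


def test_uniprot_one_tie_breaks_by_group_order(toy_provider):
    table = _table(["P3;P1"])  # B and A each occur once; B appears first
    out, _, _ = remap_gene_names(
        table, toy_provider, RemapConfig(mode="uniprot_one")
    )
    assert out.rows[0].gene_group.ids == ("B",)


def test_uniprot_primary_singleton(toy_provider):
    out, _, _ = remap_gene_names(
        _table(["P5"]), toy_provider, RemapConfig(mode="uniprot_primary")
    )
    assert out.rows[0].gene_group.ids == ("C",)


def test_uniprot_mode_filters_non_hgnc_synonyms(toy_provider):
    out, _, _ = remap_gene_names(
        _table(["P5"]), toy_provider, RemapConfig(mode="uniprot")
    )
    # Cx is known to the gene table but not HGNC-listed -> excluded
    assert out.rows[0].gene_group.ids == ("C",)
    out, _, _ = remap_gene_names(
        _table(["P1"]), toy_provider, RemapConfig(mode="uniprot")
    )
    assert out.rows[0].gene_group.ids == ("A", "A2")


def test_nameless_rows_dropped_and_logged(toy_provider):
    table = _table(["P4", "P1", "P4;P1"])
    out, overview, detail = remap_gene_names(
        table, toy_provider, RemapConfig(mode="uniprot_primary")
    )
    assert [r.row_id for r in out.rows] == [1, 2]
    reasons = [d for d in detail if d.reason is Reason.NO_GENE_NAME]
    assert [d.identifier for d in reasons] == ["P4", "P4"]


def test_keep_empty_retains_nameless_rows(toy_provider):
    out, _, _ = remap_gene_names(
        _table(["P4"]), toy_provider,
        RemapConfig(mode="uniprot_primary", keep_empty=True),
    )
    assert len(out) == 1 and not out.rows[0].gene_group


@pytest.fixture()
def fasta_file(tmp_path):
    path = tmp_path / "ref.fasta"
    path.write_text(
        ">sp|P1|A_HUMAN demo OS=Homo sapiens GN=FASTA_A PE=1\n"
        "MSEQ\n"
        ">sp|P4|D_HUMAN no gene token OS=Homo sapiens\n"
        "MSEQ\n"
    )
    return str(path)


def test_fasta_mode_uses_headers_only(toy_provider, fasta_file):
    table = _table(["P1", "P3"])
    out, _, detail = remap_gene_names(
        table, toy_provider, RemapConfig(mode="fasta", fasta_path=fasta_file)
    )
    # P1 gets its header name; P3 has no header at all -> dropped
    assert len(out) == 1
    assert out.rows[0].gene_group.ids == ("FASTA_A",)
    assert [d.identifier for d in detail] == ["P3"]


def test_all_mode_is_superset_of_fasta(toy_provider, fasta_file):
    table = _table(["P1;P3;P4"])
    fasta_out, _, _ = remap_gene_names(
        table, toy_provider,
        RemapConfig(mode="fasta", fasta_path=fasta_file, keep_empty=True),
    )
    all_out, _, _ = remap_gene_names(
        table, toy_provider,
        RemapConfig(mode="all", fasta_path=fasta_file, keep_empty=True),
    )
    assert set(all_out.rows[0].gene_group) >= set(fasta_out.rows[0].gene_group)
    # UniProt fills the gap for P3; P4 has neither header nor annotation
    assert "B" in all_out.rows[0].gene_group.ids


def test_fasta_mode_without_file_is_config_error():
    with pytest.raises(ValueError, match="fasta_path"):
        RemapConfig(mode="fasta")


def test_skip_filled_leaves_existing_cells(toy_provider):
    table = _table(["P1", "P3"], gene_cells=["OLD", ""])
    out, overview, _ = remap_gene_names(
        table, toy_provider,
        RemapConfig(mode="uniprot_primary", skip_filled=True),
    )
    assert out.rows[0].gene_group.ids == ("OLD",)
    assert out.rows[1].gene_group.ids == ("B",)
    # overwrite default replaces OLD
    out2, _, _ = remap_gene_names(
        table, toy_provider, RemapConfig(mode="uniprot_primary")
    )
    assert out2.rows[0].gene_group.ids == ("A",)


def test_remap_is_deterministic(use_case):
    s16 = next(t for t in use_case.studies if t.study_id == "schmidt2016")
    cfg = RemapConfig(mode="uniprot_primary")
    first = remap_gene_names(s16, use_case.provider, cfg)
    second = remap_gene_names(s16, use_case.provider, cfg)
    assert [r.gene_group.ids for r in first[0].rows] == [
        r.gene_group.ids for r in second[0].rows
    ]
    assert first[1] == second[1] and first[2] == second[2]


def test_n_added_counts_newly_filled_cells(toy_provider):
    table = _table(["P1", "P3", "P4"], gene_cells=["A", "", ""])
    _, overview, _ = remap_gene_names(
        table, toy_provider, RemapConfig(mode="uniprot_primary", keep_empty=True)
    )
    newly_filled = sum(
        1 for r in overview if r.n_previous == 0 and r.n_added > 0
    )
    assert newly_filled == 1  # P3's row; P4 stays empty, P1 was filled before
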