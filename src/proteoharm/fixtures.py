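"""Deterministic synthetic fixtures: annotation snapshots, study tables and
networks with known ground truth.

Every pipeline stage is testable offline against data generated here. Two
families are provided:

* randomized generators driven by a :class:`FixtureSpec` (annotation
  provider tables, study tables with planted defects, PPI networks with
  planted connector nodes), each emitting a ground-truth manifest so tests
  can compare pipeline output against what was planted;
* a hand-curated micro-fixture of four bone-regeneration studies (two human
  protein-group studies, one rat single-accession study, one mouse
  gene-only study) in which a set of named identifier behaviors — the
  cross-species tropomyosin accessions ``B4DQ80``/``B7Z722`` vs rat
  ``Q63610``, the Ensembl renames ``Ppia``→``Ppial4d`` and
  ``Serpina3n``→``RGD1565462``, the ortholog pairs ``Serpinc1``→``SERPINC1``
  and ``Postn``→``POSTN`` — are reproduced verbatim.

Same spec + seed → byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import numpy as np

from .data_model import IdGroup, StudyRow, StudyTable
from .mechanism import MechanismNetwork
from .provider import (
    GeneRecord,
    MappingProvider,
    OrthologPair,
    ProteinRecord,
)

__all__ = [
    "FixtureSpec",
    "generate_annotation",
    "generate_provider_tables",
    "generate_study_tables",
    "UseCaseFixture",
    "generate_use_case_fixture",
    "NetworkFixture",
    "generate_network_fixture",
    "write_provider_tables",
    "write_network_fixture",
]

_ENSEMBL_PREFIX = {
    "human": "ENSG",
    "rat": "ENSRNOG",
    "mouse": "ENSMUSG",
    "rabbit": "ENSOCUG",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Shapes and defect rates for the randomized generators.

    Defaults mirror the four-study meta-analysis scenario: two human
    protein-group studies (24 and 41 rows), one rat single-accession study
    (170 rows) and one mouse gene-only study (608 rows); defect rates follow
    the observed data (obsolete accessions the most common removal, ~6% of
    protein entries without a gene name, ~93% ortholog coverage).
    """

    seed: int = 0
    organisms: tuple[str, ...] = ("human", "human", "rat", "mouse")
    n_rows: tuple[int, ...] = (24, 41, 170, 608)
    gene_only: tuple[bool, ...] = (False, False, False, True)
    group_size_mean: float = 2.5
    n_genes: int = 700
    frac_obsolete: float = 0.05
    frac_unreviewed: float = 0.05
    frac_contaminant: float = 0.02
    frac_decoy: float = 0.02
    frac_wrong_organism: float = 0.02
    frac_missing_gene_name: float = 0.06
    frac_synonym: float = 0.15
    frac_no_ensembl: float = 0.05
    frac_renamed_ensembl: float = 0.08
    ortholog_coverage: float = 0.93
    frac_one_to_many: float = 0.05
    n_network_nodes: int = 100
    module_size: int = 8
    drugs_per_module_gene: int = 2

    def __post_init__(self) -> None:
        for name in (
            "frac_obsolete",
            "frac_unreviewed",
            "frac_contaminant",
            "frac_decoy",
            "frac_wrong_organism",
            "frac_missing_gene_name",
            "frac_synonym",
            "frac_no_ensembl",
            "frac_renamed_ensembl",
            "ortholog_coverage",
            "frac_one_to_many",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if len(self.organisms) != len(self.n_rows) or len(self.organisms) != len(
            self.gene_only
        ):
            raise ValueError("organisms, n_rows and gene_only must align")


def _symbol(organism: str, i: int) -> str:
    base = f"GN{i}"
    return base if organism == "human" else base.capitalize()


def _accession(organism: str, i: int, j: int) -> str:
    prefix = {"human": "PH", "rat": "QR", "mouse": "QM", "rabbit": "QB"}[organism]
    return f"{prefix}{i:04d}{j}"


def generate_annotation(
    spec: FixtureSpec,
) -> tuple[MappingProvider, dict]:
    """Build an internally consistent random annotation snapshot.

    Every organism in the spec gets ``n_genes`` genes indexed 0..n-1;
    non-human gene *i* is orthologous to human gene *i* where coverage
    allows, so the planted cross-organism correspondence is index identity.
    Returns the provider and a ground-truth manifest (which accessions are
    obsolete/unreviewed/nameless, which genes lack Ensembl ids or ortholog
    partners, ...).
    """
    rng = np.random.default_rng(spec.seed)
    organisms = sorted(set(spec.organisms) | {"human"})
    genes: list[GeneRecord] = []
    proteins: list[ProteinRecord] = []
    orthologs: list[OrthologPair] = []
    manifest: dict = {
        "obsolete": [],
        "unreviewed": [],
        "nameless": [],
        "no_ensembl": {},
        "no_ortholog": {},
        "renamed_ensembl": {},
        "synonyms": {},
    }
    ensembl_ids: dict[tuple[str, int], str | None] = {}
    for organism in organisms:
        no_ens, no_orth, renamed = [], [], {}
        for i in range(spec.n_genes):
            symbol = _symbol(organism, i)
            has_ensembl = rng.random() >= spec.frac_no_ensembl
            ensembl_id = (
                f"{_ENSEMBL_PREFIX[organism]}{i:08d}" if has_ensembl else None
            )
            ensembl_ids[(organism, i)] = ensembl_id
            if has_ensembl and rng.random() < spec.frac_renamed_ensembl:
                ensembl_symbol = f"{symbol}e"
                renamed[symbol] = ensembl_symbol
            elif has_ensembl:
                ensembl_symbol = symbol
            else:
                ensembl_symbol = None
                no_ens.append(symbol)
            genes.append(
                GeneRecord(
                    symbol=symbol,
                    organism=organism,
                    ensembl_id=ensembl_id,
                    ensembl_symbol=ensembl_symbol,
                    in_hgnc=organism == "human",
                    in_mygene=bool(rng.random() < 0.95),
                    has_functional_annotation=bool(rng.random() < 0.9),
                )
            )
            if ensembl_symbol is not None and ensembl_symbol != symbol:
                # the canonical symbol resolves to the same Ensembl gene
                genes.append(
                    GeneRecord(
                        symbol=ensembl_symbol,
                        organism=organism,
                        ensembl_id=ensembl_id,
                        ensembl_symbol=ensembl_symbol,
                        in_hgnc=organism == "human",
                        in_mygene=True,
                        has_functional_annotation=True,
                    )
                )
        manifest["no_ensembl"][organism] = no_ens
        manifest["renamed_ensembl"][organism] = renamed

        if organism != "human":
            for i in range(spec.n_genes):
                source_id = ensembl_ids[(organism, i)]
                target_id = ensembl_ids[("human", i)]
                symbol = _symbol(organism, i)
                if (
                    source_id is None
                    or target_id is None
                    or rng.random() >= spec.ortholog_coverage
                ):
                    no_orth.append(symbol)
                    continue
                orthologs.append(
                    OrthologPair(
                        source_ensembl_id=source_id,
                        source_organism=organism,
                        target_organism="human",
                        target_ensembl_id=target_id,
                        target_symbol=_symbol("human", i),
                    )
                )
                if rng.random() < spec.frac_one_to_many:
                    k = (i + 1) % spec.n_genes
                    extra_id = ensembl_ids[("human", k)]
                    if extra_id is not None:
                        orthologs.append(
                            OrthologPair(
                                source_ensembl_id=source_id,
                                source_organism=organism,
                                target_organism="human",
                                target_ensembl_id=extra_id,
                                target_symbol=_symbol("human", k),
                            )
                        )
            manifest["no_ortholog"][organism] = no_orth

        syn_map = {}
        for i in range(spec.n_genes):
            symbol = _symbol(organism, i)
            n_prot = 1 + int(rng.random() < 0.3)
            for j in range(n_prot):
                accession = _accession(organism, i, j)
                obsolete = rng.random() < spec.frac_obsolete
                if obsolete:
                    proteins.append(
                        ProteinRecord(accession=accession, obsolete=True)
                    )
                    manifest["obsolete"].append(accession)
                    continue
                unreviewed = rng.random() < spec.frac_unreviewed
                nameless = rng.random() < spec.frac_missing_gene_name
                synonyms: tuple[str, ...] = ()
                if not nameless and rng.random() < spec.frac_synonym:
                    alias = f"{symbol}b"
                    synonyms = (alias,)
                    if alias not in syn_map:
                        syn_map[alias] = symbol
                        gene_id = ensembl_ids[(organism, i)]
                        # alias resolves to the same Ensembl gene, so
                        # reduction collapses it onto the canonical symbol
                        genes.append(
                            GeneRecord(
                                symbol=alias,
                                organism=organism,
                                ensembl_id=gene_id,
                                ensembl_symbol=(
                                    None if gene_id is None
                                    else renamed.get(symbol, symbol)
                                ),
                                in_hgnc=False,
                                in_mygene=True,
                                has_functional_annotation=False,
                            )
                        )
                proteins.append(
                    ProteinRecord(
                        accession=accession,
                        organism=organism,
                        reviewed=not unreviewed,
                        obsolete=False,
                        primary_gene_name=None if nameless else symbol,
                        gene_name_synonyms=synonyms,
                    )
                )
                if unreviewed:
                    manifest["unreviewed"].append(accession)
                if nameless:
                    manifest["nameless"].append(accession)
        manifest["synonyms"][organism] = syn_map

    # deduplicate gene records that may have been added twice (alias of a
    # renamed gene colliding with its canonical record)
    unique: dict[tuple[str, str], GeneRecord] = {}
    for g in genes:
        unique.setdefault((g.symbol, g.organism), g)
    provider = MappingProvider(
        proteins=proteins, genes=list(unique.values()), orthologs=orthologs
    )
    return provider, manifest


def write_provider_tables(
    provider: MappingProvider, out_dir: str | os.PathLike
) -> None:
    """Serialize a provider to the three-TSV layout ``load_provider`` reads."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    def _b(x: bool) -> str:
        return "1" if x else "0"

    with open(os.path.join(out_dir, "proteins.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["accession", "organism", "reviewed", "obsolete",
             "primary_gene_name", "synonyms"]
        )
        for p in sorted(provider.proteins, key=lambda p: p.accession):
            w.writerow(
                [p.accession, p.organism or "", _b(p.reviewed), _b(p.obsolete),
                 p.primary_gene_name or "", "|".join(p.gene_name_synonyms)]
            )
    with open(os.path.join(out_dir, "genes.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["symbol", "organism", "ensembl_id", "ensembl_symbol",
             "in_hgnc", "in_mygene", "has_annotation"]
        )
        for g in sorted(provider.genes, key=lambda g: (g.organism, g.symbol)):
            w.writerow(
                [g.symbol, g.organism, g.ensembl_id or "",
                 g.ensembl_symbol or "", _b(g.in_hgnc), _b(g.in_mygene),
                 _b(g.has_functional_annotation)]
            )
    with open(os.path.join(out_dir, "orthologs.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["source_ensembl_id", "source_organism", "target_organism",
             "target_ensembl_id", "target_symbol"]
        )
        for o in sorted(
            provider.ortholog_pairs,
            key=lambda o: (o.source_organism, o.source_ensembl_id,
                           o.target_ensembl_id),
        ):
            w.writerow(
                [o.source_ensembl_id, o.source_organism, o.target_organism,
                 o.target_ensembl_id, o.target_symbol]
            )


def generate_provider_tables(
    spec: FixtureSpec, out_dir: str | os.PathLike
) -> dict:
    """Write proteins.tsv / genes.tsv / orthologs.tsv plus a ground-truth
    ``manifest.json`` into ``out_dir``; returns the manifest."""
    provider, manifest = generate_annotation(spec)
    out_dir = os.fspath(out_dir)
    write_provider_tables(provider, out_dir)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def generate_study_tables(
    spec: FixtureSpec, provider: MappingProvider
) -> list[StudyTable]:
    """Sample study tables consistent with a generated annotation snapshot.

    Protein studies draw accession groups (1 + Poisson group sizes) from
    their organism's proteins and plant decoy/contaminant flags and
    wrong-organism accessions at the spec's rates; gene-only studies draw
    plain symbols. An ``abundance`` extra column exercises the
    column-preservation contract.
    """
    rng = np.random.default_rng(spec.seed + 1)
    by_organism: dict[str, list[ProteinRecord]] = {}
    for p in provider.proteins:
        key = p.organism or "human"
        by_organism.setdefault(key, []).append(p)
    for records in by_organism.values():
        records.sort(key=lambda p: p.accession)
    all_accessions = sorted(p.accession for p in provider.proteins)

    tables = []
    for idx, (organism, n_rows, gene_only) in enumerate(
        zip(spec.organisms, spec.n_rows, spec.gene_only)
    ):
        study_id = f"study{idx + 1}_{organism}"
        rows = []
        if gene_only:
            symbols = [_symbol(organism, i) for i in range(spec.n_genes)]
            chosen = rng.choice(
                len(symbols), size=min(n_rows, len(symbols)), replace=False
            )
            for row_id, gi in enumerate(sorted(chosen)):
                rows.append(
                    StudyRow(
                        row_id=row_id,
                        gene_group=IdGroup((symbols[gi],)),
                        extra=(("abundance", f"{rng.normal():.3f}"),),
                    )
                )
            tables.append(
                StudyTable(
                    study_id=study_id,
                    organism=organism,
                    rows=rows,
                    columns=("Gene names", "abundance"),
                    gene_column="Gene names",
                )
            )
            continue
        pool = by_organism.get(organism, [])
        for row_id in range(n_rows):
            size = 1 + rng.poisson(max(spec.group_size_mean - 1.0, 0.0))
            members = []
            for _ in range(size):
                r = rng.random()
                if r < spec.frac_decoy:
                    members.append(
                        "REV__" + all_accessions[rng.integers(len(all_accessions))]
                    )
                elif r < spec.frac_decoy + spec.frac_contaminant:
                    members.append(
                        "CON__" + all_accessions[rng.integers(len(all_accessions))]
                    )
                elif r < (
                    spec.frac_decoy + spec.frac_contaminant
                    + spec.frac_wrong_organism
                ):
                    others = [
                        o for o in by_organism if o != organism
                    ] or [organism]
                    other = others[rng.integers(len(others))]
                    other_pool = by_organism[other]
                    members.append(
                        other_pool[rng.integers(len(other_pool))].accession
                    )
                else:
                    members.append(pool[rng.integers(len(pool))].accession)
            rows.append(
                StudyRow(
                    row_id=row_id,
                    id_group=IdGroup(tuple(dict.fromkeys(members))),
                    extra=(("abundance", f"{rng.normal():.3f}"),),
                )
            )
        tables.append(
            StudyTable(
                study_id=study_id,
                organism=organism,
                rows=rows,
                columns=("Protein IDs", "abundance"),
                id_column="Protein IDs",
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Hand-curated use-case micro-fixture
# ---------------------------------------------------------------------------


@dataclass
class UseCaseFixture:
    """Four curated studies + matching provider + expected outcomes."""

    studies: list[StudyTable]
    provider: MappingProvider
    expected: dict


def _protein_rows(study_id: str, cells: list[tuple[str, str]]) -> list[StudyRow]:
    return [
        StudyRow(
            row_id=i,
            id_group=IdGroup.from_cell(ids),
            gene_group=IdGroup.from_cell(genes),
            extra=(("log2FC", f"{(i % 7) - 3}.1"),),
            source_cells=(("Gene names", genes), ("Protein IDs", ids)),
        )
        for i, (ids, genes) in enumerate(cells)
    ]


def generate_use_case_fixture() -> UseCaseFixture:
    """The curated four-study bone-regeneration micro-scenario.

    Studies (published state, i.e. with the authors' own gene columns):

    * ``schmidt2016`` — human protein groups, incl. one group with an
      unreviewed no-name accession and one contaminant-flagged row;
    * ``schmidt2018`` — human protein groups, incl. one decoy-flagged row;
    * ``calciolari2017`` — rat single accessions, incl. the two human
      tropomyosin accessions ``B4DQ80``/``B7Z722``, the kept rat ``Q63610``,
      two name-less accessions, and the Ensembl-renamed ``Ppia`` /
      ``Serpina3n`` carriers;
    * ``dong2020`` — mouse gene symbols only, incl. two symbols without a
      human ortholog.

    ``expected`` records the planted outcomes: exact organism-filter
    removals, the Ensembl renames, occurrence counts before/after
    harmonization.
    """
    human_genes = [
        "POSTN", "MMP2", "ANXA1", "GAPDH", "HSPG2", "PGAM4", "BGN", "THBS1",
        "LUM", "TPM3", "COL1A1", "FN1", "VIM", "SPARC", "DCN", "SERPINC1",
        "PPIA", "SERPINA3",
    ]
    genes = [
        GeneRecord(
            symbol=s, organism="human", ensembl_id=f"ENSG{i:08d}",
            ensembl_symbol=s, in_hgnc=True, in_mygene=True,
            has_functional_annotation=True,
        )
        for i, s in enumerate(human_genes)
    ]
    human_id = {s: f"ENSG{i:08d}" for i, s in enumerate(human_genes)}

    rat_plain = ["Postn", "Tpm3", "Vim", "Dcn", "Gapdh", "Hspg2", "Pgam4",
                 "Serpinc1", "Col12a1"]
    rat_id = {s: f"ENSRNOG{i:08d}" for i, s in enumerate(
        rat_plain + ["Ppia", "Serpina3n"]
    )}
    for s in rat_plain:
        genes.append(
            GeneRecord(
                symbol=s, organism="rat", ensembl_id=rat_id[s],
                ensembl_symbol=s, in_mygene=True,
                has_functional_annotation=True,
            )
        )
    # renamed in the Ensembl namespace: the canonical Ensembl symbols differ
    for published, canonical in (("Ppia", "Ppial4d"),
                                 ("Serpina3n", "RGD1565462")):
        for symbol in (published, canonical):
            genes.append(
                GeneRecord(
                    symbol=symbol, organism="rat",
                    ensembl_id=rat_id[published], ensembl_symbol=canonical,
                    in_mygene=True, has_functional_annotation=symbol == published,
                )
            )

    mouse_syms = ["Postn", "Serpinc1", "Gapdh", "Mmp2", "Anxa1", "Thbs1", "Xdh"]
    mouse_id = {s: f"ENSMUSG{i:08d}" for i, s in enumerate(mouse_syms)}
    for s in mouse_syms:
        genes.append(
            GeneRecord(
                symbol=s, organism="mouse", ensembl_id=mouse_id[s],
                ensembl_symbol=s, in_mygene=True,
                has_functional_annotation=True,
            )
        )
    genes.append(GeneRecord(symbol="Gm6135", organism="mouse", in_mygene=False))

    rat_to_human = {
        "Postn": "POSTN", "Tpm3": "TPM3", "Vim": "VIM", "Dcn": "DCN",
        "Gapdh": "GAPDH", "Hspg2": "HSPG2", "Pgam4": "PGAM4",
        "Serpinc1": "SERPINC1", "Ppia": "PPIA", "Serpina3n": "SERPINA3",
    }
    mouse_to_human = {
        "Postn": "POSTN", "Serpinc1": "SERPINC1", "Gapdh": "GAPDH",
        "Mmp2": "MMP2", "Anxa1": "ANXA1", "Thbs1": "THBS1",
    }  # Xdh deliberately has no pair, Gm6135 no Ensembl id
    orthologs = [
        OrthologPair(rat_id[src], "rat", "human", human_id[dst], dst)
        for src, dst in rat_to_human.items()
    ] + [
        OrthologPair(mouse_id[src], "mouse", "human", human_id[dst], dst)
        for src, dst in mouse_to_human.items()
    ]

    human_proteins = {
        "Q15063": "POSTN", "P08253": "MMP2", "P04083": "ANXA1",
        "P04406": "GAPDH", "P98160": "HSPG2", "Q8N0Y7": "PGAM4",
        "P21810": "BGN", "P07996": "THBS1", "P51884": "LUM",
        "P06753": "TPM3", "P02452": "COL1A1", "P02751": "FN1",
        "P08670": "VIM", "P09486": "SPARC", "P07585": "DCN",
        "P01008": "SERPINC1",
    }
    proteins = [
        ProteinRecord(acc, "human", reviewed=True, primary_gene_name=name)
        for acc, name in human_proteins.items()
    ]
    # the two human tropomyosin-like accessions that contaminate the rat study
    proteins += [
        ProteinRecord("B4DQ80", "human", reviewed=False,
                      primary_gene_name="TPM3"),
        ProteinRecord("B7Z722", "human", reviewed=False),
        ProteinRecord("H0YH55", "human", reviewed=False),
    ]
    rat_proteins = {
        "D3ZAF5": "Postn", "Q63610": "Tpm3", "P31000": "Vim",
        "Q01129": "Dcn", "P04797": "Gapdh", "F1LPH1": "Hspg2",
        "M0R5V6": "Pgam4", "Q5M7T5": "Serpinc1", "P10111": "Ppia",
        "P09006": "Serpina3n",
    }
    proteins += [
        ProteinRecord(acc, "rat", reviewed=True, primary_gene_name=name)
        for acc, name in rat_proteins.items()
    ]
    proteins += [
        ProteinRecord("A0A0G2JSH1", "rat", reviewed=True),
        ProteinRecord("A0A8I6A2R4", "rat", reviewed=True),
    ]
    provider = MappingProvider(
        proteins=proteins, genes=genes, orthologs=orthologs
    )

    schmidt2016 = StudyTable(
        study_id="schmidt2016", organism="human",
        rows=_protein_rows("schmidt2016", [
            ("Q15063;H0YH55", "POSTN"),
            ("P08253", "MMP2"),
            ("P02452", "COL1A1"),
            ("P02751", "FN1"),
            ("P08670", "VIM"),
            ("P04083", "ANXA1"),
            ("P09486", "SPARC"),
            ("CON__P00761", ""),
        ]),
        columns=("Protein IDs", "Gene names", "log2FC"),
        id_column="Protein IDs", gene_column="Gene names",
    )
    schmidt2018 = StudyTable(
        study_id="schmidt2018", organism="human",
        rows=_protein_rows("schmidt2018", [
            ("Q15063", "POSTN"),
            ("P08253", "MMP2"),
            ("P04083", "ANXA1"),
            ("P04406", "GAPDH"),
            ("P98160", "HSPG2"),
            ("Q8N0Y7", "PGAM4"),
            ("P21810", "BGN"),
            ("P07996", "THBS1"),
            ("P51884", "LUM"),
            ("P06753", "TPM3"),
            ("REV__P04406", ""),
        ]),
        columns=("Protein IDs", "Gene names", "log2FC"),
        id_column="Protein IDs", gene_column="Gene names",
    )
    calciolari2017 = StudyTable(
        study_id="calciolari2017", organism="rat",
        rows=_protein_rows("calciolari2017", [
            ("D3ZAF5", "POSTN"),
            ("Q63610", "TPM3"),
            ("B4DQ80", "TPM3"),
            ("B7Z722", ""),
            ("P31000", "VIM"),
            ("Q01129", "DCN"),
            ("P04797", "Gapdh"),
            ("F1LPH1", "Hspg2"),
            ("M0R5V6", "Pgam4"),
            ("Q5M7T5", "Serpinc1"),
            ("P10111", "Ppia"),
            ("P09006", "Serpina3n"),
            ("A0A0G2JSH1", "Col12a1"),
            ("A0A8I6A2R4", ""),
        ]),
        columns=("Protein IDs", "Gene names", "log2FC"),
        id_column="Protein IDs", gene_column="Gene names",
    )
    dong2020 = StudyTable(
        study_id="dong2020", organism="mouse",
        rows=[
            StudyRow(
                row_id=i,
                gene_group=IdGroup.from_cell(symbol),
                extra=(("log2FC", f"{(i % 5) - 2}.4"),),
                source_cells=(("Gene names", symbol),),
            )
            for i, symbol in enumerate(
                ["Postn", "Serpinc1", "Gapdh", "Mmp2", "Anxa1", "Thbs1",
                 "Xdh", "Gm6135"]
            )
        ],
        columns=("Gene names", "log2FC"),
        gene_column="Gene names",
    )

    expected = {
        "organism_filter_removed": ("B4DQ80", "B7Z722"),
        "organism_filter_kept_contains": "Q63610",
        "ensembl_renames": {"Ppia": "Ppial4d", "Serpina3n": "RGD1565462"},
        "ortholog_examples": {("rat", "Serpinc1"): ["SERPINC1"],
                              ("mouse", "Postn"): ["POSTN"]},
        "postn_count_after": 4,
        "postn_count_before": 3,
    }
    return UseCaseFixture(
        studies=[schmidt2016, schmidt2018, calciolari2017, dong2020],
        provider=provider,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# Network fixture with planted connectors
# ---------------------------------------------------------------------------


@dataclass
class NetworkFixture:
    """A PPI network with planted seed clusters bridged by known connectors."""

    network: MechanismNetwork
    seeds: tuple[str, ...]
    planted_connectors: tuple[str, ...]


def generate_network_fixture(spec: FixtureSpec) -> NetworkFixture:
    """Plant ``module_size`` seeds as two intra-connected clusters whose only
    link runs through one bridge node, surround them with random background
    trees hanging off each half (so no alternative cross-cluster path
    exists), and attach ``drugs_per_module_gene`` drugs to every seed.

    Any Steiner tree over the seeds must use the bridge, which is the
    recoverable ground truth.
    """
    import networkx as nx

    rng = np.random.default_rng(spec.seed + 2)
    half = max(spec.module_size // 2, 2)
    cluster_a = [f"SEEDA{i}" for i in range(half)]
    cluster_b = [f"SEEDB{i}" for i in range(spec.module_size - half)]
    bridge = "CONNECT0"
    graph = nx.Graph()
    for cluster in (cluster_a, cluster_b):
        for u, v in zip(cluster, cluster[1:]):
            graph.add_edge(u, v, weight=1.0)
        # one chord so induced seed subgraphs are not trees
        if len(cluster) > 2:
            graph.add_edge(cluster[0], cluster[-1], weight=1.0)
    graph.add_edge(cluster_a[0], bridge, weight=1.0)
    graph.add_edge(bridge, cluster_b[0], weight=1.0)

    n_background = max(spec.n_network_nodes - graph.number_of_nodes(), 0)
    halves = (cluster_a, cluster_b)
    background_of: dict[int, list[str]] = {0: [], 1: []}
    for i in range(n_background):
        node = f"BG{i}"
        side = int(rng.integers(2))
        anchors = halves[side] + background_of[side]
        anchor = anchors[int(rng.integers(len(anchors)))]
        graph.add_edge(node, anchor, weight=float(1.0 + rng.random()))
        background_of[side].append(node)

    seeds = tuple(cluster_a + cluster_b)
    drug_targets: dict[str, frozenset[str]] = {}
    drug_approved: dict[str, bool] = {}
    drug_index = 0
    for seed in seeds:
        for _ in range(spec.drugs_per_module_gene):
            drug = f"DRUG{drug_index}"
            drug_index += 1
            targets = {seed}
            if rng.random() < 0.3:
                targets.add(seeds[int(rng.integers(len(seeds)))])
            drug_targets[drug] = frozenset(targets)
            drug_approved[drug] = bool(rng.random() < 0.8)
    network = MechanismNetwork(
        graph=graph,
        drug_targets=drug_targets,
        drug_approved=drug_approved,
        seeds=frozenset(seeds),
    )
    return NetworkFixture(
        network=network, seeds=seeds, planted_connectors=(bridge,)
    )


def write_network_fixture(
    fixture: NetworkFixture, out_dir: str | os.PathLike
) -> None:
    """Serialize a network fixture as ppi.tsv, drug_targets.tsv, seeds.txt
    and ground_truth.json."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "ppi.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_a", "node_b", "weight"])
        for u, v, data in sorted(fixture.network.graph.edges(data=True)):
            w.writerow([u, v, f"{data.get('weight', 1.0):.6f}"])
    with open(os.path.join(out_dir, "drug_targets.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug_id", "protein_id", "approved"])
        for drug in sorted(fixture.network.drug_targets):
            for protein in sorted(fixture.network.drug_targets[drug]):
                w.writerow(
                    [drug, protein,
                     "1" if fixture.network.drug_approved.get(drug, True) else "0"]
                )
    with open(os.path.join(out_dir, "seeds.txt"), "w") as fh:
        fh.write("\n".join(fixture.seeds) + "\n")
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(
            {"planted_connectors": list(fixture.planted_connectors),
             "seeds": list(fixture.seeds)},
            fh, indent=2,
        )
        fh.write("\n")
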