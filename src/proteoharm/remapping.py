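"""Remapping protein groups to gene names.

Meta-analysis across studies that published gene symbols requires every
protein-level study to carry gene names too. ``remap_gene_names`` attaches a
gene-name group to each protein group under one of five modes:

``fasta``
    Names parsed from the ``GN=`` token of UniProt-dialect FASTA headers in a
    user-supplied reference file.
``uniprot``
    All annotated gene names (primary + synonyms) of each accession, kept
    only if the symbol is HGNC-listed according to the provider's gene table
    (symbols unknown to the gene table pass through — absence of a record is
    not evidence of absence from HGNC in a snapshot).
``uniprot_primary``
    Primary gene names only.
``uniprot_one``
    The single most frequent primary name across the whole group; ties break
    by group order, then lexicographically.
``all``
    FASTA first, accessions without a header-derived name filled from
    UniProt annotation.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, replace

from .data_model import (
    DetailLogRow,
    IdGroup,
    OverviewLogRow,
    Reason,
    StudyTable,
    replace_rows,
)
from .provider import AnnotationProvider

__all__ = [
    "RemapConfig",
    "parse_fasta_header",
    "read_fasta_gene_names",
    "remap_gene_names",
]

_MODES = ("fasta", "uniprot", "uniprot_primary", "uniprot_one", "all")

#: Column name used when the input table had no gene column.
DEFAULT_GENE_COLUMN = "Gene names"


@dataclass(frozen=True)
class RemapConfig:
    """Mode selection for gene-name remapping.

    ``skip_filled=False`` (default) overwrites pre-existing gene cells so all
    names come from one annotation snapshot; ``True`` leaves filled cells
    untouched and only fills gaps. ``fasta_path`` is required for the modes
    that read headers.
    """

    mode: str = "uniprot_primary"
    fasta_path: str | None = None
    keep_empty: bool = False
    skip_filled: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(
                f"unknown remap mode {self.mode!r}; choose from {_MODES}"
            )
        if self.mode in ("fasta", "all") and not self.fasta_path:
            raise ValueError(f"mode {self.mode!r} requires fasta_path")


def parse_fasta_header(header_line: str) -> tuple[str | None, str | None]:
    """Extract ``(accession, gene_name)`` from a UniProt-dialect header.

    Grammar: ``>db|ACCESSION|ENTRY description KEY=value ...`` where the
    ``GN=`` token is optional. Returns ``(None, None)`` for headers that do
    not follow the three-field pipe layout.
    """
    if not header_line.startswith(">"):
        raise ValueError("FASTA header must start with '>'")
    body = header_line[1:].strip()
    first_token = body.split(None, 1)[0] if body else ""
    fields = first_token.split("|")
    if len(fields) < 3 or not fields[1]:
        return None, None
    accession = fields[1]
    gene = None
    for token in body.split():
        if token.startswith("GN="):
            gene = token[3:] or None
            break
    return accession, gene


def read_fasta_gene_names(path: str | os.PathLike) -> dict[str, str]:
    """Scan a FASTA file's headers into an accession → gene-name map.

    Sequence lines are skipped untouched; headers without a ``GN=`` token or
    outside the UniProt dialect contribute nothing.
    """
    mapping: dict[str, str] = {}
    with open(os.fspath(path)) as fh:
        for line in fh:
            if line.startswith(">"):
                accession, gene = parse_fasta_header(line)
                if accession and gene and accession not in mapping:
                    mapping[accession] = gene
    return mapping


def _dedup(names: list[str]) -> tuple[str, ...]:
    seen: list[str] = []
    for n in names:
        if n and n not in seen:
            seen.append(n)
    return tuple(seen)


def _uniprot_names(record, gene_records, mode: str) -> list[str]:
    """Candidate names for one accession under a UniProt-backed mode."""
    if record is None:
        return []
    if mode in ("uniprot_primary", "uniprot_one"):
        return [record.primary_gene_name] if record.primary_gene_name else []
    names = []
    for name in record.all_gene_names():
        gene = gene_records.get(name)
        if gene is not None and not gene.in_hgnc:
            continue
        names.append(name)
    return names


def remap_gene_names(
    table: StudyTable,
    provider: AnnotationProvider,
    config: RemapConfig,
) -> tuple[StudyTable, list[OverviewLogRow], list[DetailLogRow]]:
    """Attach a gene-name group to every protein group of ``table``.

    The overview log accounts for the *gene* column: previous names that
    survive are kept, replaced ones are removed, new names appear as added.
    Accessions for which no name could be derived get a detail-log entry
    with reason ``no_gene_name``; rows ending up with an empty gene cell are
    dropped unless ``config.keep_empty``.
    """
    if table.id_column is None:
        raise ValueError(
            f"study {table.study_id!r} has no protein ID column; gene-name "
            "remapping needs protein accessions"
        )
    fasta_names = (
        read_fasta_gene_names(config.fasta_path)
        if config.mode in ("fasta", "all")
        else {}
    )
    accessions = sorted(
        {acc for row in table.rows if row.id_group for acc in row.id_group}
    )
    records = provider.lookup_proteins(accessions)
    all_names = sorted(
        {n for r in records.values() for n in r.all_gene_names()}
    )
    gene_records = provider.lookup_genes(all_names, table.organism)

    new_rows = []
    overview: list[OverviewLogRow] = []
    detail: list[DetailLogRow] = []
    for row in table.rows:
        previous = row.gene_group or IdGroup(separator=table.separator)
        if config.skip_filled and previous:
            new_rows.append(row)
            overview.append(
                OverviewLogRow(
                    row_id=row.row_id,
                    previous_ids=previous,
                    kept_ids=previous,
                    removed_ids=IdGroup(separator=table.separator),
                )
            )
            continue
        group = row.id_group or IdGroup(separator=table.separator)
        names: list[str] = []
        nameless: list[str] = []
        if config.mode == "uniprot_one":
            counts = Counter()
            order: list[str] = []
            for acc in group:
                for name in _uniprot_names(
                    records.get(acc), gene_records, config.mode
                ):
                    counts[name] += 1
                    if name not in order:
                        order.append(name)
                if records.get(acc) is None or not records[
                    acc
                ].primary_gene_name:
                    nameless.append(acc)
            if counts:
                best = max(counts.values())
                # tie-break: first appearance in group order, then lexicographic
                names = [
                    min(
                        (n for n in order if counts[n] == best),
                        key=lambda n: (order.index(n), n),
                    )
                ]
        else:
            for acc in group:
                candidates = []
                if config.mode in ("fasta", "all") and acc in fasta_names:
                    candidates = [fasta_names[acc]]
                if not candidates and config.mode != "fasta":
                    candidates = _uniprot_names(
                        records.get(acc), gene_records, config.mode
                    )
                if candidates:
                    names.extend(candidates)
                else:
                    nameless.append(acc)
        cell = _dedup(names)
        kept = tuple(n for n in previous if n in cell)
        removed = tuple(n for n in previous if n not in cell)
        added = _dedup([n for n in cell if n not in previous.ids])
        overview.append(
            OverviewLogRow(
                row_id=row.row_id,
                previous_ids=previous,
                kept_ids=IdGroup(kept, table.separator),
                removed_ids=IdGroup(removed, table.separator),
                added_ids=IdGroup(added, table.separator),
            )
        )
        for acc in nameless:
            detail.append(DetailLogRow(acc, Reason.NO_GENE_NAME))
        if cell or config.keep_empty:
            new_rows.append(
                replace(row, gene_group=IdGroup(cell, table.separator))
            )

    out = replace_rows(table, new_rows)
    if out.gene_column is None:
        out.gene_column = DEFAULT_GENE_COLUMN
    return out, overview, detail
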