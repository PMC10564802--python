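"""Reduction of synonym-laden gene cells to a single canonical namespace.

A gene may carry several published names, and different resources list
different primary symbols; left unreduced, two studies can report the same
gene under different names and their overlap goes undetected. This stage
collapses every gene cell to one namespace:

``ensembl``
    Keep names that have an Ensembl gene id and replace each by the symbol
    Ensembl itself lists for that gene (e.g. rat ``Ppia`` → ``Ppial4d``).
``hgnc``
    Keep names with an HGNC entry (human only).
``mygeneinfo``
    Keep names with a MyGene.info entry.
``enrichment``
    Keep names carrying a functional annotation.

Duplicates created by the reduction (two synonyms collapsing onto one
canonical symbol) are merged, which is exactly the redundancy the step
exists to prevent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .data_model import (
    DetailLogRow,
    IdGroup,
    OverviewLogRow,
    Reason,
    StudyTable,
    normalize_organism,
    replace_rows,
)
from .provider import AnnotationProvider

__all__ = ["ReduceConfig", "reduce_gene_names"]

_GROUNDS = ("ensembl", "hgnc", "mygeneinfo", "enrichment")


@dataclass(frozen=True)
class ReduceConfig:
    ground: str = "ensembl"
    organism: str = "human"
    keep_empty: bool = False

    def __post_init__(self) -> None:
        if self.ground not in _GROUNDS:
            raise ValueError(
                f"unknown reduction ground {self.ground!r}; choose from {_GROUNDS}"
            )
        object.__setattr__(self, "organism", normalize_organism(self.organism))
        if self.ground == "hgnc" and self.organism != "human":
            raise ValueError("HGNC reduction is only defined for human data")


def reduce_gene_names(
    table: StudyTable,
    provider: AnnotationProvider,
    config: ReduceConfig,
) -> tuple[StudyTable, list[OverviewLogRow], list[DetailLogRow]]:
    """Collapse every gene cell of ``table`` onto the configured namespace.

    Names outside the namespace are removed with reason
    ``not_in_namespace``; under ``ground=ensembl`` a name whose Ensembl
    symbol differs is logged as a removal (with ``replaced_by`` metadata)
    plus an addition of the canonical symbol, and a name already equal to
    its Ensembl symbol is a fixed point. Rows emptied by the reduction are
    dropped unless ``config.keep_empty``.
    """
    if table.gene_column is None:
        raise ValueError(
            f"study {table.study_id!r} has no gene column; run remapping first"
        )
    symbols = sorted(table.gene_symbols())
    gene_records = provider.lookup_genes(symbols, config.organism)

    new_rows = []
    overview: list[OverviewLogRow] = []
    detail: list[DetailLogRow] = []
    logged: set[tuple[int, str]] = set()
    for row in table.rows:
        previous = row.gene_group or IdGroup(separator=table.separator)
        kept: list[str] = []
        removed: list[str] = []
        cell: list[str] = []
        for name in previous:
            record = gene_records.get(name)
            if config.ground == "ensembl":
                if record is None or record.ensembl_symbol is None:
                    verdict = None
                elif record.ensembl_symbol == name:
                    verdict = name
                else:
                    verdict = record.ensembl_symbol
            else:
                if record is None:
                    flag = False
                elif config.ground == "hgnc":
                    flag = record.in_hgnc
                elif config.ground == "mygeneinfo":
                    flag = record.in_mygene
                else:
                    flag = record.has_functional_annotation
                verdict = name if flag else None
            if verdict is None:
                removed.append(name)
                if (row.row_id, name) not in logged:
                    logged.add((row.row_id, name))
                    detail.append(DetailLogRow(name, Reason.NOT_IN_NAMESPACE))
            elif verdict == name:
                kept.append(name)
                if name not in cell:
                    cell.append(name)
            else:  # renamed onto the canonical Ensembl symbol
                removed.append(name)
                if (row.row_id, name) not in logged:
                    logged.add((row.row_id, name))
                    detail.append(
                        DetailLogRow(
                            name,
                            Reason.NOT_IN_NAMESPACE,
                            (("replaced_by", verdict),),
                        )
                    )
                if verdict not in cell:
                    cell.append(verdict)
        added = tuple(
            n for n in cell if n not in previous.ids
        )
        overview.append(
            OverviewLogRow(
                row_id=row.row_id,
                previous_ids=previous,
                kept_ids=IdGroup(tuple(kept), table.separator),
                removed_ids=IdGroup(tuple(removed), table.separator),
                added_ids=IdGroup(added, table.separator),
            )
        )
        if cell or config.keep_empty:
            new_rows.append(
                replace(row, gene_group=IdGroup(tuple(cell), table.separator))
            )
    return replace_rows(table, new_rows), overview, detail
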