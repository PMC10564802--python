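"""Cross-organism gene-symbol translation through Ensembl gene ids.

Studies run in different model organisms report organism-specific symbols
(rat ``Serpinc1``, human ``SERPINC1``) that never intersect literally. This
stage maps every gene cell from the table's organism to a chosen target
organism in two steps: symbol → Ensembl gene id (via the provider's gene
table), then Ensembl homology pairs → target symbols. A row survives as long
as at least one member has an ortholog partner; symbols without a partner
are removed and logged with reason ``no_ortholog``.
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

__all__ = ["OrthologConfig", "map_orthologs"]


@dataclass(frozen=True)
class OrthologConfig:
    """Source and target organism for ortholog mapping.

    ``source == target`` is an explicit identity pass-through (no lookup, no
    log entries), useful when a pipeline maps a mixed study set onto one
    organism and some studies are already there.
    """

    source_organism: str
    target_organism: str
    keep_empty: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "source_organism", normalize_organism(self.source_organism)
        )
        object.__setattr__(
            self, "target_organism", normalize_organism(self.target_organism)
        )


def map_orthologs(
    table: StudyTable,
    provider: AnnotationProvider,
    config: OrthologConfig,
) -> tuple[StudyTable, list[OverviewLogRow], list[DetailLogRow]]:
    """Translate every gene cell of ``table`` into the target organism.

    One-to-many orthologs expand the cell (all targets kept, logged as
    additions); many-to-one collisions are deduplicated within a cell. The
    returned table's organism is the target organism. Rows where no member
    has a partner are dropped unless ``config.keep_empty``.
    """
    if table.gene_column is None:
        raise ValueError(
            f"study {table.study_id!r} has no gene column; ortholog mapping "
            "needs gene symbols"
        )
    if table.organism != config.source_organism:
        raise ValueError(
            f"table organism {table.organism!r} does not match configured "
            f"source organism {config.source_organism!r}"
        )
    if config.source_organism == config.target_organism:
        return table, [], []

    symbols = sorted(table.gene_symbols())
    mapping = provider.lookup_orthologs(
        symbols, config.source_organism, config.target_organism
    )

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
            targets = mapping.get(name, [])
            if targets:
                kept.append(name)
                for t in targets:
                    if t not in cell:
                        cell.append(t)
            else:
                removed.append(name)
                if (row.row_id, name) not in logged:
                    logged.add((row.row_id, name))
                    detail.append(DetailLogRow(name, Reason.NO_ORTHOLOG))
        added = tuple(n for n in cell if n not in previous.ids)
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
    out = replace_rows(table, new_rows)
    out.organism = config.target_organism
    return out, overview, detail
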