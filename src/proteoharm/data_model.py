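"""Core table and log types shared by all pipeline stages, plus study-table I/O.

A *study table* is one study's published hit list: an ordered set of rows,
each carrying a protein group (one or more accessions that could not be
distinguished by the identified peptides, MaxQuant-style ";"-separated) and/or
a gene-name group, plus any number of extra columns that the pipeline must
preserve verbatim. Every identifier-changing stage returns, next to the
altered table, an *overview log* (per-row loss/gain accounting) and a
*detail log* (per-identifier reason), so that the success of every conversion
step can be audited after the fact.
"""

from __future__ import annotations

import csv
import enum
import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "SUPPORTED_ORGANISMS",
    "normalize_organism",
    "IdGroup",
    "StudyRow",
    "StudyTable",
    "Reason",
    "OverviewLogRow",
    "DetailLogRow",
    "StepLog",
    "HarmonizationLog",
    "read_study_table",
    "write_study_table",
    "merge_logs",
]

#: Organisms the ortholog layer supports, keyed by canonical lowercase name.
SUPPORTED_ORGANISMS = ("human", "rat", "mouse", "rabbit")

#: NCBI taxon identifiers accepted as aliases for the canonical names.
_TAXON_ALIASES = {
    "9606": "human",
    "10116": "rat",
    "10090": "mouse",
    "9986": "rabbit",
}


def normalize_organism(organism: str | int) -> str:
    """Map an organism name or NCBI taxon id onto a canonical organism code.

    Raises ``ValueError`` for anything outside the supported set
    (human, rat, mouse, rabbit).
    """
    key = str(organism).strip().lower()
    key = _TAXON_ALIASES.get(key, key)
    if key not in SUPPORTED_ORGANISMS:
        raise ValueError(
            f"unsupported organism {organism!r}; supported: "
            f"{', '.join(SUPPORTED_ORGANISMS)} (or taxon ids "
            f"{', '.join(_TAXON_ALIASES)})"
        )
    return key


@dataclass(frozen=True)
class IdGroup:
    """An ordered group of identifiers sharing one table cell.

    Empty-string members are never stored; order is preserved from the input
    cell. Duplicates may arrive from upstream data but are never introduced
    by pipeline operations.
    """

    ids: tuple[str, ...] = ()
    separator: str = ";"

    def __post_init__(self) -> None:
        if any(i == "" for i in self.ids):
            raise ValueError("IdGroup may not contain empty-string members")
        object.__setattr__(self, "ids", tuple(self.ids))

    @classmethod
    def from_cell(cls, cell: str, separator: str = ";") -> "IdGroup":
        parts = [p.strip() for p in cell.split(separator)]
        return cls(tuple(p for p in parts if p), separator)

    def to_cell(self) -> str:
        return self.separator.join(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __bool__(self) -> bool:
        return bool(self.ids)


@dataclass(frozen=True)
class StudyRow:
    """One row of a study table.

    ``extra`` holds every non-group column byte-identically; ``source_cells``
    keeps the raw input text of the group columns so that ``add_column``
    output mode can emit the untouched originals next to the harmonized
    values.
    """

    row_id: int
    id_group: IdGroup | None = None
    gene_group: IdGroup | None = None
    extra: tuple[tuple[str, str], ...] = ()
    source_cells: tuple[tuple[str, str], ...] = ()

    @property
    def extra_map(self) -> dict[str, str]:
        return dict(self.extra)

    @property
    def source_map(self) -> dict[str, str]:
        return dict(self.source_cells)


@dataclass
class StudyTable:
    """A study's hit list plus the bookkeeping needed to write it back out.

    ``columns`` records the original column order; ``id_column`` /
    ``gene_column`` name which columns hold protein accessions and gene
    symbols respectively (either may be absent). ``row_id`` values are unique
    and stable: rows dropped by a stage disappear, surviving rows keep their
    id.
    """

    study_id: str
    organism: str
    rows: list[StudyRow]
    columns: tuple[str, ...]
    id_column: str | None = None
    gene_column: str | None = None
    separator: str = ";"

    def __post_init__(self) -> None:
        self.organism = normalize_organism(self.organism)
        ids = [r.row_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("row_ids must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    def gene_symbols(self) -> set[str]:
        """Union of all gene-cell members (exact string, case-sensitive)."""
        out: set[str] = set()
        for row in self.rows:
            if row.gene_group:
                out.update(row.gene_group.ids)
        return out


class Reason(str, enum.Enum):
    """Why an identifier was removed (or could not be produced) at a stage."""

    WRONG_ORGANISM = "wrong_organism"
    UNREVIEWED = "unreviewed"
    OBSOLETE = "obsolete"
    CONTAMINANT = "contaminant"
    DECOY = "decoy"
    NO_GENE_NAME = "no_gene_name"
    NOT_IN_NAMESPACE = "not_in_namespace"
    NO_ORTHOLOG = "no_ortholog"


@dataclass(frozen=True)
class OverviewLogRow:
    """Per-row loss/gain accounting for one identifier-changing stage.

    Invariants (enforced at construction): ``kept + removed == previous`` as
    multisets, hence ``n_previous == n_kept + n_removed``; added identifiers
    are disjoint from the previous ones.
    """

    row_id: int
    previous_ids: IdGroup
    kept_ids: IdGroup
    removed_ids: IdGroup
    added_ids: IdGroup = field(default_factory=IdGroup)

    def __post_init__(self) -> None:
        if sorted(self.kept_ids.ids + self.removed_ids.ids) != sorted(
            self.previous_ids.ids
        ):
            raise ValueError(
                f"row {self.row_id}: kept + removed must equal previous as multisets"
            )
        if set(self.added_ids.ids) & set(self.previous_ids.ids):
            raise ValueError(f"row {self.row_id}: added ids overlap previous ids")

    @property
    def n_previous(self) -> int:
        return len(self.previous_ids)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    @property
    def n_added(self) -> int:
        return len(self.added_ids)


@dataclass(frozen=True)
class DetailLogRow:
    """One removed/affected identifier with the reason and any annotation."""

    identifier: str
    reason: Reason
    metadata: tuple[tuple[str, str], ...] = ()

    @property
    def metadata_map(self) -> dict[str, str]:
        return dict(self.metadata)


@dataclass(frozen=True)
class StepLog:
    """The paired overview/detail log of one named pipeline step."""

    step: str
    overview: tuple[OverviewLogRow, ...]
    detail: tuple[DetailLogRow, ...]

    def summary(self) -> dict[str, int]:
        return {
            "n_rows": len(self.overview),
            "n_previous": sum(r.n_previous for r in self.overview),
            "n_kept": sum(r.n_kept for r in self.overview),
            "n_removed": sum(r.n_removed for r in self.overview),
            "n_added": sum(r.n_added for r in self.overview),
        }


@dataclass
class HarmonizationLog:
    """Ordered concatenation of per-step logs for one pipeline run."""

    steps: list[StepLog] = field(default_factory=list)

    def append(
        self,
        step: str,
        overview: Sequence[OverviewLogRow],
        detail: Sequence[DetailLogRow],
    ) -> None:
        self.steps.append(StepLog(step, tuple(overview), tuple(detail)))

    def summary(self) -> dict[str, dict[str, int]]:
        return {s.step: s.summary() for s in self.steps}

    def write(self, prefix: str | os.PathLike) -> None:
        """Serialize as ``<prefix>_overview.tsv``, ``<prefix>_detail.tsv`` and
        ``<prefix>_summary.json``."""
        prefix = os.fspath(prefix)
        with open(f"{prefix}_overview.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                [
                    "step",
                    "row_id",
                    "previous_ids",
                    "kept_ids",
                    "removed_ids",
                    "added_ids",
                    "n_previous",
                    "n_kept",
                    "n_removed",
                    "n_added",
                ]
            )
            for s in self.steps:
                for r in s.overview:
                    w.writerow(
                        [
                            s.step,
                            r.row_id,
                            r.previous_ids.to_cell(),
                            r.kept_ids.to_cell(),
                            r.removed_ids.to_cell(),
                            r.added_ids.to_cell(),
                            r.n_previous,
                            r.n_kept,
                            r.n_removed,
                            r.n_added,
                        ]
                    )
        with open(f"{prefix}_detail.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["step", "identifier", "reason", "metadata"])
            for s in self.steps:
                for d in s.detail:
                    meta = ";".join(f"{k}={v}" for k, v in d.metadata)
                    w.writerow([s.step, d.identifier, d.reason.value, meta])
        with open(f"{prefix}_summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def merge_logs(
    step_logs: Iterable[
        tuple[str, Sequence[OverviewLogRow], Sequence[DetailLogRow]]
    ],
) -> HarmonizationLog:
    """Concatenate (step_name, overview, detail) triples into one log,
    preserving pipeline order."""
    log = HarmonizationLog()
    for step, overview, detail in step_logs:
        log.append(step, overview, detail)
    return log


def _dialect_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.lower().endswith(".csv") else "\t"


def read_study_table(
    path: str | os.PathLike,
    id_column_name: str | None = None,
    *,
    gene_column_name: str | None = None,
    separator: str = ";",
    organism: str = "human",
    study_id: str | None = None,
    delimiter: str | None = None,
) -> StudyTable:
    """Read a TSV/CSV study file into a :class:`StudyTable`.

    The cell of ``id_column_name`` (and of ``gene_column_name``, if given) is
    split on ``separator`` into an :class:`IdGroup`; every other column is
    preserved verbatim in ``extra``. The dialect is sniffed from the file
    extension (``.csv`` → comma, anything else → tab) unless ``delimiter``
    overrides it. Empty cells parse to an empty group — the downstream
    ``keep_empty`` switch decides their fate, not the reader.
    """
    path = os.fspath(path)
    delim = _dialect_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        for name in (id_column_name, gene_column_name):
            if name is not None and name not in header:
                raise ValueError(
                    f"{path}: column {name!r} not found; available columns: "
                    f"{', '.join(header)}"
                )
        special = {c for c in (id_column_name, gene_column_name) if c}
        rows: list[StudyRow] = []
        for row_id, record in enumerate(reader):
            record += [""] * (len(header) - len(record))
            cells = dict(zip(header, record))
            rows.append(
                StudyRow(
                    row_id=row_id,
                    id_group=(
                        IdGroup.from_cell(cells[id_column_name], separator)
                        if id_column_name
                        else None
                    ),
                    gene_group=(
                        IdGroup.from_cell(cells[gene_column_name], separator)
                        if gene_column_name
                        else None
                    ),
                    extra=tuple(
                        (c, cells[c]) for c in header if c not in special
                    ),
                    source_cells=tuple((c, cells[c]) for c in sorted(special)),
                )
            )
    return StudyTable(
        study_id=study_id or os.path.splitext(os.path.basename(path))[0],
        organism=organism,
        rows=rows,
        columns=tuple(header),
        id_column=id_column_name,
        gene_column=gene_column_name,
        separator=separator,
    )


#: Suffix appended to the harmonized column in ``add_column`` output mode.
ADD_COLUMN_SUFFIX = "_harmonized"


def write_study_table(
    table: StudyTable,
    path: str | os.PathLike,
    mode: str = "replace",
    *,
    delimiter: str | None = None,
) -> None:
    """Write a study table back to TSV/CSV.

    ``mode="replace"`` overwrites the original ID/gene columns in place;
    ``mode="add_column"`` appends ``<column>_harmonized`` columns carrying the
    current groups and re-emits the original input cells untouched. A group
    column that did not exist in the input (e.g. a gene column created by
    remapping) is emitted once under its plain name in either mode.
    """
    if mode not in ("replace", "add_column"):
        raise ValueError(f"unknown output mode {mode!r}")
    path = os.fspath(path)
    delim = _dialect_delimiter(path, delimiter)

    group_cols: dict[str, object] = {}
    if table.id_column:
        group_cols[table.id_column] = lambda r: (
            r.id_group.to_cell() if r.id_group else ""
        )
    if table.gene_column:
        group_cols[table.gene_column] = lambda r: (
            r.gene_group.to_cell() if r.gene_group else ""
        )

    header = list(table.columns)
    new_cols = [c for c in group_cols if c not in header]
    header += new_cols
    if mode == "add_column":
        header += [
            f"{c}{ADD_COLUMN_SUFFIX}" for c in group_cols if c not in new_cols
        ]

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(header)
        for row in table.rows:
            extra = row.extra_map
            source = row.source_map
            record = []
            for col in header:
                if col.endswith(ADD_COLUMN_SUFFIX) and mode == "add_column":
                    record.append(group_cols[col[: -len(ADD_COLUMN_SUFFIX)]](row))
                elif col in group_cols:
                    if mode == "add_column" and col in source:
                        record.append(source[col])
                    else:
                        record.append(group_cols[col](row))
                elif col in extra:
                    record.append(extra[col])
                else:
                    record.append("")
            w.writerow(record)


def replace_rows(table: StudyTable, rows: list[StudyRow]) -> StudyTable:
    """Return a copy of ``table`` with a new row list (helper for stages)."""
    return StudyTable(
        study_id=table.study_id,
        organism=table.organism,
        rows=rows,
        columns=table.columns,
        id_column=table.id_column,
        gene_column=table.gene_column,
        separator=table.separator,
    )
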