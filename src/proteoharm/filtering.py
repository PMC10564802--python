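"""Quality filtering of protein accessions inside protein groups.

Published hit lists routinely contain accessions that should not enter a
meta-analysis: entries assigned to the wrong organism (spurious cross-species
matches of highly similar sequences), unreviewed (TrEMBL) entries, accessions
retired in newer UniProt releases, and MaxQuant's bookkeeping entries —
reversed-sequence decoys flagged ``REV__`` and sample-handling contaminants
flagged ``CON__``. ``filter_protein_ids`` removes them per user-selected mode
and logs every removal with its reason.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .data_model import (
    IdGroup,
    DetailLogRow,
    OverviewLogRow,
    Reason,
    StudyTable,
    normalize_organism,
    replace_rows,
)
from .provider import AnnotationProvider, ProteinRecord

__all__ = ["FilterConfig", "classify_id", "filter_protein_ids", "strip_flag"]

DECOY_PREFIX = "REV__"
CONTAMINANT_PREFIX = "CON__"

_VALID_MODES = frozenset({"organism_based", "reviewed_based", "decoy_based"})


@dataclass(frozen=True)
class FilterConfig:
    """Which checks to run and what to do with emptied rows.

    modes
        Any nonempty subset of ``organism_based`` (drop accessions annotated
        to another organism than ``target_organism``), ``reviewed_based``
        (drop TrEMBL/unreviewed entries) and ``decoy_based`` (drop ``REV__``
        decoys and ``CON__`` contaminants).
    keep_empty
        Retain rows whose whole group was removed (default: drop them).
    output_mode
        ``replace`` overwrites the ID column on write; ``add_column`` appends
        a harmonized copy.
    """

    modes: frozenset[str]
    target_organism: str | None = None
    keep_empty: bool = False
    output_mode: str = "replace"

    def __post_init__(self) -> None:
        modes = frozenset(self.modes)
        if not modes:
            raise ValueError("at least one filtering mode is required")
        unknown = modes - _VALID_MODES
        if unknown:
            raise ValueError(f"unknown filtering modes: {sorted(unknown)}")
        object.__setattr__(self, "modes", modes)
        if "organism_based" in modes:
            if self.target_organism is None:
                raise ValueError(
                    "organism_based filtering requires target_organism"
                )
            object.__setattr__(
                self, "target_organism", normalize_organism(self.target_organism)
            )
        if self.output_mode not in ("replace", "add_column"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")


def strip_flag(accession: str) -> tuple[str, str | None]:
    """Split a MaxQuant flag prefix off an accession.

    Returns ``(bare_accession, flag)`` where flag is ``"decoy"``,
    ``"contaminant"`` or ``None``. Decoy takes precedence on stacked
    prefixes (``REV__CON__...``).
    """
    if accession.startswith(DECOY_PREFIX):
        return accession[len(DECOY_PREFIX):].removeprefix(
            CONTAMINANT_PREFIX
        ), "decoy"
    if accession.startswith(CONTAMINANT_PREFIX):
        return accession[len(CONTAMINANT_PREFIX):], "contaminant"
    return accession, None


def classify_id(
    accession: str,
    record: ProteinRecord | None,
    config: FilterConfig,
) -> str:
    """Classify one accession as ``keep`` or a removal reason.

    Checks run in fixed precedence — decoy → contaminant → obsolete/unknown →
    wrong organism → unreviewed — and the first failing check wins, so every
    removed accession carries exactly one reason. Flag prefixes are stripped
    before any provider-backed check.
    """
    _, flag = strip_flag(accession)
    if "decoy_based" in config.modes:
        if flag == "decoy":
            return Reason.DECOY.value
        if flag == "contaminant":
            return Reason.CONTAMINANT.value
    provider_modes = config.modes & {"organism_based", "reviewed_based"}
    if provider_modes:
        # Unknown accessions are indistinguishable from retired ones in a
        # frozen snapshot; both classify as obsolete.
        if record is None or record.obsolete:
            return Reason.OBSOLETE.value
        if (
            "organism_based" in config.modes
            and record.organism != config.target_organism
        ):
            return Reason.WRONG_ORGANISM.value
        if "reviewed_based" in config.modes and not record.reviewed:
            return Reason.UNREVIEWED.value
    return "keep"


def filter_protein_ids(
    table: StudyTable,
    provider: AnnotationProvider,
    config: FilterConfig,
) -> tuple[StudyTable, list[OverviewLogRow], list[DetailLogRow]]:
    """Remove bad-quality accessions from every protein group of ``table``.

    Rows whose whole group is removed are dropped unless
    ``config.keep_empty``; surviving rows keep their ``row_id`` and their
    extra columns verbatim. Raises ``ValueError`` on a gene-only table:
    filtering operates on protein accessions only.
    """
    if table.id_column is None:
        raise ValueError(
            f"study {table.study_id!r} has no protein ID column; filtering "
            "of protein IDs cannot be performed on gene-only data"
        )

    bare_accessions = sorted(
        {
            strip_flag(acc)[0]
            for row in table.rows
            if row.id_group
            for acc in row.id_group
        }
    )
    records = provider.lookup_proteins(bare_accessions)

    new_rows = []
    overview: list[OverviewLogRow] = []
    detail: list[DetailLogRow] = []
    logged: set[tuple[int, str]] = set()
    for row in table.rows:
        group = row.id_group or IdGroup(separator=table.separator)
        kept, removed = [], []
        for acc in group:
            bare, _ = strip_flag(acc)
            verdict = classify_id(acc, records.get(bare), config)
            if verdict == "keep":
                kept.append(acc)
            else:
                removed.append(acc)
                # duplicate occurrences within one group are logged once
                if (row.row_id, acc) not in logged:
                    logged.add((row.row_id, acc))
                    record = records.get(bare)
                    meta = []
                    if verdict == Reason.OBSOLETE.value and record is None:
                        meta.append(("note", "not found"))
                    if record is not None and record.organism:
                        meta.append(("annotated_organism", record.organism))
                    detail.append(
                        DetailLogRow(acc, Reason(verdict), tuple(meta))
                    )
        overview.append(
            OverviewLogRow(
                row_id=row.row_id,
                previous_ids=IdGroup(tuple(group.ids), table.separator),
                kept_ids=IdGroup(tuple(kept), table.separator),
                removed_ids=IdGroup(tuple(removed), table.separator),
            )
        )
        if kept or config.keep_empty:
            new_rows.append(
                replace(row, id_group=IdGroup(tuple(kept), table.separator))
            )
    return replace_rows(table, new_rows), overview, detail
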