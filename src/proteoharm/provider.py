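"""Pluggable annotation lookup: protein records, gene namespaces, orthologs.

All annotation knowledge the pipeline needs — UniProt-style protein records
(organism, review status, obsolescence, gene names), gene namespace
membership (Ensembl / HGNC / MyGene.info / functional annotation), and
Ensembl-mediated ortholog pairs — is reached through one contract,
:class:`AnnotationProvider`. Pipeline stages never contact a network service;
the bundled :class:`LocalTableProvider` answers every lookup from three flat
TSV snapshots (``proteins.tsv``, ``genes.tsv``, ``orthologs.tsv``), which
keeps every run reproducible against a frozen annotation release.

Lookups are pure: the same input always yields the same output, absence is
data (``None`` / empty list), never an error.
"""

from __future__ import annotations

import abc
import os
from dataclasses import dataclass

import pandas as pd

from .data_model import normalize_organism

__all__ = [
    "ProteinRecord",
    "GeneRecord",
    "OrthologPair",
    "AnnotationProvider",
    "LocalTableProvider",
    "MappingProvider",
    "load_provider",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A UniProt-style protein entry snapshot.

    Obsolete records (accessions retired in newer releases) may lack every
    other annotation; a present ``primary_gene_name`` is never empty.
    """

    accession: str
    organism: str | None = None
    reviewed: bool = False
    obsolete: bool = False
    primary_gene_name: str | None = None
    gene_name_synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.primary_gene_name == "":
            object.__setattr__(self, "primary_gene_name", None)

    def all_gene_names(self) -> tuple[str, ...]:
        names = []
        if self.primary_gene_name:
            names.append(self.primary_gene_name)
        names += [s for s in self.gene_name_synonyms if s not in names]
        return tuple(names)


@dataclass(frozen=True)
class GeneRecord:
    """Namespace membership of one gene symbol in one organism.

    ``ensembl_symbol`` is present exactly when ``ensembl_id`` is: the symbol
    a gene is listed under by Ensembl only exists for genes Ensembl knows.
    """

    symbol: str
    organism: str
    ensembl_id: str | None = None
    ensembl_symbol: str | None = None
    in_hgnc: bool = False
    in_mygene: bool = False
    has_functional_annotation: bool = False

    def __post_init__(self) -> None:
        if bool(self.ensembl_id) != bool(self.ensembl_symbol):
            raise ValueError(
                f"gene {self.symbol!r}: ensembl_symbol must be present "
                "iff ensembl_id is present"
            )


@dataclass(frozen=True)
class OrthologPair:
    """One Ensembl homology edge between two organisms' genes."""

    source_ensembl_id: str
    source_organism: str
    target_organism: str
    target_ensembl_id: str
    target_symbol: str

    def __post_init__(self) -> None:
        if self.source_organism == self.target_organism:
            raise ValueError("ortholog pair requires two distinct organisms")


class AnnotationProvider(abc.ABC):
    """Lookup contract every pipeline stage depends on.

    Implementations must be pure (repeated calls identical) and must treat
    unknown identifiers as absence, not as an error.
    """

    @abc.abstractmethod
    def lookup_proteins(
        self, accessions: list[str]
    ) -> dict[str, ProteinRecord]:
        """Map each known accession to its record; unknowns are omitted."""

    @abc.abstractmethod
    def lookup_genes(
        self, symbols: list[str], organism: str
    ) -> dict[str, GeneRecord]:
        """Map each known (case-sensitive) symbol to its record for one
        organism; unknowns are omitted."""

    def lookup_orthologs(
        self, symbols: list[str], source_organism: str, target_organism: str
    ) -> dict[str, list[str]]:
        """Two-step ortholog mapping: symbol → Ensembl gene id → target
        symbols. Symbols without an Ensembl id or without pairs map to an
        empty list."""
        source = normalize_organism(source_organism)
        target = normalize_organism(target_organism)
        genes = self.lookup_genes(symbols, source)
        out: dict[str, list[str]] = {}
        for symbol in symbols:
            record = genes.get(symbol)
            if record is None or record.ensembl_id is None:
                out[symbol] = []
            else:
                out[symbol] = self._ortholog_targets(
                    record.ensembl_id, source, target
                )
        return out

    @abc.abstractmethod
    def _ortholog_targets(
        self, source_ensembl_id: str, source_organism: str, target_organism: str
    ) -> list[str]:
        """Target symbols for one source Ensembl id (ordered, deduplicated)."""


def _parse_bool(value: str, path: str, line: int, column: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise ValueError(
        f"{path}, line {line}: column {column!r} must be 0 or 1, got {value!r}"
    )


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"provider file missing: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {', '.join(missing)}")
    return frame


class LocalTableProvider(AnnotationProvider):
    """Provider backed by three flat TSV snapshots in one directory.

    Expected files and headers::

        proteins.tsv   accession organism reviewed obsolete primary_gene_name synonyms
        genes.tsv      symbol organism ensembl_id ensembl_symbol in_hgnc in_mygene has_annotation
        orthologs.tsv  source_ensembl_id source_organism target_organism target_ensembl_id target_symbol

    Booleans are 0/1; synonyms are "|"-joined. Every row is validated against
    the record invariants at load time; a malformed row is a hard error
    naming the file and line.
    """

    def __init__(self, directory: str | os.PathLike):
        directory = os.fspath(directory)
        self.directory = directory
        self._proteins = self._load_proteins(
            os.path.join(directory, "proteins.tsv")
        )
        self._genes = self._load_genes(os.path.join(directory, "genes.tsv"))
        self._orthologs = self._load_orthologs(
            os.path.join(directory, "orthologs.tsv")
        )

    @staticmethod
    def _load_proteins(path: str) -> dict[str, ProteinRecord]:
        frame = _read_tsv(
            path,
            [
                "accession",
                "organism",
                "reviewed",
                "obsolete",
                "primary_gene_name",
                "synonyms",
            ],
        )
        records: dict[str, ProteinRecord] = {}
        for i, row in enumerate(frame.itertuples(index=False), start=2):
            if row.accession in records:
                raise ValueError(
                    f"{path}, line {i}: duplicate accession {row.accession!r}"
                )
            try:
                organism = (
                    normalize_organism(row.organism) if row.organism else None
                )
                records[row.accession] = ProteinRecord(
                    accession=row.accession,
                    organism=organism,
                    reviewed=_parse_bool(row.reviewed, path, i, "reviewed"),
                    obsolete=_parse_bool(row.obsolete, path, i, "obsolete"),
                    primary_gene_name=row.primary_gene_name or None,
                    gene_name_synonyms=tuple(
                        s for s in row.synonyms.split("|") if s
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from None
        return records

    @staticmethod
    def _load_genes(path: str) -> dict[tuple[str, str], GeneRecord]:
        frame = _read_tsv(
            path,
            [
                "symbol",
                "organism",
                "ensembl_id",
                "ensembl_symbol",
                "in_hgnc",
                "in_mygene",
                "has_annotation",
            ],
        )
        records: dict[tuple[str, str], GeneRecord] = {}
        for i, row in enumerate(frame.itertuples(index=False), start=2):
            try:
                organism = normalize_organism(row.organism)
                key = (row.symbol, organism)
                if key in records:
                    raise ValueError(
                        f"duplicate gene row {row.symbol!r}/{organism}"
                    )
                records[key] = GeneRecord(
                    symbol=row.symbol,
                    organism=organism,
                    ensembl_id=row.ensembl_id or None,
                    ensembl_symbol=row.ensembl_symbol or None,
                    in_hgnc=_parse_bool(row.in_hgnc, path, i, "in_hgnc"),
                    in_mygene=_parse_bool(row.in_mygene, path, i, "in_mygene"),
                    has_functional_annotation=_parse_bool(
                        row.has_annotation, path, i, "has_annotation"
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from None
        return records

    @staticmethod
    def _load_orthologs(
        path: str,
    ) -> dict[tuple[str, str, str], list[OrthologPair]]:
        frame = _read_tsv(
            path,
            [
                "source_ensembl_id",
                "source_organism",
                "target_organism",
                "target_ensembl_id",
                "target_symbol",
            ],
        )
        pairs: dict[tuple[str, str, str], list[OrthologPair]] = {}
        for i, row in enumerate(frame.itertuples(index=False), start=2):
            try:
                pair = OrthologPair(
                    source_ensembl_id=row.source_ensembl_id,
                    source_organism=normalize_organism(row.source_organism),
                    target_organism=normalize_organism(row.target_organism),
                    target_ensembl_id=row.target_ensembl_id,
                    target_symbol=row.target_symbol,
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from None
            key = (
                pair.source_ensembl_id,
                pair.source_organism,
                pair.target_organism,
            )
            pairs.setdefault(key, []).append(pair)
        return pairs

    def lookup_proteins(
        self, accessions: list[str]
    ) -> dict[str, ProteinRecord]:
        return {a: self._proteins[a] for a in accessions if a in self._proteins}

    def lookup_genes(
        self, symbols: list[str], organism: str
    ) -> dict[str, GeneRecord]:
        organism = normalize_organism(organism)
        out = {}
        for symbol in symbols:
            record = self._genes.get((symbol, organism))
            if record is not None:
                out[symbol] = record
        return out

    def _ortholog_targets(
        self, source_ensembl_id: str, source_organism: str, target_organism: str
    ) -> list[str]:
        pairs = self._orthologs.get(
            (source_ensembl_id, source_organism, target_organism), []
        )
        seen: list[str] = []
        for pair in pairs:
            if pair.target_symbol not in seen:
                seen.append(pair.target_symbol)
        return seen


class MappingProvider(AnnotationProvider):
    """In-memory provider built from record collections.

    Convenient for constructing small curated annotation sets in code; the
    fixture generator uses it as the staging structure before serializing to
    the three-TSV layout that :class:`LocalTableProvider` reads.
    """

    def __init__(
        self,
        proteins: list[ProteinRecord] = (),
        genes: list[GeneRecord] = (),
        orthologs: list[OrthologPair] = (),
    ):
        self._proteins = {p.accession: p for p in proteins}
        self._genes = {(g.symbol, g.organism): g for g in genes}
        self._orthologs: dict[tuple[str, str, str], list[OrthologPair]] = {}
        for pair in orthologs:
            key = (
                pair.source_ensembl_id,
                pair.source_organism,
                pair.target_organism,
            )
            self._orthologs.setdefault(key, []).append(pair)

    lookup_proteins = LocalTableProvider.lookup_proteins
    lookup_genes = LocalTableProvider.lookup_genes
    _ortholog_targets = LocalTableProvider._ortholog_targets

    @property
    def proteins(self) -> list[ProteinRecord]:
        return list(self._proteins.values())

    @property
    def genes(self) -> list[GeneRecord]:
        return list(self._genes.values())

    @property
    def ortholog_pairs(self) -> list[OrthologPair]:
        return [p for pairs in self._orthologs.values() for p in pairs]


def load_provider(directory: str | os.PathLike) -> LocalTableProvider:
    """Load and validate a local-TSV annotation provider from ``directory``."""
    return LocalTableProvider(directory)
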