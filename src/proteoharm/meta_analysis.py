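"""Intersection analysis across harmonized studies.

Once every study reports genes in one shared namespace and organism, the
meta-analysis reduces to exact set arithmetic: which genes occur in how many
studies. Genes are rated by occurrence count; only genes found in at least
``min_studies`` studies (default 2) are reported. Membership is per study as
a set — a gene present in ten rows of one study counts that study once.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import pandas as pd

from .data_model import StudyTable

__all__ = [
    "IntersectionResult",
    "study_gene_set",
    "intersect_studies",
    "intersection_matrix",
    "write_intersection",
]


@dataclass
class IntersectionResult:
    """Gene → study-membership map at a given occurrence threshold.

    ``genes`` maps each reported gene to the frozen set of study ids it was
    found in; ``count(gene) == len(genes[gene]) >= min_studies`` always
    holds. ``ranked()`` orders count-descending, then lexicographically.
    """

    genes: dict[str, frozenset[str]]
    min_studies: int
    study_ids: tuple[str, ...] = ()

    def count(self, gene: str) -> int:
        return len(self.genes[gene])

    def ranked(self) -> list[tuple[str, int, tuple[str, ...]]]:
        return [
            (g, len(s), tuple(sorted(s)))
            for g, s in sorted(
                self.genes.items(), key=lambda kv: (-len(kv[1]), kv[0])
            )
        ]

    def __len__(self) -> int:
        return len(self.genes)


def study_gene_set(table: StudyTable) -> set[str]:
    """Flatten a study table into its set of gene symbols.

    Exact-string and case-sensitive: pre-harmonization rat ``Serpinc1`` and
    human ``SERPINC1`` deliberately do not match.
    """
    if table.gene_column is None:
        raise ValueError(
            f"study {table.study_id!r} has no gene column; harmonize first"
        )
    return table.gene_symbols()


def intersect_studies(
    tables: list[StudyTable],
    min_studies: int = 2,
    allow_mixed_organisms: bool = False,
) -> IntersectionResult:
    """Count per-gene study membership over ≥2 harmonized studies.

    Raises ``ValueError`` if the tables disagree on organism — symbols from
    different organisms live in different namespaces and must be mapped to
    orthologs first. ``allow_mixed_organisms=True`` disables that guard for
    the deliberate "what would we have found without harmonization"
    comparison, where unmapped published lists are intersected literally.
    """
    if len(tables) < 2:
        raise ValueError("intersection analysis needs at least two studies")
    if min_studies < 2:
        raise ValueError("min_studies must be at least 2")
    organisms = {t.organism for t in tables}
    if len(organisms) > 1 and not allow_mixed_organisms:
        raise ValueError(
            f"studies span multiple organisms ({', '.join(sorted(organisms))}); "
            "map orthologs before intersecting"
        )
    study_ids = [t.study_id for t in tables]
    if len(set(study_ids)) != len(study_ids):
        raise ValueError("study_ids must be unique")
    membership: dict[str, set[str]] = {}
    for table in tables:
        for gene in study_gene_set(table):
            membership.setdefault(gene, set()).add(table.study_id)
    return IntersectionResult(
        genes={
            g: frozenset(s)
            for g, s in membership.items()
            if len(s) >= min_studies
        },
        min_studies=min_studies,
        study_ids=tuple(study_ids),
    )


def intersection_matrix(
    result: IntersectionResult,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Binary gene × study membership matrix plus per-combination counts.

    Rows (genes) are in ranked order, columns in the study order of the
    intersection call; each row sums to that gene's occurrence count, and
    the combination counts sum to the number of reported genes.
    """
    studies = list(result.study_ids)
    ranked = result.ranked()
    matrix = pd.DataFrame(
        [[1 if s in result.genes[g] else 0 for s in studies] for g, _, _ in ranked],
        index=[g for g, _, _ in ranked],
        columns=studies,
        dtype=int,
    )
    combos: dict[tuple[str, ...], int] = {}
    for gene, _, members in ranked:
        combos[members] = combos.get(members, 0) + 1
    return matrix, combos


def write_intersection(
    result: IntersectionResult, out_dir: str | os.PathLike
) -> None:
    """Write the ranked gene list and the binary membership matrix as TSV."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    with open(
        os.path.join(out_dir, "intersection_ranked.tsv"), "w", newline=""
    ) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "count", "studies"])
        for gene, count, members in result.ranked():
            w.writerow([gene, count, ";".join(members)])
    matrix, _ = intersection_matrix(result)
    matrix.to_csv(
        os.path.join(out_dir, "intersection_matrix.tsv"),
        sep="\t",
        index_label="gene",
    )
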