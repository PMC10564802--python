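"""Convenience pipelines composing the harmonization stages.

The per-study stage sequence depends on what a study published: protein
groups are filtered, remapped to gene names and reduced before ortholog
mapping, while gene-only studies go straight to ortholog mapping. These
helpers encode that dispatch once, for the library, the CLI examples and
the tests alike.
"""

from __future__ import annotations

from .data_model import HarmonizationLog, StudyTable
from .filtering import FilterConfig, filter_protein_ids
from .orthologs import OrthologConfig, map_orthologs
from .provider import AnnotationProvider
from .reduction import ReduceConfig, reduce_gene_names
from .remapping import RemapConfig, remap_gene_names

__all__ = ["harmonize_study"]


def harmonize_study(
    table: StudyTable,
    provider: AnnotationProvider,
    target_organism: str = "human",
    filter_modes: frozenset[str] = frozenset({"organism_based", "decoy_based"}),
    remap_mode: str = "uniprot_primary",
    reduce_ground: str = "ensembl",
    keep_empty: bool = False,
) -> tuple[StudyTable, HarmonizationLog]:
    """Run the full harmonization cascade on one study.

    Protein studies: filter → remap → reduce → orthologs; gene-only
    studies: orthologs only (their published symbols are taken as-is, since
    no protein evidence exists to re-derive them from). The ortholog stage
    is an identity pass-through when the study is already in the target
    organism. Returns the harmonized table plus the merged step log.
    """
    log = HarmonizationLog()
    if table.id_column is not None:
        table, overview, detail = filter_protein_ids(
            table,
            provider,
            FilterConfig(
                modes=filter_modes,
                target_organism=table.organism,
                keep_empty=keep_empty,
            ),
        )
        log.append("filter", overview, detail)
        table, overview, detail = remap_gene_names(
            table, provider, RemapConfig(mode=remap_mode, keep_empty=keep_empty)
        )
        log.append("remap", overview, detail)
        table, overview, detail = reduce_gene_names(
            table,
            provider,
            ReduceConfig(
                ground=reduce_ground,
                organism=table.organism,
                keep_empty=keep_empty,
            ),
        )
        log.append("reduce", overview, detail)
    table, overview, detail = map_orthologs(
        table,
        provider,
        OrthologConfig(
            source_organism=table.organism,
            target_organism=target_organism,
            keep_empty=keep_empty,
        ),
    )
    log.append("orthologs", overview, detail)
    return table, log
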