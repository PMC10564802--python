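# proteoharm

Harmonization of multi-study protein/gene identifier lists, intersection
meta-analysis, and network-based mechanism mining with drug-repurposing
candidate ranking.

## The problem

Published proteomics hit lists are hard to compare across studies: different
groups report protein groups (MaxQuant-style `;`-separated accessions),
single accessions, or bare gene symbols; data come from different model
organisms (human, rat, mouse, rabbit); and lists are contaminated with
wrong-organism accessions, unreviewed (TrEMBL) entries, retired (obsolete)
accessions, and MaxQuant bookkeeping entries — reversed-sequence decoys
(`REV__`) and sample-handling contaminants (`CON__`). Taken literally, a rat
`Serpinc1` never intersects a human `SERPINC1`, so naive meta-analysis
undercounts shared biomarker candidates.

`proteoharm` converts heterogeneous study lists into one shared namespace
in four audited stages, each returning the altered table **plus** a paired
log (per-row loss/gain accounting and a per-identifier reason), so every
conversion can be checked after the fact:

1. **Filtering** — remove wrong-organism / unreviewed / obsolete /
   decoy / contaminant accessions from protein groups (reason precedence:
   decoy → contaminant → obsolete → wrong organism → unreviewed).
2. **Remapping** — attach gene names to protein groups (FASTA `GN=`
   headers, all annotated names, primary names only, the single most
   frequent name in a group, or FASTA-first with annotation gap-filling).
3. **Reduction** — collapse synonym-laden gene cells onto one canonical
   namespace (Ensembl symbol, HGNC, MyGene.info, or
   functional-annotation membership), e.g. rat `Ppia` → `Ppial4d`.
4. **Ortholog mapping** — translate symbols between organisms in two
   steps (symbol → Ensembl gene id → target-organism symbols); a row
   survives as long as at least one member has an ortholog partner.

Harmonized studies feed an **intersection analysis** (genes rated by the
number of studies they occur in, membership counted per study as a set) and
a **network stage**: biomarker candidates become seeds on a protein–protein
interaction graph, a Multi-Steiner-Tree search finds the connector proteins
joining them, and drugs targeting the resulting mechanism are ranked by
TrustRank or by degree/closeness/harmonic/betweenness centrality.

All annotation knowledge (protein records, gene namespaces, ortholog pairs)
is reached through a provider contract backed by three flat TSV snapshots —
no pipeline stage ever contacts a network service, so every run is
reproducible against a frozen annotation release.

## Core algorithms

**Multi-Steiner-Tree connector search.** One tree is grown with the
Takahashi–Matsuyama attachment heuristic: start from a seed, repeatedly
join the nearest unconnected seed along a weighted shortest path, prune
non-seed leaves (weight ≤ 2·(1 − 1/ℓ) × optimum for ℓ terminals on the
metric closure). `must_connect` runs `n_trees` such iterations (default
10), multiplying the weights of used edges by (1 + δ), δ = 0.05, after
each so later iterations explore alternative near-optimal trees; an
optional hub penalty inflates edge weights by
w → w·(1 + hp·((deg u + deg v)/2)/max-degree). Connectors (union nodes
minus seeds) are ranked by participation count, then degree.

**TrustRank.** Seed-personalized damped propagation on the combined
protein+drug graph: s ← (1 − d)·p + d·M·s with p uniform over the seeds,
M the column-normalized adjacency and d = 0.85, iterated until the L1
change falls below 1e-8 (dangling-node mass redistributed along p). Scores
sum to ≈1 over nodes reachable from the seeds.

**Drug ranking.** Candidate drugs target ≥1 mechanism node. With
`method="trustrank"` a drug is scored by its own propagation score in the
combined graph seeded on the mechanism; with a centrality method it scores
the sum of its mechanism-target centralities. Ties break by number of
mechanism targets, then drug id.

## Worked example

The bundled curated micro-fixture reproduces a four-study bone-regeneration
meta-analysis (two human protein-group studies, one rat single-accession
study, one mouse gene-only study):

```python
from proteoharm import (FilterConfig, filter_protein_ids,
                        generate_use_case_fixture, intersect_studies)
from proteoharm.workflow import harmonize_study

fixture = generate_use_case_fixture()
cal = next(t for t in fixture.studies if t.study_id == "calciolari2017")

# organism-based filtering of the rat study
cfg = FilterConfig(modes=frozenset({"organism_based"}), target_organism="rat")
_, overview, detail = filter_protein_ids(cal, fixture.provider, cfg)
print(sorted(a for r in overview for a in r.removed_ids))
# ['B4DQ80', 'B7Z722']        <- the two human accessions, nothing else

before = intersect_studies(fixture.studies, 2, allow_mixed_organisms=True)
after = intersect_studies(
    [harmonize_study(t, fixture.provider, "human")[0] for t in fixture.studies], 2)
print(len(before), len(after), after.count("POSTN"))
# 7 10 4
```

The two removed accessions are human tropomyosin entries that slipped into
a rat study (the genuine rat entry `Q63610` is kept); harmonization grows
the shared gene set from 7 to 10 (+43 %), and `POSTN` — absent from the
four-way intersection beforehand — is found in all four studies afterwards,
with rat `Serpinc1` replaced by its human ortholog `SERPINC1`.

The same stages are scriptable from the shell:

```
proteoharm fixtures --out demo --use-case
proteoharm filter --in demo/calciolari2017.tsv --provider demo/provider \
    --organism rat --modes organism --out filtered.tsv
proteoharm run --config pipeline.json
```

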