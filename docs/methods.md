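# Methods

## Pipeline model and assumptions

A *study table* is an ordered list of rows, each holding a protein group
(accessions indistinguishable by the identified peptides, `;`-separated by
MaxQuant convention) and/or a gene-name group, plus arbitrary extra columns.
Three contracts hold across every identifier-changing stage:

* **Conservation** — per row, the previous identifiers equal the kept plus
  the removed ones as multisets (`n_previous = n_kept + n_removed`);
  additions are disjoint from the previous set. These invariants are
  enforced at log-construction time, not merely tested.
* **Row stability** — `row_id`s are unique and stable; a stage may drop a
  row (when its whole group is gone and `keep_empty` is off) but never
  renumbers survivors. Extra columns pass through byte-identically.
* **Audit completeness** — every removed identifier appears in the detail
  log with exactly one reason from a closed set (`wrong_organism`,
  `unreviewed`, `obsolete`, `contaminant`, `decoy`, `no_gene_name`,
  `not_in_namespace`, `no_ortholog`).

Annotation is read through a provider contract (protein records, gene
namespace records, ortholog pairs) implemented by a local three-TSV
snapshot. Lookups are pure and absence is data: an accession unknown to the
snapshot is treated like an obsolete one (a retired accession and a missing
one are indistinguishable in a frozen snapshot) but tagged `not found` in
the log metadata. Live web services are deliberately out of scope; frozen
snapshots trade freshness for reproducibility.

## Stage-specific choices

**Filtering.** Checks run in fixed precedence — decoy → contaminant →
obsolete/unknown → wrong organism → unreviewed — so each removal carries one
reason even when several apply; a `CON__`-flagged accession that would also
fail the organism check is logged as contaminant only. Flag prefixes are
stripped before lookup. When decoy mode is off, flagged accessions are
looked up like any other (their bare accession decides). Single-accession
rows drop with their one removed ID, which is why Proteome-Discoverer-style
tables lose whole rows. Duplicate occurrences of an identifier within one
group are logged once per row.

**Remapping.** `uniprot` collects primary names plus synonyms, excluding
symbols the gene table explicitly marks as not HGNC-listed (symbols without
a gene record pass through — absence of a record is not evidence of absence
from HGNC). `uniprot_one` counts primary-name frequency across the group;
ties break by first appearance in group order, then lexicographically.
Existing gene cells are overwritten by default so all names come from one
annotation snapshot; `skip_filled` preserves them. Accessions yielding no
name are logged `no_gene_name`; a row is dropped only when *no* member
yields a name.

**Reduction.** Under the Ensembl ground, a name whose listed Ensembl symbol
differs is logged as a removal with `replaced_by` metadata plus an addition
of the canonical symbol; a name equal to its Ensembl symbol is a kept fixed
point, which makes the stage idempotent. Two synonyms collapsing onto one
canonical symbol merge into one cell entry — exactly the redundancy the
stage exists to remove. The HGNC ground is defined for human data only and
errors otherwise. For the enrichment ground, the provider's
`has_annotation` boolean is the contract for what counts as a functional
annotation.

**Ortholog mapping.** Two steps: symbol → Ensembl gene id via the gene
table, then homology pairs → target symbols. One-to-many orthologs expand
the cell (all targets kept, logged as additions); many-to-one collisions
deduplicate; no transitive mapping through a third organism. A row survives
iff at least one member has a partner. `source == target` is an explicit
identity pass-through with empty logs, so one pipeline configuration can
drive a mixed-organism study set.

**Intersection.** Gene matching is exact-string and case-sensitive: rat
`Gapdh` and human `GAPDH` deliberately do not match, which is the point of
harmonizing first. Mixed-organism input is a hard error unless explicitly
overridden for the "what would we have found without harmonization"
comparison. A gene present in many rows of one study counts that study
once. Default threshold: present in ≥2 studies.

## Network stage

Seeds map onto the protein graph by exact id; unmapped seeds are reported,
never dropped. Because "spanning a connected subnetwork" admits two
readings, the connectivity report carries both: component sizes of the
seed-induced subgraph, and seed groupings by reachability through non-seed
nodes.

The Steiner routine is the Takahashi–Matsuyama attachment heuristic
(classical ≤2× approximation on the metric closure); ties between equally
near seeds break on node id, so a single tree is deterministic given its
start seed. `must_connect` parameters, all configurable:

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 10 | attachment iterations whose trees are unioned |
| `delta` | 0.05 | used-edge weight inflation factor between iterations |
| `hub_penalty` | 0.0 | weight inflation ∝ mean endpoint degree / max degree |
| `rng_seed` | 42 | chooses each iteration's start seed |

The diversification schedule (multiply used-edge weights by 1 + δ after
each iteration) makes later trees avoid earlier ones just enough to expose
alternative near-optimal connectors; connectors are ranked by participation
count across iterations, then degree, then id. Seeds spanning several
graph components yield per-component trees with a warning.

TrustRank iterates s ← (1−d)·p + d·M·s with p uniform over seeds, M the
column-normalized adjacency of the combined protein+drug graph, d = 0.85,
L1 tolerance 1e-8, max 1000 iterations; mass on degree-0 nodes is
redistributed along p (standard dangling-node correction), so scores sum to
≈1 over nodes reachable from the seeds. Centralities use the conventions
that stay well defined on disconnected graphs: raw degree, unnormalized
pair-count betweenness, per-component closeness scaled by component
coverage, harmonic centrality with 1/∞ = 0.

Drug ranking considers only drugs with ≥1 target inside the mechanism and,
by default, only approved ones. TrustRank scores drugs directly (they are
nodes of the propagation graph); centrality methods score a drug as the sum
of its mechanism-target scores. Ties break by target count, then id, making
rankings deterministic.

## Synthetic data

The randomized generator emulates the shapes of a four-study
meta-analysis: two human protein-group studies (24 and 41 rows), one rat
single/group-accession study (170 rows), one mouse gene-only study (608
rows); group sizes are 1 + Poisson(1.5). Default defect rates: 5 %
obsolete accessions (the most common removal class in practice), 5 %
unreviewed, 2 % each decoy/contaminant flags and wrong-organism
accessions, 6 % of protein entries without a gene name, 93 % ortholog
coverage with 5 % one-to-many pairs, 15 % of proteins carrying a synonym
that resolves to the same Ensembl gene, and 8 % of genes listed under a
different canonical Ensembl symbol. Cross-organism correspondence is index
identity (non-human gene *i* ↔ human gene *i*), which makes ground truth
trivially recoverable; every generator emits a manifest of what it planted.

The network fixture plants two intra-connected seed clusters whose only
link runs through one bridge node; background nodes attach as trees
hanging off either half, so no alternative cross-cluster path exists and
the bridge is the unique necessary connector. Drugs attach to seeds with
known multiplicity and an 80 % approval rate.

The hand-curated micro-fixture reproduces named identifier behaviors
exactly (two human accessions planted in the rat study; Ensembl renames
`Ppia`→`Ppial4d`, `Serpina3n`→`RGD1565462`; ortholog pairs
`Serpinc1`→`SERPINC1`, `Postn`→`POSTN`; a gene present in the published
list whose carrier protein has no gene-name annotation and therefore
vanishes during harmonization). It is curated, not sampled: its before/after
intersection sizes (7 → 10 shared genes, `POSTN` 3 → 4 studies) are
construction facts the pipeline must recover, not statistical outcomes.

What passing on synthetic data does **not** show: real annotation
snapshots are larger, messier (isoform suffixes, history merges,
species-specific naming conventions) and internally inconsistent in ways
the generator's referential integrity rules out; real PPI networks have
hubs and alternative paths that make connector recovery genuinely
ambiguous rather than planted-unique. Results on the fixtures validate the
mechanics and the bookkeeping, not biological conclusions.

## Numerical and procedural choices

* Randomized checks use sizes chosen to finish in seconds while exercising
  the combinatorics: 1,000 rows for the log-conservation audit, 500 rows
  for the ortholog row-survival oracle, 200 sampled connected graphs with
  ≤9 nodes and ≤4 seeds for the exhaustive Steiner comparison, 50 random
  12-node graphs for the all-pairs centrality comparison, 100 seeded runs
  for connector recovery.
* The exhaustive Steiner oracle enumerates all Steiner-node subsets and
  takes the minimum spanning tree of each induced connected subgraph — an
  exact optimum at these sizes, independent of the heuristic's code path.
* The centrality oracle recomputes all four measures from a Floyd–Warshall
  distance matrix and explicit geodesic counting, independent of the graph
  library's implementations.
* TSV/CSV dialects are sniffed from the file extension and can be
  overridden; empty cells parse to empty groups whose fate downstream
  `keep_empty` switches decide. Group separator defaults to `;`.
* Organism codes accept lowercase names and NCBI taxon ids (9606, 10116,
  10090, 9986).
* `add_column` output mode emits the untouched input cell next to a
  `_harmonized` copy; `replace` overwrites in place.

## Known limitations

* No isoform (accession-dash-number) resolution beyond exact-string lookup,
  no fuzzy symbol matching, no alias-graph resolution beyond the provider's
  synonym list.
* No FDR re-estimation after decoy removal; filtering is bookkeeping, not
  statistics.
* The ortholog table is agnostic to homology type (one2one vs one2many);
  confidence tiers and synteny are not modeled.
* Statistical significance of intersections or mined modules is out of
  scope; the intersection analysis is exact set arithmetic, not an
  enrichment test.
* Disease-layer annotations of drug–target networks are not modeled; only
  protein and drug layers exist.
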