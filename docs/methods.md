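# Methods

## Scope and model of the data

The package operates downstream of array preprocessing: its expression
input is a gene × sample matrix of log2 intensities keyed by Entrez ID,
with per-sample metadata (compound, dose level, time point, treated/control
role, DILI-risk group). Ten compounds in two groups of five (most-DILI vs
no-DILI) are analysed at one stratum each — by convention the highest dose
and latest time point, applied as a metadata filter before testing.
Everything upstream (CEL-file handling, RMA normalization, array QC) and
everything inside the third-party knowledge bases (text mining, ontology
construction, WGCNA module building) is out of scope; those products are
consumed as snapshot tables.

## Identifier harmonization

All gene sets are reduced to Entrez IDs through a fixed cascade: numeric
token already in the catalog → primary symbol → synonym → UniProt
accession, case-insensitively. A token with two or more candidates at its
winning step is reported as *ambiguous* and excluded rather than resolved
arbitrarily: a silently mis-mapped gene could flip a darkness call, which
is the quantity the whole pipeline exists to get right. The catalog is a
frozen snapshot; withdrawn or secondary IDs are not resurrected.

## Differential expression

Per compound, log2 fold change is the difference of arm means, and
two-sided p-values come from one of three statistics:

- `eb_moderated` (default): the pooled per-gene variance s²_g is shrunk
  toward the mean pooled variance s̄² with a fixed prior weight,
  s²_post = (d₀·s̄² + d·s²_g)/(d₀ + d), and the t statistic is referred to
  d + d₀ degrees of freedom. Defaults: prior df d₀ = 4, d = n₁+n₂−2.
- `t_pooled`, `t_welch`: the classical two-sample tests (scipy).

Moderation is the default because at n = 3 per arm the raw pooled variance
has 4 df and the classical t is badly underpowered: in pilot simulations at
the package's default study conditions (effect 1.2 log2 units, noise sd
0.25) pooled t recovers ~63% of planted effects where the moderated
statistic recovers ~97%, and moderated statistics are the field standard
for small-replicate microarray designs. Genes with zero variance in both
arms and equal means get p = 1 by convention (p = 0 when means differ).

Multiple testing uses Benjamini–Hochberg step-up (via statsmodels); a
quadratic-time reference implementation exists only in the test suite as an
independent oracle. The DEG gate is |log2FC| ≥ log2(1.5) — the exact
binary log, not the rounded 0.585 — AND q < 0.05, both inclusive/strict
exactly as written.

## Darkness classification

The annotation universe is a list of named resources, each a set of
annotated Entrez IDs after resource-specific filters:

- **GO_BP**: only rows with aspect code P; molecular-function and
  cellular-component annotations do not rescue a gene.
- **Reactome / MSigDB**: union of GMT set members after ID mapping.
- **Pathway Commons**: rows whose pathway field is empty after whitespace
  stripping are discarded before collecting participants.
- **OmniPath**: rows whose source-database set is a subset of
  {BioGRID, HPRD, IntAct} are discarded (empty source lists count as
  PPI-only); the remaining participants are annotated.

A gene is dark iff it is in none of the resources. Darkness is always
reported for the DEG union alongside the full measured background
(the catalog/platform gene list), and the biotype tally separates genes
with no biotype record (`uncategorized`) from the categorized total.
Because published summaries mix rounding conventions, coverage percentages
are emitted in both round-half-up and floor display forms next to the raw
fraction.

GO evidence-code filtering is exposed in configuration but defaults to
keeping all rows, since reasonable audits differ on electronic annotations.

## Interactomes and literature

Each interaction snapshot is cleaned to an undirected simple graph:
self-loops and duplicate/reversed pairs removed, unmappable rows dropped,
predicted interactions optionally removed (on by default for the
InBioMap-style snapshot), an optional minimum-score filter available.
Presence in a snapshot requires at least one retained edge, so presence ⇔
degree ≥ 1. The top-connected ranking uses the maximum degree across
snapshots by default (sum and mean selectable) with ties broken by
ascending Entrez ID, reflecting a "highly connected in at least one
resource" reading; the criterion is configurable because no single ranking
is canonical.

Literature evidence counts distinct disease IDs per gene within a source
tier (curated ⊆ all), GeneRIF rows per gene (with a highlight set at ≥ 10
entries, configurable), and distinct publication IDs per gene. A
publication mentioning several genes counts once for each.

## Regulons, signatures, consensus

A TF regulon or pathway signature *maps* to a compound when its gene set
intersects that compound's dark genes — membership, not enrichment,
matching how sets of regulated targets are used to annotate unknown genes.
An optional hypergeometric over-representation mode (background = all dark
genes) exists for exploratory use but is off by default. Group consensus
intersects per-compound regulator sets under one of two empty-set policies:
`strict` (an empty set empties the consensus) or `exclude_empty` (compounds
with nothing mapped are left out, as a compound with no enriched pathway is
conventionally dropped from a Venn diagram). Venn region counts are the
disjoint subset-signature sizes over 2–6 sets; they sum to the union and
the all-sets region equals the strict intersection.

## Cross-species context

Human dark genes map to rat orthologs (one-to-many kept and flagged, since
dropping them would hide module hits), orthologs map to published liver
co-expression modules, and modules join to free-text pathology labels
("BDH", "Adverse at 29 days", …) and GO-BP strings. The pathology report
lists only modules with at least one pathology label and renders absent
GO-BP annotation as the placeholder "-".

## Evidence integration

Twelve default binary sources per gene: presence in each of four
interactome snapshots, curated and all-tier disease association, GeneRIF,
publication hits, regulon membership, signature membership, rat ortholog,
and module membership. The score S is their sum; tiers are high (S ≥ 8),
moderate (S ≥ 4), low (S ≥ 1), none (S = 0). Whether curated and all-tier
disease evidence should count separately is genuinely arguable; both are
kept as distinct sources by default and the source list is fully
configurable. "Not perturbed by no-DILI drugs" is operationalized as "not
a called DEG in any no-DILI compound"; the exclusivity flags are
`most_dili_exclusive` (DEG in ≥ 1 most-DILI, 0 no-DILI) and
`deg_in_4of5_dili` (≥ 4 of 5 most-DILI, 0 no-DILI), the latter implying
the former.

## Synthetic world

The generator emits every pipeline input from one seed. Defaults define
the study conditions: 2,000 genes; 200 planted dark genes excluded from
all five resources while every other gene is guaranteed at least one
annotation; 10 compounds (5 + 5) with 300 planted DEGs each of which 60
are dark; treated shifts of exactly 1.2 log2 units with random sign on a
per-gene N(7, 1) baseline and N(0, 0.25) noise, n = 3 per arm; four
heavy-tailed interactomes (6,000 edges each over 70% of genes, rank-power
endpoint weights, predicted-edge flags only in the InBioMap-like file);
40 regulons × 25 targets and 12 signatures × 30 genes with 3 + 3 planted
consensus TFs and 2 + 2 planted consensus pathways per group, each
guaranteed to target several planted dark DEGs of every compound in its
group (so strict consensus must recover them); Poisson-rate literature
tables; a 60% ortholog rate with 5% one-to-many pairs; 25 modules with
50% membership and 50% pathology-label probability.

Randomness is split into named substreams (one per artifact file) derived
from CRC32 of the stream name plus the seed, so adding an output never
perturbs existing files and identical config + seed gives byte-identical
bundles. The world emulates the *structure* of real inputs, not their
realism: no probe effects, batch structure, correlated genes, realistic
literature-count tails, or annotation biases. Passing planted-truth tests
therefore demonstrates correctness of the set algebra, statistics and
plumbing — not field performance on real databases.

## Numerical and design choices

- Percent displays: round-half-up and floor are both computed because
  published conventions mix them (a 13.24% darkness rate prints as 13;
  a 76.5% evidence coverage prints as 76).
- Degenerate inputs: empty gene lists raise; a world with zero planted
  dark genes runs end-to-end with empty downstream tables.
- The run log excludes timestamps and filesystem paths so report bundles
  are byte-comparable across reruns and locations.
- Problem sizes in tests and the acceptance script (300–2,000-gene worlds,
  200 null replicates at 2,000 genes) were chosen to exercise every code
  path at comfortably interactive runtimes.

## Known limitations

- The five-resource universe and twelve-source evidence list reconstruct a
  typical audit; real studies may weight or merge sources differently
  (the lists are configuration, not code).
- The moderated test shrinks toward the mean pooled variance with fixed
  prior df rather than estimating prior parameters from the variance
  distribution; at the default design this is nearly indistinguishable in
  pilot runs, and the classical tests remain available.
- Ambiguous identifiers are dropped, so heavily aliased loci can be
  under-counted; the mapping report makes the exclusions visible.
- No ontology-graph reasoning: a gene annotated only to an obsolete or
  ancestral GO term is handled purely by what its annotation rows say.
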