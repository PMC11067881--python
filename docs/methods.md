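# Methods

This note documents the models, statistical procedures, numerical choices
and known limitations behind each analysis stage, and what the synthetic
generator does and does not emulate.

## Orthogroup taxon specificity

The unit of analysis is the orthogroup: the set of genes, across all
sampled species, inferred to descend from a single ancestral gene. The
possessor set of an orthogroup is every species with at least one member
gene; there is no minimum-gene or minimum-species threshold (a
`min_species` filter is available on the reporting side for sensitivity
analysis). Specificity is expressed two ways:

* **Inclusive confinement** — an orthogroup is confined to clade X iff its
  possessor set is a subset of X's leaves. This is the primary view: it is
  monotone over nested clades, so a ladder such as genus ⊆ family-level
  clade ⊆ subphylum ⊆ phylum yields monotonically non-increasing counts as
  the clade shrinks, which is how taxon-restricted fractions are normally
  quoted.
* **MRCA stratification (exclusive)** — each orthogroup assigned once, to
  the smallest confining clade (or to its tree MRCA node). Emitted
  alongside, because the two views answer different questions and
  conflating them silently changes percentages several-fold.

Gene-level categories for a focal species partition its full gene list:
species-specific (single-possessor orthogroup), phylum-specific (confined
to the flagged focal phylum but not species-specific; this bucket
deliberately merges genus/family/subphylum confinement levels),
metazoan-specific (confined to the flagged Metazoa clade but not the
phylum), other multispecies (everything else with an orthogroup — i.e.
shared with at least one non-metazoan), and unassigned (genes in no
orthogroup). Unassigned genes stay in the denominator: orthology-inference
tools leave singletons out of orthogroups, and dropping them would inflate
every other share. The residual definition of "other multispecies"
guarantees the partition is total and exact (tested: the five counts sum
to the proteome size for every species).

Clade-overlap tables count, for disjoint named species groups, orthogroups
possessed by at least one member of every group in a combination and by no
member of any group outside it. Orthogroups possessed only by unpartitioned
species are excluded from the universe, so combination counts always sum
to the number of orthogroups with at least one partitioned possessor.

## Gene-family dynamics

Ancestral family sizes are a consumed input when available: a counts table
whose columns already include internal-node names (e.g. exported from a
birth–death reconstruction such as CAFE) is used verbatim and flagged
`provenance="external"`. Otherwise internal counts are filled by
linear-cost (Wagner) parsimony: a Sankoff dynamic program over integer
states 0..max(leaf count), with transition cost |parent − child|, which
minimizes total absolute copy-number change over the tree. Ties are broken
deterministically toward the smallest count, resolved root-to-tip; this
makes outputs reproducible but differs from probabilistic reconstructions,
which is why provenance is carried through to every report. The DP is
exact (tested against exhaustive enumeration over every rooted topology
with ≤ 5 leaves and sampled 6-leaf trees) and, being a minimum over an
unrooted quantity, reaches the same total cost under re-rooting.

Per-branch tallies count families expanded/contracted/unchanged and gene
copies gained/lost (delta = child − parent). The terminal-vs-internal
comparison is a two-sided Welch two-sample *t*-test on a per-branch
metric; the default metric is families changed (expanded + contracted),
with gene copies changed available by flag, since published per-branch
means are of the order of the number of families, not gene copies. Both
samples need ≥ 2 branches; identical constant samples return t = 0, p = 1
rather than NaN. The species-pair report gives, per species: the fraction
of families whose extant size differs from the size at the reference node
(default: the pair's MRCA), terminal-branch gains and losses, cross-species
gain and loss ratios, and the families lost to zero on each terminal
branch together with the size of their intersection.

A caution on conservation identities: per-branch deltas telescope along
each root-to-leaf *path* (the path sum equals leaf count minus root count,
per family); summing signed deltas over *all* branches does not reduce to
a leaf-only expression because internal branches are shared between paths.
The tests assert the per-path identity.

## Macrosynteny

The shared-orthogroup matrix collapses orthogroup membership to presence
per scaffold (multi-copy families count once) and excludes orthogroups
present on more than `max_scaffolds_per_og` scaffolds (default 5) in
either species; both guards keep repeat-derived families from dominating
the counts and both are configurable. The universe N is the number of
retained orthogroups placed in both genomes. Each sharing scaffold pair is
tested with the exact hypergeometric upper tail (via scipy's log-space
implementation, verified against direct summation of the mass function to
1e-12 for N ≤ 200); pairs sharing nothing are untested. Benjamini–Hochberg
at FDR 0.05 is the default correction — the field-standard choice for this
kind of enrichment screen. Linkage groups are connected components of the
bipartite significant-pair graph: deterministic and parameter-free, at the
cost of chaining risk on fragmented assemblies (one spurious edge can
merge two true groups; community detection would trade that risk for
parameters and nondeterminism). Components are numbered by descending
shared-orthogroup content; dot-plot ranks order scaffolds by linkage
group, then gene count, then name, making plots reproducible byte-for-byte.

## Marker evolutionary profiling

Markers are filtered with Seurat-convention thresholds (defaults: adjusted
p ≤ 0.05, avg_log2FC ≥ 0.25, expressed in ≥ 25% of cluster cells,
positive-only); all four thresholds are exposed because published "strict"
criteria vary. Each surviving marker is annotated with the smallest ladder
clade its orthogroup is confined to, with two terminal buckets:
focal-species-specific (single-possessor orthogroups) below the ladder and
"other multispecies" above it, plus "not assigned" for genes in no
orthogroup. The lineage-specific fraction of a group counts markers in a
configurable category subset (default: focal-species-specific plus every
within-phylum confinement level) over all markers of the group *including*
not-assigned ones; unassigned genes are unknowns, not evidence of deep
conservation. An `assigned-only` denominator switch reports the
alternative. A gene marking several clusters counts once per cluster, but
only once in any union group (e.g. a pooled stem-cell group), so pooled
fractions are not inflated by shared markers. The sharing histogram
restricts to orthogroup-assigned markers of chosen clusters (deduplicated
by gene) and reports how many possessor species each has, plus the
fraction at or above a configurable wide-sharing threshold.

## Synthetic data generator

The generator exists so every stage can be validated against planted
truth. Families originate on a uniformly drawn tree branch (root included)
with one copy; below the origin each branch loses the family outright with
probability `loss_prob` (Dollo: no regain, the whole subtree stays absent)
or drifts by ±1 copy with probability `drift_prob`, with 0 absorbing so
drift never resurrects a lost family — confinement classification assumes
single origin, and the generator honors that assumption. Families extinct
at every leaf are kept in the truth record but omitted from emitted
tables, as an orthology-inference run would never see them. Genome layouts
assign shared families to `n_linkage_groups` ancestral groups, split each
group into scaffolds per species, move genes to a uniformly random group
with probability `translocation_rate` (so at rate 1 the scaffold/group
association vanishes), and reverse local segments at `inversion_rate`.
Marker tables draw genes per cluster from planted category mixtures and
give each row effect sizes and p-values that realize a planted pass/fail
label under the default filter.

Defaults (16 leaves, 5,000 families, loss 0.05, drift 0.2, 5 linkage
groups, 12 clusters × 100 markers) give a mid-size study with realistic
sparsity that runs in seconds. All randomness flows from one seed through
named substreams per stage, so adding a stage never perturbs another
stage's output, and fixed seeds give byte-identical files.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: orthology-inference error (families are
known exactly, never split or merged), rate heterogeneity across branches
and families, gene-tree/species-tree discordance, assembly fragmentation
and missing annotation, correlated marker noise and ambient expression.
Recovery results on synthetic data are best-case bounds.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; GFF3 I/O converts at the
  boundary (1-based closed), and export → import is an involution.
* Gene identifiers match by exact string equality after trimming; no fuzzy
  matching. Species names are matched between tree, tables and configs
  exactly; mismatches are hard errors, never silent drops.
* Clade configs must be nesting-consistent (any two clades disjoint or
  nested); partial overlaps are rejected at load time.
* Proportion vectors are validated to sum to 1 within 1e-9; hypergeometric
  p-values are exact, not normal approximations; BH q-values come from
  statsmodels.
* Every output table carries a comment header with the tool version and a
   12-hex config hash, so files from different runs cannot be mixed
  unnoticed.
* The acceptance script (`scripts/acceptance.py`) uses a 16-species ladder
  tree, 8,000 families, 300 markers per cluster and two planted marker
  mixtures (6% and 50% lineage-specific); these sizes exercise every code
  path at full statistical strength while keeping a complete run to a few
  seconds.

## Known limitations

* Inclusive confinement with no minimum-species floor counts an orthogroup
  possessed by two congeneric species as genus-confined; studies using a
  floor will report smaller taxon-restricted fractions.
* Parsimony ancestral counts are a stand-in where no external
  reconstruction is supplied; they systematically concentrate change on
  terminal branches relative to birth–death models, and reports label the
  provenance for exactly this reason.
* Connected-component linkage groups can chain across a single false
  positive pair; inspect the pair-test table when a group looks too large.
* The marker ladder reconstruction assumes one gene = one proteome entry
  (splice-filtered inputs); isoform-suffix stripping is available in the
  reader config but off by default.
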