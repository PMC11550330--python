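# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Gene trees and the LGT screen

Trees are treated as **unrooted**: maximum-likelihood tools emit unrooted
topologies and no rooting is assumed anywhere, so a "clade" means one side
of a bipartition (split), and every side of every edge — including
complements and, degenerately, single leaves — is examined. Supports are
ultrafast-bootstrap percentages attached to internal edges; IQ-TREE-style
`aLRT/UFBOOT` slash pairs are parsed by taking the **last** slash field.
Edges without a label are treated as support 0 for threshold tests, the
conservative reading: an unsupported clade can never trigger the clade
criterion.

Classification parameters (`LgtParams`), with defaults:

| parameter | default | meaning |
|---|---|---|
| `support_threshold` | 70 | minimum UFBOOT % for a qualifying clade |
| `composition_fraction` | 0.95 | minimum prokaryote+virus fraction of tree leaves |
| `donor_majority` | 0.50 | strict lower bound on a donor group's share |
| `max_stray_eukaryotes` | 1 | non-host eukaryotes tolerated inside a qualifying clade |
| `min_sites_for_tree` | 80 | alignment columns below which clusters skip tree building |

Decisions taken where the procedure is genuinely open:

- **Denominator of the composition rule**: all leaves, including the host
  sequences (the literal reading of "sequences in the tree");
  `include_host_in_denominator=False` excludes them for sensitivity
  analysis.
- **Several qualifying sides**: the smallest is recorded for donor
  inference (the most local phylogenetic neighbourhood), ties broken by
  higher support, then lexicographic leaf set.
- **Composition gating**: by default the composition criterion fires when
  no side *qualifies* under the clade criterion; `composition_gate=
  "no_supported_clade"` switches to the stricter reading (no side anywhere
  reaches the support threshold).
- **Paralogs**: every host gene in a tree receives its own call; event
  collapsing (below) de-duplicates at the orthogroup level.
- **Short clusters**: the tree path handles alignments of ≥ 80 columns;
  clusters strictly below that use the all-non-host-prokaryotic rule.

Donor inference is a strict plurality over the **non-host** leaves of the
qualifying clade at a configurable rank (default phylum): the winning group
must hold a share strictly above `donor_majority`, so an exact 50/50 split
is unassigned by construction.

Taxonomic-redundancy reduction collapses each maximal monophyletic group of
leaves sharing a lineage label at a configurable rank (default genus) to at
most `keep_per_clade` representatives, preferring longer sequence IDs; host
leaves are never removed. The rank and count are exposed as parameters
because the original thinning procedure is not fully specified; no fidelity
to it is claimed.

## Acquisition events on the host tree

One orthogroup containing ≥ 1 LGT-positive gene is one event: orthogroups
proxy gene families, so post-acquisition duplications inflate gene counts
but not event counts. Events are placed by **Dollo-style parsimony** on the
fixed topology `((BUSSELTON2, SCHOONER1), BMAN)`: a single gain on the stem
of the smallest clade containing all species that possess the gene, losses
unmodelled. A pattern such as BUSSELTON2+BMAN therefore maps to the genus
stem even though ancestral-presence-with-loss in SCHOONER1 would explain it
equally well; the mapping deliberately reports the single-gain solution and
leaves loss scenarios to the reader. Event donors are the plurality of
member-call donors (ties unassigned); functional categories are input COG
letters, tallied and never predicted.

## Family expansion/contraction

The screen works on integer counts of proteins per family per species, with
species partitioned into groups:

1. **Filter**: families non-zero in a single species (taxon-specific),
   non-zero in only one group (group-exclusive), or with a zero median in
   any group are flagged and excluded from scoring — flagged, not deleted,
   each with a machine-readable reason. A caller-supplied exclusion list
   covers lineages known to carry idiosyncratic expansions.
2. **Outlier replacement**: within each (family, group) vector, values with
   |z| > 1.5 are replaced by the group median. The z-score uses the
   **population** standard deviation: with the sample estimator, |z| > 1.5
   is unattainable for groups of ≤ 3 and barely attainable at 4, which
   would nullify the step at realistic group sizes. Replacement is
   **iterated to a fixed point** (a gross outlier can mask a milder one;
   a single pass is not idempotent in such cases), capped at 100 rounds;
   constant vectors (zero sd) and single-member groups pass through
   untouched.
3. **Scoring**: counts are normalised by the family median over all
   included species (making scores exactly invariant to scaling a family
   row), and log2FC is computed between group **medians** of normalised
   counts (`group_agg="mean"` switches to means), as
   `log2(agg_A) − log2(agg_B)` so that antisymmetry is exact in floating
   point. |log2FC| ≥ 2.35 flags an expansion or contraction — the
   five-fold criterion (log2 5 ≈ 2.32). Both thresholds are two-sided:
   |z| > 1.5 and |log2FC| ≥ 2.35.
4. **Core/accessory**: core iff count > 0 in every species.

## Symbiosome connectivity

The compartment network is a simple undirected graph: nodes are symbiont
compartments with a boolean external-contact flag, edges are
symbiont–symbiont membrane connections (no self-loops or parallel edges;
whether the published connection count includes parallel connections is
unknowable from the text, so simple edges are assumed). The summary reports
node/edge/component counts, multi-node components, largest component,
singletons, contacted nodes (degree ≥ 1), the contacted percentage rounded
to the nearest integer, and external-contact counts.

The packaged BUSSELTON2 graph is a **reconstruction, not the measured
adjacency**: the true volume data are not shipped. The generator is
constrained to the printed tallies — 183 nodes; 15 multi-node components of
which the largest has 105 nodes; 25 singletons; 171 edges; 108 external
contacts. Only the aggregate of the 14 smaller multi-node sizes (53) is
printed, so the split `6,5,5,5,4,4,4,4,3,3,3,3,2,2` is fixed in a versioned
constant; the 143 spanning-tree edges are topped up with 28 within-component
edges. Every printed tally is reproduced by construction for any wiring
seed; node-level quantities not printed (degree distribution, which nodes
are external) are arbitrary.

## Genome utilities

Coordinates are 1-based inclusive (GFF3) throughout. A+T content is
computed over unambiguous bases only (N excluded from the denominator,
case-insensitive, strand-agnostic); ambiguity codes other than N are
rejected with positions, to fail loudly rather than silently skew
composition. Introns are gaps between consecutive exons; zero-length gaps
(adjacent exons) produce no intron; the GT-AG boundary check is
strand-aware and reported, never enforced. Symbiont load is the ratio of
mean symbiont to mean host-nuclear depth times host ploidy, with
**length-weighted** means by default (a per-base mean); the result object
also carries the contig-level spread since the published range could
reflect either replicate libraries or contig scatter. Ploidy is a plain
multiplier supplied by the caller (the published estimates posit a haploid
host).

## Synthetic generators

All generators take explicit seeds and are byte-identical under a fixed
seed. What they emulate — and deliberately do not:

- **Gene trees**: random topologies by sequential random attachment with a
  trifurcating root (unrooted convention), not sequence evolution; supports
  are drawn uniformly on a configurable range rather than estimated. The
  `lgt_nested` scenario plants the host inside a prokaryote subtree whose
  stem gets the requested support and stray-eukaryote count, so the planted
  clade exists as a bipartition by construction. The `vertical` scenario
  attaches the host on a eukaryote-subtree edge with ≥ 2 eukaryotes on each
  side (hence `n_euk ≥ 4`), which guarantees structurally — for any support
  draw — that no bipartition side contains the host and a prokaryote with
  fewer than two stray eukaryotes, i.e. no qualifying clade exists. Passing
  recovery tests therefore demonstrates correct rule application, not
  robustness to reconstruction error in real trees.
- **Count matrices**: negative binomial baselines (overdispersion is
  typical of gene-family sizes), defaults mean 40, shape 20, two groups of
  five species; planted expansions multiply the target group's mean by the
  fold factor; isolated outlier cells are multiplied by a large factor.
  Defaults were chosen so that an 8-fold planted change sits roughly two
  group-median standard errors above the 2.35 threshold — detectable but
  not trivially so. Real count matrices have family-specific means and
  correlated species, which the generator does not model.
- **Compartment graphs**: exact component spectra by construction (random
  spanning trees plus within-component extra edges); external flags prefer
  multi-component nodes first, a documented arbitrary rule.
- **Genomes**: i.i.d. bases at the requested A+T fraction with forced GT-AG
  (or CT-AC on the plus strand of minus-strand genes) intron boundaries;
  no codon structure, repeats, or isochores. Coverage depths are lognormal
  with a mean-preserving parameterisation, so the planted depth ratio is
  the expectation at any noise level and exact at zero noise.

## Problem sizes in the test suite

The suite exercises the classifier against a literal brute-force
bipartition oracle (an independent newick parser) on 300 random trees of
≤ 12 leaves, planted-scenario recovery on 1000 simulations, family-dynamics
recovery on twenty 1000-family matrices, graph statistics against a
depth-first-search oracle on 200 random graphs, and a ten-orthogroup demo
pipeline — sizes chosen to give exhaustive small-case coverage and stable
stochastic margins while keeping the default run fast.

## Known limitations

- Differential gene loss is not modelled; branch counts are single-gain
  assignments.
- Orthogroups are consumed, never computed; mis-clustered inputs propagate.
- The composition criterion ignores supports entirely (by design) and so
  cannot distinguish a well-resolved prokaryote tree from an unresolved
  one.
- The BUSSELTON2 graph reproduces printed aggregate tallies only; any
  node-level statistic computed from it is a property of the
  reconstruction, not of the specimen.
- The expansion screen's z-replacement is a hard substitution, not a robust
  estimator; families with genuinely bimodal counts within a group will be
  flattened toward the median.
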