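# Methods

## Scope and model of the screen

`mosaicscreen` reimplements a lateral-gene-transfer screen for euglenid
nuclear genomes as five cooperating components: a lineage-group registry,
alignment processing, a neighbor-joining tree engine with bootstrap, a
closest-lineage screen, and a support-thresholded topology classifier, plus
a simulator that generates gene families with known (planted) histories so
every stage can be tested without external databases.

The unit of analysis is one gene family: an aligned set of protein
sequences containing a designated euglenid query (by default
`Euglena_gracilis`). The question asked of each family is whether the query
belongs, with quantified support, to a clade of red-lineage sequences (red
algae plus the Chromalveolata+Rhizaria assemblage, "CR") rather than to the
green algae/plants expected from the euglenophyte plastid's origin.

## Lineage groups

Nine fixed group codes partition all OTUs: euglenids, other excavates, CR,
red algae, green (algae + land plants), glaucophytes, unikonts,
cyanobacteria and other bacteria. CR deliberately bundles stramenopiles,
alveolates, cryptophytes (including nucleomorph-encoded entries, registered
with subgroup `nucleomorph`), haptophytes and Rhizaria: these are the
lineages whose plastids, where present, trace to red algae. Glaucophytes
have their own code but play no role in any classification rule. OTU labels
follow `Genus_species[_suffix]`, which makes genus extraction deterministic
and removes any dependency on a live taxonomy service. Lookups of
unregistered labels always raise; there is no default group.

## Alignment processing

* Column trimming removes columns with gap fraction above
  `col_max_gap_frac` (default 0.5); taxon trimming then removes rows above
  `taxon_max_gap_frac` (default 0.75). "Indel-rich" has no canonical
  definition, so both knobs are surfaced in configuration. Columns are
  trimmed before taxa; the order is fixed in one place. The query row is
  never removed — a query above the threshold rejects the whole family.
* Distances: p-distance over columns where both sequences have an
  unambiguous residue (`-` and `X` excluded; EST-derived translations carry
  many `X`s), optionally Poisson-corrected `d = -ln(1-p)`. Distances
  saturate at `p >= 0.99`, capped to `-ln(0.01)`, keeping matrices finite
  for NJ. The Poisson correction is the classic single-rate protein
  correction; it slightly underestimates large distances under the 20-state
  generating model used by the simulator, which matters only for deep,
  near-saturated branches.
* Shared-indel signatures: maximal runs of at least `min_len` columns where
  a candidate taxon set and all remaining rows sit on opposite sides of the
  gap/non-gap divide. Universal gap columns are not discriminative and never
  match. Coordinates are 0-based half-open throughout.

## Tree engine

Neighbor joining follows the Saitou–Nei agglomeration with the three-point
pendant-length formulas and the standard matrix reduction. Two rules make
runs bit-reproducible:

* Q-criterion ties are broken by the lexicographically smallest pair of
  cluster representatives (a cluster's representative is its smallest leaf
  label). The Q matrix is computed as `(m-2) d - (r_i + r_j)` with the row
  sums added *before* subtraction, which keeps Q exactly symmetric in
  floating point — otherwise a tie's mirror entry can differ in the last
  bit and the tie-break sees only half the candidates.
* Negative pendant estimates are clamped to zero with the deficit moved to
  the sibling edge (the pair's joint length is preserved).

On an additive matrix NJ recovers the generating topology and branch
lengths exactly; the test suite verifies this against an independent
brute-force oracle and cross-checks generic matrices against scikit-bio's
NJ implementation.

Bootstrap supports: the point tree is built from the full alignment; each
of `n_bootstrap` replicates resamples columns with replacement (same
length), rebuilds a tree, and each internal edge's support is the
percentage of replicates containing the same leaf bipartition. Replicate
pairs that lose all comparable columns are treated as saturated rather than
aborting the replicate. Supports attach to bipartitions, so they survive
rerooting unchanged. Newick I/O stores supports as internal node labels —
the dominant wild convention — with the scale (`bootstrap_pct` on [0,100]
or `posterior` on [0,1]) declared out of band.

Single-genus collapsing orients the tree away from the protected query,
finds maximal clades whose leaves share one genus, keeps the
lexicographically smallest leaf of each, and repeats to a fixpoint.
Patristic distances among retained leaves are unchanged, and the output's
bipartitions are exactly the input's restricted to the retained leaves.

Pipeline order is fixed as: full tree → bootstrap supports → collapse; the
closest-taxon scan runs on the collapsed tree, classification on the full
supported tree.

## Screen

Two E-value gates reproduce the original screen's filters and are strict
inequalities by construction: a family enters only if it has a green-plant
hit with E-value < 1e-5, and its homologue set is the hits with
E-value < 1e-3, sorted by (E-value, subject), capped at 500. Hit tables are
consumed as TSV; running BLAST is out of scope.

The closest-taxon scan reports the leaf minimising patristic distance to
the query among leaves whose group is not excluded; the query's own
(euglenid) group is excluded by default so conspecific and congeneric
sequences cannot mask the donor signal. Exact ties are recorded and broken
lexicographically. The tally counts the nearest single OTU, not a
nearest-clade majority; report headers state this.

## Classifier

A clade passes the monophyly test when its subtending edge's support meets
the threshold for the tree's scale — 70 on bootstrap trees or 0.9 on
posterior trees, boundaries inclusive; one tree carries one scale. Trees
are rooted on the edge subtending the maximal clade of the first outgroup
group present, in preference order cyanobacteria → other bacteria →
unikonts.

The defining clade is found by walking the query's ancestors while the
clade's other members remain within {CR, red, euglenid}; among ancestors
containing at least one CR or red member, the *largest* supported one wins.
Taking the largest (not the smallest) qualifying clade is deliberate: a
query nested deep inside the CR assemblage has many small supported clades
whose sister is simply more CR, and the biologically meaningful sister
question applies to the full euglenid+CR(+red) clade. Categories then
follow:

* red algae present inside the defining clade (alongside CR) → `CR_RED`;
* otherwise the sister of the defining clade decides: a supported sister
  that is ≥ 80 % red → `CR_RED`; ≥ 80 % green → `CR_GREEN`; anything
  mixed, unsupported, or other → `RED_OTHER`. The sister relation counts
  as supported when the parent clade's edge meets the threshold, or when
  the parent is the root (the sister is then fixed by the outgroup
  rooting). The 80 % majority absorbs stray taxa that real sister clades
  accumulate;
* a defining clade with red algae but *no* CR member is reported
  `UNCLASSIFIED` with an explanatory note — the triose-phosphate-isomerase
  situation, deliberately not designated a red-lineage gene;
* with no red-lineage clade at all, a supported clade of only
  green+euglenid leaves yields `GREEN`; otherwise `UNCLASSIFIED`.

Where the original analysis relied on manual topology inspection, these
rules are explicit and deterministic, and every call records the defining
edge, its support, the rooting group and a human-readable note, so a
curator can audit decisions the way the original authors did by eye. The
Peranema flag is true when the defining clade contains an OTU of the genus
*Peranema*.

## Simulator

`build_scenario_tree` plants one of five histories in a fixed backbone
`((bacteria,(unikonts,((green,(red,CR)),excavates))))`:

* `VERTICAL` — euglenids remain with the other excavates;
* `GREEN_EGT` — euglenids inside the green algae;
* `CR_RED` — euglenids inside CR, euglenid+CR monophyletic with red algae;
* `CR_GREEN` — euglenid+CR sister to the green clade, red algae outside;
* `RED_OTHER` — euglenid+CR supported, but its true sister is a mixed
  green+red clade.

The `RED_OTHER` design is worth a note. An earlier variant attached the
euglenid+CR clade through a zero-length edge, aiming for "sister
unresolved" via low bootstrap support. That fails in practice because of
the star-tree paradox: bootstrap pseudo-replicates correlate with the
original sample, so an arbitrary resolution of a true polytomy frequently
receives high support, and such families were misclassified as `CR_GREEN`.
Representing "unclear sister" as *mixed composition* instead of low
support makes the planted label recoverable regardless of how well edges
resolve, and matches what the real trees in this category look like — a
well-supported euglenid+CR clade adrift in a mixed assemblage.

Sequences evolve under a 20-state Poisson model: uniform root frequencies,
per-site substitution counts Poisson(branch length), each event jumping
uniformly to one of the other 19 residues (so the expected proportion of
differing sites at distance *d* is `(19/20)(1 - exp(-20d/19))`). Insertion
events occur at `indel_rate` per positive-length branch (zero-length
branches evolve nothing, so an all-zero tree yields identical, gap-free
rows), with geometric lengths of mean 3; the leaves below the event's
branch carry residues and all other rows carry gaps, exactly the signature
the shared-indel scanner detects. Only this Poisson model is implemented;
empirical exchangeability matrices (e.g. WAG) would matter for inference on
real data but not for exercising the pipeline's logic, and the model tag is
validated so misconfiguration fails loudly.

Default study conditions: 20 taxa (2 euglenids, 4 CR, 3 red, 4 green, 3
other excavates, 2 unikonts, 2 cyanobacteria), internal branches 0.5
substitutions/site, exponential tips with mean 0.2, 500 columns, 0.1
insertions per branch, 100 bootstrap replicates. These give clean but not
saturated signal — roughly what a conserved single-copy protein family with
good taxon sampling looks like. The benchmark in the acceptance suite runs
20 families per history at exactly these settings.

The fourteen worked-example fixtures encode, from the study's verbal
descriptions, one tree per red-lineage gene family (4 expected `CR_RED`, 2
`CR_GREEN`, 8 `RED_OTHER`; Peranema leaves in the GND and ADP/ATP
transporter trees). The ClpP fixture is a synthetic stand-in: the real
fragment was too short for a reliable tree, and its topology is imputed
from residue-level evidence; the fixture's note says so.

## What the synthetic data does and does not show

The simulator produces clock-like, indel-simple, single-rate data with
clean planted topologies. Passing the benchmark therefore demonstrates the
*pipeline logic* — trimming, NJ, bootstrap accounting, collapsing, distance
scans and classification rules compose correctly and deterministically —
not robustness to the pathologies of real EST data (compositional bias,
long-branch attraction, rate heterogeneity across sites, missing data
structure, paralogy). Gamma-distributed rate heterogeneity is a noted
extension, not silently included. The database-scale tallies of the
original screen (hundreds of closest-lineage queries, thousands of input
queries) depend on the original EST set and a contemporary database and are
explicitly not reproduced; the planted benchmark and invariant suite stand
in for them.

## Numerical and interface choices

* Supports live on bipartitions; rerooting restores them by bipartition
  key. Edge lengths are written with 17 significant digits, so newick
  round-trips are lossless.
* Boundary semantics are inclusive everywhere a threshold is stated (70,
  0.9); E-value gates are strict (`<`) everywhere.
* Per-gene bootstrap seeds derive from the run seed XOR a CRC-32 of the
  gene id, keeping genes independent but the whole run reproducible from
  one integer.
* Ties (NJ joins, collapse representatives, closest-taxon) all break
  lexicographically.
* The pipeline manifest records a digest per stage (configuration +
  inputs); a rerun with matching digests skips completed stages, so
  deleting a downstream file resumes cheaply.

## Known limitations

NJ is the only tree builder (no ML/Bayesian inference); trees with
posterior supports are consumed, never produced. The distance cap biases
deep branches short. The sister-majority threshold (80 %) and the trimming
fractions are sensible defaults, not fitted quantities. The simulator's
backbone is fixed; it does not model incomplete lineage sorting, gene
duplication/loss, or within-family paralogy.
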