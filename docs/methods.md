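# Methods

## Orthology model

Two proteins are orthologues when (a) each is the other's best hit — the hit
with the smallest E-value — in the pairwise comparison of their two
proteomes, and (b) both directed E-values are strictly below a threshold.
Orthologous groups are connected components of the undirected RBH graph;
singleton components are retained. Because an RBH edge depends only on the
two proteomes it connects, orthology over any isolate subset is the subgraph
induced by that subset's pairwise edges. `PanGenome` exploits this: one
all-vs-all run answers every per-set query (genus cores, random-set cores in
the cohesiveness test, genus-restricted singlet counts) by filtering edges,
which is also why singlets are computed on the genus-restricted graph — a
genus singlet may still have orthologues outside the genus.

The threshold is E = M/(n_p²·n_o²), where M is the tolerated expected number
of spurious matches across the whole experiment (default 1), n_p the size of
the largest proteome (callers may round it up conservatively, e.g. 10⁴ for an
8951-protein maximum), and n_o the number of organisms. The derivation treats
the E-value as a proxy for the per-comparison spurious-match probability
P = 1 − e^(−E), which is accurate to better than 1% relative for E < 0.01.
Ties exactly at the threshold are excluded (strict inequality); equal-E best
hits are broken by larger bit score, then lexicographically smallest subject
ID, so runs are deterministic.

## Similarity engine

The built-in engine scores every candidate pair by exact Smith–Waterman local
alignment (BLOSUM62, affine gaps, BLAST convention: a gap of length k costs
11 + k) through scikit-bio's DP kernel, and converts raw scores S to
E = K·m·n·e^(−λS) with the standard gapped Karlin–Altschul parameters
λ = 0.267, K = 0.041, m the query length and n the total residue count of the
subject proteome. No edge-effect length correction is applied: only hit ranks
and a threshold matter downstream, and fixed parameters keep runs
reproducible. Alignment is computed once per unordered protein pair (the
score is symmetric) and reported in both directions with direction-specific
E-values.

A candidate prescreen skips pairs sharing no 6-mer (an inverted k-mer index
per proteome pair). Unrelated 300-residue proteins share a 6-mer with
probability well under 1%, while family members at the divergences the
generator produces share dozens, so the prescreen discards only pairs whose
E-values would sit many orders of magnitude above any threshold of interest.
Hit tables with thousands of permissive hits per query (e.g. from an external
aligner) can be ingested as 12-column tabular files instead; within-isolate
self-comparisons are never run, since singlet status is defined purely by the
absence of cross-isolate edges.

## Synthetic pan-proteomes

The generator plants a known family structure on a random ultrametric tree:
species subtrees (coalescing below 0.3× the genus root age) nested inside
genus subtrees (deepest split pinned at within_genus_divergence/2) under a
global root at (within + between)/2, so the deepest within-genus pair
diverges by `within_genus_divergence` substitutions/site and cross-genus
pairs by `within + between`.

Family categories:

- **core** — one ancestor at the global root, one member in every isolate of
  every genus. Core families are shared across genera by design: if they
  were genus-private they would also satisfy the genus-unique definition and
  the core/unique distinction would collapse.
- **unique** — genus-private, one member in every isolate of the genus.
- **dispensable** — genus-private with partial presence. Default: i.i.d.
  Bernoulli(p) per isolate, resampled until at least two isolates carry the
  family (so configured category counts are exact). Optional
  `dispensable_mode="tree"`: the family is present at the genus root and
  lost along branches at `dispensable_loss_rate`, giving tree-correlated
  accessory content — the mechanism by which gene content carries
  phylogenetic signal in real pan-genomes, and required for the
  marker-regression experiments below.
- **species_core** (default 0) — private to one species and present in all
  of its isolates; used to plant a cohesive species.
- **singlets** — fresh random sequences per isolate with no ancestor, so no
  reciprocal hits arise at any sane threshold.

Sequences evolve with no indels under uniform replacement over the 20-residue
alphabet: substitution events arrive as Poisson(L·d) per branch and redraw
the residue uniformly among the other 19. This K-state Jukes–Cantor-type
model has closed-form expected difference fraction
p(d) = (19/20)(1 − e^(−20d/19)), which the tests use as an independent
oracle. Protein lengths are Poisson around `protein_length` (default 300).

The marker (default 1500 bases, `marker_rate` = 0.1 marker substitutions per
site per unit of tree depth — a slow clock, like 16S rRNA against whole
proteomes) evolves down the same tree with a deterministic substitution
count allocated cumulatively along each root-to-leaf path at previously
unmutated sites (infinite-sites allocation). Pairwise marker differences are
therefore exactly additive along tree paths, and at `marker_coupling = 1`
marker identity is a strictly decreasing function of planted depth (rank
correlation −1 whenever distinct depths map to distinct rounded counts).
`marker_coupling` interpolates branch lengths toward isolate-specific uniform
noise on terminal branches, so at coupling 0 marker identity is independent
of the tree. The default coupling of 0.9 reflects a mostly clock-like marker.

One RNG stream is spawned per family from the config seed, so identical
config + seed reproduces byte-identical FASTA output and truth tables.

## Marker regression and trees

Percent identity of two aligned marker sequences is identical columns over
counted columns × 100, rounded half-up to 0.01; columns where both sequences
have a gap are excluded from the denominator and gap-versus-residue counts
as a difference (the generator's markers are gap-free, but external
alignments need the rule fixed). Pairs at ≥ 99.50% identity are excluded
before fitting — near-identical pairs anchor the line and inflate R² — and
the filter ignores species naming. Fits are ordinary least squares of shared
proteins (and of average unique proteins) on identity; a genus needs at
least 3 surviving pairs and non-constant identity, otherwise its row is ND.
Slope significance is flagged by a two-sided t-test on the slope with
"**" below 0.001 and "*" below 0.05 — a documented convention of this
package. Constant responses are reported as slope 0, R² 0.

UPGMA merges the closest cluster pair at height d/2 with member-count-
weighted average linkage; ties pick the lexicographically smallest pair of
cluster labels (label = smallest leaf name). Neighbour joining is plain
Saitou–Nei, exact on additive matrices, with negative branch estimates
clamped to zero; bootstrap support and likelihood-based distances are out of
scope, so the marker tree here is a distance tree, a documented deviation
from likelihood-based marker phylogenies. Both are cross-checked in the test
suite against independent implementations (scipy average linkage, scikit-bio
nj).

## Cohesiveness test

For species S with N_I ≥ 2 isolates, the observed core proteome (orthology
restricted to S's isolates) and unique proteome (groups in all of S, in no
other isolate of the genus) are compared with the same quantities for random
sets of N_I isolates from the genus. A random set is valid unless all its
members are one species; the focal species' own isolates are eligible
members. When at most 25 valid sets exist they are all enumerated
(deterministically); otherwise 25 distinct sets are sampled uniformly over
valid sets. The number of valid sets is C(N, k) − Σ_s C(n_s, k). A two-tailed
one-sample t-test compares the random-set mean to the observed value
(undefined, rendered "-", when the random values are constant and unequal to
it), and exceedance columns count random sets strictly beating the species.

Note the structure of this test: the observed value is a single draw, not a
mean, so when species labels carry no signal the t statistic does not follow
its nominal null distribution (its variance is inflated by roughly √m). The
calibration experiment therefore checks the test in the regime where its H0
actually holds — random-set means tested against the exact mean over the
full valid-set population — where the rejection rate sits at or slightly
below α (sampling without replacement from a finite pool is mildly
conservative). The scattered-label experiment separately checks that a
signal-free species is not an outlier of the random-set distribution.

## Validation experiments and their problem sizes

`pancore.experiments` fixes the setups used by the tests and by
`scripts/acceptance.py`:

- **Parameter recovery** — default family structure (2 genera × 4 isolates;
  300 core / 50 unique per genus / 100 dispensable at p = 0.5 / 20 singlets
  per isolate; 300-residue proteins; ~3500 proteins total) at low divergence
  (0.05 within, 0.15 between), full alignment pipeline, threshold with
  M = 0.01. Low divergence and the smaller M instantiate the regime the
  recovery claim is about: every within-family hit passes, nothing else
  does. Recovery of core/unique/singlet counts is exact against the truth
  table (not against raw config numbers: a dispensable family present in
  every isolate legitimately joins the core).
- **Regression contrast** — one 10-isolate genus, 1000 tree-loss dispensable
  families (loss rate 2.5), marker at full vs zero coupling, truth-level
  orthology (sequences are not aligned, so protein length is 30). Full
  coupling yields R² > 0.9 because expected shared content decays smoothly
  (≈ e^(−λ·d/2)) while marker identity falls linearly in d; zero coupling
  yields mean R² ≈ 1/(n_pairs − 1) over 50 marker redraws.
- **Cohesive species** — one 9-isolate genus, three species, 30
  species-private families each: the focal species is never beaten by any of
  25 random sets on either measure.
- **t-test calibration** — 12-isolate genus, 150 i.i.d. dispensable
  families; 500 replicates of 25 sampled sets tested against the exact
  population mean over all 216 valid 3-isolate sets.

## What the synthetic data does and does not show

The generator reproduces the *combinatorial* structure of pan-proteomes —
nested presence/absence categories, divergence growing with tree depth, a
coupled slow marker — so passing tests demonstrate that the pipeline's
bookkeeping, thresholding, grouping and statistics are correct. It does not
emulate horizontal gene transfer, paralogous expansions, domain shuffling,
indels, codon/composition bias, or annotation noise; real proteomes can
produce chained RBH components that mix families, and real E-values come
from heuristic aligners with composition corrections. Exact parameter
recovery on synthetic data therefore validates the machinery, not the
biological accuracy of RBH orthology itself.

## Numerical and degenerate-input choices

- E-values underflow to 0.0 for extremely strong hits (λS beyond ~700);
  0 compares below any positive threshold and ties are then resolved by bit
  score and subject ID, so determinism is preserved.
- Median proteome size uses the lower median for even counts.
- `count_valid_sets` errors on k ≤ 0 or k > N; sampling errors when no valid
  set exists; exhaustive mode ignores the seed.
- Distance matrices must be symmetric, finite, non-negative with a zero
  diagonal; UPGMA requires ≥ 2 taxa, NJ ≥ 3.
- The marker's infinite-sites pool can exhaust (total tree length ×
  marker_rate × length > length); substitution then stops and additivity
  degrades gracefully — defaults stay far from this regime.
- Group IDs are assigned by smallest member protein ID, making partitions
  invariant under input permutation.
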