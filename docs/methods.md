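# Methods

`serpintools` re-implements, as a tested toolkit, the analysis workflow used
to survey a protein superfamily at global scale: a sequence similarity
network (SSN) clustered with Markov clustering, a structure-seeded profile
alignment with consensus-representative selection, a molecular-marker screen
for horizontal gene transfer (HGT), tree utilities, and rigid-body
structural comparison.  Every stage is exercised end to end on synthetic
data with known ground truth; nothing requires downloads or external
inference software.

## Sequence identity

The workflow's thresholds (75% redundancy collapse, >40% network edges,
52.5% refinement) are percent identities.  Identity here is computed from
an optimal global alignment: BLOSUM62 scores, affine gaps (open 10,
extend 0.5, end gaps penalized), with

    identity = 100 x (identical aligned pairs) / (alignment columns),

excluding the terminal runs of gap-containing columns from the denominator
so dangling ends do not dilute identity.  Because co-optimal alignments can
differ in identity count, the dynamic program maximizes the pair
(score, identities) lexicographically, with a fixed per-cell tie-break
(diagonal > gap-in-second > gap-in-first); the value is therefore
deterministic and reproducible by an independent implementation.  Absolute
values differ from BLAST-style local-alignment identities, so thresholds
are comparable run to run within this toolkit but not directly against
BLAST output.

## Similarity network and clustering

Redundancy collapse is greedy and longest-first (CD-HIT style): records
sorted by (length descending, id ascending) either join the first node
whose *representative* they match at >= 75% identity or found a new node.
Edges connect representatives sharing *strictly more* than 40% identity.

MCL runs on the column-stochastic edge-weight matrix with self-loops at
each node's maximum incident weight, alternating expansion (matrix square)
and inflation (entrywise power, default 2.0, then column renormalization),
pruning entries below 1e-6, until the maximum entrywise change is below
1e-8 (cap 200 iterations, with a warning on non-convergence).  Clusters are
attractor basins: attractors are nodes with residual diagonal mass,
attractors supporting one another form one cluster, and a node in several
basins goes to its highest-weight attractor (ties to the smallest node
index), so the output is always a partition.  A divide-and-conquer
refinement re-networks any cluster above a size bound at a raised
threshold (default +12.5 points, mirroring the 40 -> 52.5 step) and
re-clusters it.

The scale-free check fits a discrete power law P(X = x) ∝ x^-alpha to the
degree distribution: maximum-likelihood alpha (Hurwitz-zeta likelihood),
lower cutoff xmin chosen by Kolmogorov-Smirnov minimization over observed
values (candidates thinned to 60, tails of at least 10 observations), and
a semiparametric bootstrap p-value (100 replicates; "plausible" at
p >= 0.1).  The bootstrap resamples the observed body below xmin and draws
the tail from the fitted model by exact inverse-CDF sampling.  P-values
are approximately uniform under the true model, so roughly one seeded
sample in ten is labeled implausible at the 0.1 cutoff — single draws
should not be over-read.

## Profile alignment workflow

A profile is a linear sequence of match states with per-state emission
probabilities, flanked and separated by insert and delete states, with one
*shared* transition distribution (M->M/I/D, I->I/M, D->D/M) estimated from
the seed rows' own state paths with +1 smoothing.  A column is a match
state iff its gap fraction is at most 0.5 (and, when a structural mask is
supplied, the column is resolved in the seed crystal structures).
Emissions are pseudocounted toward the pooled background:

    e_j(a) = (c_j(a) + w * bg(a)) / (n_j + w).

Scoring and alignment use Viterbi in log-odds space (emissions relative to
the background; insert emissions score zero), global in the profile with
*free unaligned tails*: transitions touching the flanking insert states
cost nothing.  The traceback tie-break is match > delete > insert.  This
deliberately replaces ensemble HMM tooling (Dirichlet mixtures, forward
scoring, tree-based placement) with a minimal, fully specified model; the
guide-tree stage of the original ensemble workflow has no counterpart here
— the enriched-profile re-alignment below is the stand-in.

The superfamily alignment runs in five stages: (1) global profile from the
masked seed alignment; (2) per SSN cluster, align surviving members to the
global profile, build a cluster profile, and select the member with the
highest log-odds score as the consensus-like representative (ties to the
smallest id); (3) align representatives to the global profile;
(4) build the enriched profile from the representative alignment;
(5) align every record surviving the length filter to the enriched
profile.  Output rows live in match coordinates; insert-state residues are
reported in a side channel, mirroring the exclusion of non-conserved
insertions.

**Pseudocount weight.** `build_profile` defaults to w = 1; the workflow
stages default to w = 5.  With desk-scale seeds (5-10 rows) and w = 1, a
residue unseen in the seed costs about -1.9 nats against roughly -0.7 for
a delete step, so sequences at 20-30% identity are ejected wholesale into
an all-delete path with their residues in the free tails.  A heavier
background prior — standard profile-HMM practice — keeps distant homologs
aligned; w = 5 puts an unseen residue near the cost of a delete.

**Known error mode.** When a family-stem indel falls in a low-information
region, the Viterbi gap placement is only weakly determined and a block of
columns can shift by one relative to the true homology; the representative
inherits the shift and propagates it to its family.  Column-homology
recovery on the synthetic workflow superfamily is typically 0.95-1.0 for
near-consensus sequences but can dip to ~0.8 on unlucky draws.  This is an
inherent limitation of profile alignment at high divergence, not a defect
of the seed.

## Length filter

Records more than 25% shorter or longer than the median input length are
removed (strict inequalities: exactly 1.25x or 0.75x the median survives).
The median is the lower median (the element at index (n-1)//2), so it is
always a realized length.  The filter is applied once, against the input
median; it is idempotent in its intended regime — a tight length core
(spread ratio below 1.25) plus fragment/fusion outliers — but not for
arbitrary length distributions, where removing outliers can shift the
median.

## Hinge motif

The reactive-center-loop hinge of inhibitory serpins, positions P17-P9, is
the consensus E-x-G-T-E-A-A-A-A with x in {E, K, R}.  The scan reports all
(possibly overlapping) 0-based windows; any window containing the
ambiguity letter X never matches — the motif is treated as positive
evidence of inhibitory competence, so ambiguity is conservative.

## HGT marker screen

Per gene, GC content is (G+C)/(A+C+G+T) with ambiguity letters excluded
from both numerator and denominator, and the gene is flagged
compositionally anomalous when GC_gene/GC_genome is strictly above 1.2 or
strictly below 0.8.  The marker codon at a conserved aligned position
(the Ser56-style site) is read off the CDS by counting non-gap residues
before the column; a gap means the site was lost.  Codon classes default
to the dichotomy as published — ACY = {ACC, ACT} vs TCN = {TCA, TCC, TCG,
TCT} — even though ACN encodes threonine under the standard code; the
class sets are plain configuration, so AGY = {AGC, AGT} (the serine-coding
reading) substitutes in one line.

Small parsimony of the codon-class character is computed by unit-cost
dynamic programming over the observed states (Sankoff recursion), which
handles binary trees and polytomies identically, is invariant to child
order by construction, and yields exact per-node sets of states attaining
the minimum via a second (rerooting) pass.  A left-fold pairwise Fitch
over a polytomy's children equals a zero-length binary refinement, and
refining a polytomy never changes the parsimony minimum, so the two
formulations agree; the DP form was chosen for its exact per-node state
sets.  The tests cross-check against exhaustive enumeration of all
internal labelings on trees of up to 6 leaves.

The aggregate verdict calls the anomaly pattern "systematic" when more
than half the genes in any clade of at least 5 leaves are anomalous; this
operationalizes a qualitative judgement ("few and nonsystematic") and the
clade size is a parameter.  Amelioration (decay of donor composition over
time) is out of scope.

## Tree utilities

Newick I/O follows the convention of numeric support values stored as
internal node labels.  Canonical output orders children by their smallest
descendant leaf label and formats lengths with %.6g, so write-parse-write
is a fixpoint.  Midpoint rooting finds the maximally distant leaf pair
(all-pairs over leaf paths; fine at desk scale), walks the path, and
reroots at the exact halfway point — on a node when the midpoint falls
there, otherwise splitting the containing edge; the two deepest leaves end
up equidistant to 1e-9 and patristic distances are untouched.  Support
collapse contracts every internal edge with support <= threshold (strict
keep above, matching a "BS > 90 shown" convention); edges without a
parsable support count as weak, contracted edge lengths are dropped
(polytomy semantics) and logged, and leaves are never removed.

## Structural comparison

Superposition is the Kabsch algorithm: SVD of the cross-covariance of the
centered point sets with the smallest singular vector sign-flipped when
needed, so the rotation is always proper (determinant +1, enforced to
1e-9).  Correspondence is positional (point i to point i); deriving
residue equivalences from a structural alignment is out of scope, so
published RMSD values for specific structure pairs are explicitly not
reproduced — the machinery (per-member RMSDs, min/mean/max over an
ensemble, summaries at 0.1 Å) is what is tested, against a quaternion
eigenvalue oracle to 1e-6 Å.  Degenerate (collinear) inputs are rejected.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, with explicit seeds and machine-readable ground-truth sidecars:

- **Trees**: Yule process; waiting times exponential with rate
  birth_rate x (current lineages).
- **Sequence evolution**: per-branch Poisson substitutions with uniform
  replacement over the 19 alternatives and Poisson indels with geometric
  length (mean 2).  Site tokens are threaded through the simulation, so
  the true residue homology of every leaf is recorded exactly.  The
  uniform replacement model (not LG) was chosen because its closed-form
  identity expectation, exp(-r d) + (1 - exp(-r d))/20, makes the
  generator verifiable; empirical means match within ~1 point at r d = 0.3.
- **Planted families** (`plant_families`): k family subtrees (height
  normalized to `within_depth`, default 0.06 expected substitutions/site)
  joined by stem branches of `between_depth` (default 0.8).  The defaults
  realize within-family identity of roughly 86-99% and between-family
  identity of roughly 19-29% — distantly related but homologous families,
  as in a real superfamily.  Realized identities are verified against the
  >= 75% / <= 35% constraints and the draw is repeated (up to 10 times)
  if violated.
- **Genomes** (`generate_genomes`): gene bases i.i.d. at the genome's GC
  (or the donor's, for planted transfers), by codon with stop codons
  resampled.  Because stop codons are AT-rich, naive rejection inflates
  GC by ~+0.013 at GC 0.5; the base composition is pre-adjusted so the
  non-stop conditional expectation equals the target exactly.
- **Codon classes**: root state uniform; per edge, loss (absorbing) with
  one probability, class switch with another; the true change count is
  recorded and always upper-bounds the parsimony minimum.
- **Coordinates**: i.i.d. Gaussian displacement per axis, optionally
  followed by a random proper rotation and translation.

What passing tests do *not* show: real superfamilies have non-uniform
substitution processes, rate heterogeneity, domain architecture, biased
indel placement and database noise; the generators emulate none of these.
Recovery rates measured here (cluster ARI 1.0, HGT sensitivity/specificity
~1.0 at a >= 0.15 GC gap and 900 nt genes) characterize the machinery
under its stated assumptions, not performance on real data — in
particular, GC-based HGT detection is known to lose power on ameliorated
or compositionally typical transfers.

## Problem sizes

The shipped analyses and checks run on deliberately small instances —
15-18 sequence superfamilies, 50 genomes x 10 genes, 5000-point degree
sequences, 100-point coordinate sets, trees of 10-20 leaves — chosen so
the full suite completes in well under a minute while every code path and
threshold is exercised.  All sizes are parameters of the generators.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| collapse threshold | 75% | identity for node collapse |
| edge threshold | 40% (strict) | identity for network edges |
| refinement step | +12.5 points | re-clustering threshold raise |
| MCL inflation | 2.0 | cluster granularity |
| support collapse | 90 (collapse <= 90) | weak-edge contraction |
| GC ratio bounds | 0.8 / 1.2 (strict) | compositional anomaly |
| length filter | 25% of lower median | fragment/fusion removal |
| min cluster size | 4 unique sequences | reporting threshold |
| gap fraction | 0.5 | match-state designation |
| pseudocount w | 1 (profiles), 5 (workflow) | emission prior strength |
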