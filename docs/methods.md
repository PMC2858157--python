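# Methods

`trnmotif` infers transcriptional regulatory network motifs (TRNMs) by
integrating three data layers: gene-expression time courses, a mixed
molecular-interaction network, and Gene Ontology annotation.  The pipeline
runs in six stages — preprocess, cluster, validity, motifs, assign, infer —
each a pure function of its inputs, the configuration and one master seed.

## Preprocessing

Expression tables are probe-level.  Multi-probe genes are collapsed by
keeping the probe with the largest sample variance (denominator n−1 over
observed entries; ties go to the lexicographically smallest probe id).
Missing cells are imputed from the k = 10 nearest gene profiles, with
distance defined as the root-mean-square difference over time points
observed in both genes and neighbours weighted by 1/distance; when no
neighbour is observed at the missing time point the gene's own mean is used
and logged.  Each profile is then min–max standardized,
x′ = 2(x − min)/(max − min) − 1, so every gene spans exactly [−1, 1].
Min–max (rather than z-scoring or amplitude normalisation) was chosen
because the RNN state is tanh-bounded in (−1, 1): targets and model outputs
then share a scale.  Constant profiles are a hard error — an RMSE against a
flat line is not meaningful, and silently passing such genes downstream
would corrupt the module search.

## Fuzzy c-means and the fuzziness exponent

FCM alternates the classic membership and centroid updates
(u_ik = 1/Σ_j (d_ik/d_jk)^{2/(m−1)}, v_i = Σ u_ik^m x_k / Σ u_ik^m) until
the largest centroid shift falls below 1e−5 or 300 iterations.  Centroids
are initialised as c distinct data rows drawn by a seeded RNG; each
candidate c is run from 3 seeds and the lowest-objective run kept, which
blunts (but cannot eliminate) local optima.  A data point coinciding with a
centroid receives full membership there.

The fuzziness exponent m is estimated from the empirical distribution of
pairwise squared Euclidean distances: for each m on the grid
1.05, 1.10, …, 3.00 the coefficient of variation of {d_kl^{1/(m−1)}} is
computed; the largest grid value whose CV still reaches 0.03 marks the upper
edge m_ub of the regime in which memberships remain informative, and the
estimate is the midpoint m = 1 + (m_ub − 1)/2.  The grid, the 0.03
threshold and the halving are this package's concretization of the
distance-distribution approach; distances are rescaled to unit mean first
(the CV is scale-invariant, and this avoids overflow at the large exponents
near m = 1).  Degenerate inputs — all pairwise distances equal — are an
error, since no finite m is distinguished.

## GO semantic validity and the cluster number

Term information content is ic(t) = −ln p(t) with p(t) the fraction of
genes (among those annotated in t's namespace) whose annotation set,
propagated along `is_a` links, contains t.  Only `is_a` links are honoured;
`part_of` and other relations are ignored.  Term similarity is Schlicker's
relevance measure, rel(t₁,t₂) = max over common ancestors a of
[2·ic(a)/(ic(t₁)+ic(t₂))]·(1 − p(a)); Resnik and Lin are available as
alternatives.  Gene similarity is the best-match average of the relevance
matrix over the two genes' *direct* term sets, computed per namespace and
averaged over the namespaces in which both genes are annotated; pairs with
no shared namespace are skipped (not scored 0) so that annotation sparsity
is not punished, and skip counts are reported.

The validity of a hardened partition is the pooled mean similarity over all
scoreable within-cluster gene pairs (a mean-of-cluster-means variant is
available via `pooling="clusters"`).  Over a sweep of c the
highest-validity partition wins; scores within 1e−12 are treated as tied
and resolved toward the smallest c.  The tolerance absorbs floating-point
summation noise when two partitions score the same pair population, and the
direction of the tie-break encodes a parsimony preference: splitting a
functionally homogeneous cluster cannot raise the mean pair similarity, so
among equally coherent partitions the coarsest is kept.

## Motif discovery

Each connected three-node subgraph of the mixed network is assigned to a
triad class.  A triple's state is coded pairwise — 3 bits per ordered node
pair (PPI; PDI forward; PDI backward), 9 bits per triple — and the class
signature is the minimum of this code over the 6 relabelings, making it
permutation-invariant.  A PPI edge and a reciprocal PDI pair are distinct
states by default (binding and mutual regulation are different biology); an
untyped mode merges them.  Enumeration walks the undirected skeleton
edge-by-edge, collects third nodes, de-duplicates sorted triples and
classifies them vectorised through a precomputed 512-entry canonicalization
table; the result is defined by (and tested against) brute force over all
C(n,3) triples.

The null model preserves each node's PPI degree and PDI in/out-degree by
independent edge switching within each edge type (100 attempted switches
per edge; proposals creating self-loops or duplicate edges are rejected).
Each of the 1000 null networks is re-randomized from the observed network
with a seed derived from the master seed.  A class is a motif when it
occurs at least 5 times and its count is reached by at most 5% of the null
networks; the observed network is excluded from the null ensemble.
z-scores are reported where the null standard deviation is positive.

TFs are genes whose propagated annotations intersect the
transcription-regulation GO terms (GO:0003700, GO:0061019, GO:0005667 by
default; descendants are covered automatically because propagated sets are
ancestor-closed).  A TF is assigned to a significant class when it occupies,
in at least one instance, a node with an outgoing PDI edge *within that
instance* — occupying a target position does not count.

## Module inference

A motif class is instantiated for a TF from a representative instance: the
focal TF becomes a clamped role, other instance genes that are TFs with
expression profiles become clamped partner roles, and the remaining genes
become free cluster roles.  Cluster nodes follow the discrete-time leaky
recurrence

    x_i(t+dt) = (dt/τ_i) tanh(Σ_j w_ji x_j(t) + β_i) + (1 − dt/τ_i) x_i(t)

with inputs from PDI regulators and PPI partners; PPI edges carry one
shared weight acting in both directions; τ_i ≥ dt keeps the state a convex
combination of bounded quantities, so trajectories remain in [−1, 1].
tanh was chosen over the logistic because profiles are standardized to
[−1, 1].  The initial state of each cluster node is its target centroid's
first value; the RMSE objective covers t ≥ 2.

PSO fits the continuous parameters (bounds w, β ∈ [−5, 5], τ/dt ∈ [1, 10];
ω = 0.729, c₁ = c₂ = 1.49445, velocity clamped to half the box; library
defaults swarm 30 and 1000 iterations, the pipeline preset uses 24 × 150).
The GA searches the discrete space — one cluster index per cluster role
(distinct roles must name distinct clusters) plus a partner-TF locus when a
second TF role is not fixed — with tournament selection (k = 3), uniform
crossover (0.8), per-locus mutation (0.1) and elitism (2); library defaults
population 50 and 600 generations, preset 24 × 40.  Fitness is the
PSO-fitted RMSE, cached per chromosome with a chromosome-derived sub-seed
so results are independent of evaluation order; when the whole space is no
larger than the population it is enumerated outright.  Search stops at the
generation limit or when the best RMSE reaches 0.05.  Candidate target
centroids are min–max standardized before fitting — a centroid of a
coherent cluster is essentially unchanged, while the flat centroid of an
incoherent cluster becomes amplified noise instead of a trivially fittable
constant.  Both the PSO and GA best-objective traces are monotone by
construction and are reported per module.

All randomness flows from one master seed through `numpy` seed sequences;
identical inputs and seed reproduce the module JSON byte for byte.

## Synthetic scenarios and what they do (not) show

The generator plants ground truth at every level.  TF profiles are
sinusoids with seeded random period (0.8–1.2 × T/2) and phase, echoing
cell-cycle periodicity over a default course of T = 47 points.  Planted
module targets follow the module's own RNN trajectory (weights of magnitude
1.8–2.8, biases within ±0.25, τ ∈ [1, 2] — strong enough to traverse most
of [−1, 1] without saturating tanh, which would flatten the fitting
landscape) plus Gaussian noise (σ = 0.15); other true clusters share a
smooth random standardized base; filler genes are independent smoothed
noise; 2% of cells are masked.  The network plants 8 instances per module
over distinct target nodes and adds background edges that avoid planted
pairs.  Annotations use a three-level toy DAG per namespace; cluster
members share a cluster-specific deep term with probability 0.8 by default
plus random shallow terms, and TF genes carry the TF GO terms.

Two presets tighten the defaults so that the planted structure is
*identifiable*, which the verification properties require.  The
cluster-number scenario separates its six expression groups well beyond the
within-group spread and makes within-group annotations homogeneous (share
probability 1, no shallow terms): merging or mixing groups then strictly
lowers the validity score, over-splitting a pure group ties it exactly, and
the smallest-c tie rule recovers the planted number.  During generator
validation the noisier first design was found unidentifiable in principle —
finer partitions were genuinely purer, so no correct implementation could
select the planted c — which is why identifiability, not difficulty, drives
these preset choices.  The end-to-end preset likewise uses homogeneous
annotations.  Consequences for interpretation: passing these checks shows
the machinery is correct and the optimizers recover recoverable structure;
it does not show that real annotation noise, non-periodic expression, or
motif classes absent from the planted catalog would be handled with the
same accuracy.  Real GO term-frequency distributions, evidence codes,
Affymetrix-style noise and probe cross-hybridisation are explicitly not
modelled.

## Problem sizes

Desk-scale sizes keep every stage interactive: the end-to-end preset uses
86 genes × 47 time points, ~125 edges, a c-sweep of 2–12, 1000 null
networks, and GA/PSO budgets of 24 × 40 and 24 × 150; the motif-detection
scenario uses 100 nodes and 1000 nulls over 20 seeds.  The library defaults
(c up to 50, PSO 1000 iterations, GA 600 generations) match what one would
use on a full-size dataset.

## Known limitations

- Motifs are three-node only; larger patterns are out of scope.
- The GA chromosome assumes at most one unfixed partner-TF role.
- The FuncAssociate-style enrichment adjustment resamples same-size gene
  sets uniformly; it does not stratify by annotation multiplicity.
- Edge switching can mix poorly on very sparse or highly constrained
  degree sequences; the switch count per edge is configurable.
- Cluster-number selection inherits the annotation quality: with noisy,
  heterogeneous annotations the validity curve can plateau or drift, and
  the selected c then reflects annotation structure as much as expression
  structure.
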