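# trnmotif

Inference of **transcriptional regulatory network motifs (TRNMs)** from
three data layers: gene-expression time courses, a mixed molecular
interaction network, and Gene Ontology annotation.

A transcriptional regulatory network is built from small repeated circuits
— network motifs — in which transcription factors (TFs) drive target genes
directly (protein–DNA interactions, PDIs) and through protein complexes
(protein–protein interactions, PPIs).  `trnmotif` is for computational
biologists who want to go from raw time-course and interaction data to
concrete, quantitative motif-level modules: *this* TF, acting through
*this* circuit shape, regulating *these* gene clusters, with a fitted
dynamical model and an error to judge it by.

## What it does

1. **Preprocess** probe-level expression: collapse multi-probe genes by
   variance, KNN-impute missing values, min–max standardize to [−1, 1].
2. **Cluster** profiles with fuzzy c-means, the fuzziness exponent *m*
   estimated from the pairwise-distance distribution.
3. **Select the cluster number** by GO semantic validity: partitions for
   c = 2…50 are scored by the mean within-cluster gene similarity
   (Schlicker's relevance measure, best-match average across ontology
   branches) and the best-scoring partition is kept.  Per-cluster GO
   over-representation (hypergeometric with resampling adjustment) is
   available for annotating the clusters.
4. **Discover motifs**: every connected three-node subgraph of the mixed
   PPI/PDI network is classified into a canonical triad class; a class is a
   motif if it occurs ≥ 5 times and at most 5% of 1000 degree-preserving
   randomized networks reach its count.
5. **Assign TFs** (selected by GO terms for transcription-regulatory
   function) to each significant class in which they hold a regulator
   position.
6. **Infer modules**: each (TF, motif class) pair is modelled as a small
   recurrent neural network whose clamped nodes are TF profiles and whose
   free nodes should reproduce candidate cluster centroids,

       x_i(t+Δt) = (Δt/τ_i) · tanh(Σ_j w_ji x_j(t) + β_i) + (1 − Δt/τ_i) · x_i(t),

   fitted by particle swarm optimization (RMSE objective) inside a genetic
   algorithm that searches which clusters (and, where needed, which partner
   TF) the motif connects.

A synthetic-data module generates complete scenarios — expression,
network, ontology, annotations — with planted modules and full ground
truth, so every stage is testable without downloads.

## Worked example

`examples/05_infer_module.py` plants a single-regulator module
(w = +2.4, β = +0.1, τ = 1.5) driven by a sinusoidal TF profile, hides its
trajectory among 10 decoy clusters, and lets the GA–PSO search rank all
candidates:

```
rank  cluster  fitted RMSE
   1        0  0.0108  <- planted target
   2        2  0.2203
   3        6  0.2982
   4        7  0.3258
   5        3  0.3548

fitted weight +2.57 (true +2.40), bias +0.10 (true +0.10)
```

The planted cluster is the only candidate the module's own dynamics can
reproduce (RMSE 0.011, an order of magnitude below the best decoy), and the
fitted parameters land near the generating ones.

`examples/06_run_pipeline.py` runs the whole framework on the default
synthetic scenario (86 genes × 47 time points, three planted modules) and
scores it against the ground truth; with master seed 17 it prints, among
other things:

```
  TF01   pdi>|pdi>|ppi          [5,1]  0.080
  TF02   pdi<|pdi<|ppi          [0]  0.097
  TF04   pdi>|pdi>|pdi>         [4,2]  0.235

planted modules recovered exactly: 3 of 3
```

Each line is an inferred module: the TF, the canonical signature of its
motif class (three tokens, one per node pair — `pdi>` a regulatory edge,
`ppi` a binding edge), the chosen cluster indices and the fitted RMSE.  All
three planted modules — a TF driving two interacting clusters, a
co-regulating TF pair, and a feed-forward loop — are rediscovered from the
data alone.

The remaining examples (`examples/01`–`04`) cover scenario generation,
preprocessing, cluster-number selection and motif discovery one capability
at a time.

## Command line

```bash
trnmotif synth --preset small --seed 17 --out scenario/
trnmotif run --config scenario/config.toml --out run/
```

`run` executes all six stages, resumes from existing stage outputs, and
writes a manifest (input digests, stage timings, seeds).  Identical inputs
and master seed reproduce `trnm.json` byte for byte.  Each stage is also
available as its own subcommand.

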