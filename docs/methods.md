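# Methods

## Evaluation protocol

For a graph G = (V, E) with |E| = m edges, one experiment *run* proceeds:

1. **Test split.** A uniformly random 20% of E (round-half-up) is hidden as
   the test edge set Y; an equally sized set of non-edges Ỹ is drawn
   uniformly at random. E′ = E − Y is the remaining graph.
2. **Missingness sampling.** The sampler under study selects an observed edge
   set E_sample from the largest connected component of E′, targeting 64% of
   m. E_sample is all any predictor sees when computing features. The
   leftover Z = E′ − E_sample (~16% of m) is the validation edge set for
   supervised methods; validation and training non-edge pools are drawn
   disjointly from the non-edges excluding Ỹ.
3. **Scoring and AUC.** Test pairs are class-balanced by drawing 10,000
   positives from Y and 10,000 negatives from Ỹ with replacement. The AUC is
   the Mann–Whitney rank statistic with midranks, i.e. the probability that a
   random true missing edge outranks a random non-edge, ties counted ½.
4. **Repeats.** Five runs per network by default; within a run, every sampler
   and predictor shares the same Y/Ỹ so comparisons are paired.

Split sizes use round-half-up so stated percentages are exact on paper-sized
counts. If the sampler's target exceeds the LCC of E′, the target is clamped
and logged. A `SplitBundle.audit()` verifies all containment and disjointness
invariants (Y ∪ Ỹ disjoint from E′, E_sample ⊆ LCC(E′), Z = E′ − E_sample,
non-edge pools mutually disjoint and disjoint from Ỹ) on every construction.

## Missingness samplers (20, in 5 categories)

- **Edge-based:** uniform random edges; random node–edge (pick a node, then
  one incident edge); a 50/50 hybrid of those two (α = 0.5); random edge
  induction (each node retained with p = 0.5; induced edges kept, topped up
  uniformly).
- **Node-based:** nodes drawn without replacement proportionally to degree,
  uniformly, or to PageRank; the sample is the growing induced edge set.
- **Traversal:** depth-first search keeping tree edges.
- **Neighbor-based (connected growth):** diffusion, forest fire (burn
  probability p = 0.4, geometric fan-out), non-backtracking / plain /
  restarting (r = 0.1) / Metropolis–Hastings (β = 1, acceptance
  min(1, d_u/d_v)) / circulated-neighbors random walks, and BFS. Stalled
  walks reseed inside the visited region, so samples stay connected.
- **Jump-based:** random walk with jump (j = 0.1), random node–neighbor
  closure, shortest paths between random pairs, and loop-erased random walk
  (whose output is a spanning tree of the k nodes it covers).

Defaults (0.4, 0.5, 0.1, β = 1) are the conventional values for these
processes. DFS and loop-erased sampling cannot exceed n − 1 edges; on sparse
graphs this means they may fall short of the 64% target by construction —
that deficiency is part of the missingness pattern being studied, not an
error.

## Link predictors (9, in 4 families)

- **Local similarity:** Adamic–Adar, Jaccard, preferential attachment,
  computed on the observed sample.
- **Embedding:** spectral (leading eigenvectors of the normalized adjacency,
  dim 16, deterministic sign convention) and node2vec (unbiased walks,
  p = q = 1, 10 walks × length 40, window 5, dim 32, skip-gram with 5
  negative samples) scored either by inner product or by a logistic
  classifier on Hadamard edge features (C ∈ {0.1, 1, 10} by 5-fold CV).
- **Block models:** greedy-modularity partition scored by between-block edge
  density, and a degree-corrected stochastic block model selected by minimum
  description length (agglomerative merges plus node moves, 3 restarts)
  scored by θ_i θ_j ω_{rs}.
- **Ensemble (stacking):** a random forest (100 trees, depth/feature grid by
  5-fold CV) over 13 topological pair features (endpoint degrees, common
  neighbors, Adamic–Adar, Jaccard, resource allocation, preferential
  attachment, endpoint clustering, shortest path capped at 10, endpoint
  PageRank, same-community flag). Features are computed from E_sample only;
  training positives come from the validation edges Z — edges *not* present
  when features were computed — because training on E_sample edges teaches
  the model to detect edges already baked into the features, which overfits
  (the forest then keys on the shortest-path-equals-1 presence indicator).
  The leaky arrangement is retained behind a flag solely for regression
  testing.

Any pair with an endpoint outside the observed sample receives the table's
minimum score (feature rows: zeros with the path length at its cap) — such a
pair is indistinguishable from nothing.

## Synthetic benchmark suite

Six domains stand in for the kinds of networks the protocol targets:
planted partitions for social (mixing 0.1) and informational (0.25) networks
with k = max(2, n // 50) communities; preferential-attachment graphs for
biological and economic networks; random geometric graphs (largest
component) for technological and transportation networks. Sizes are drawn
from [100, 400] (full envelope 21–899) with mean degree ≈ 5.

The suite emulates the *structural families* — community structure, heavy
tails, spatial constraint — at realistic size and sparsity. It does not
emulate degree–degree correlations, clustering levels, weighted or temporal
structure, or any particular real network; absolute AUC values on it are not
comparable to values on empirical corpora, only the *contrasts* between
samplers and predictors are meaningful.

## Numerical conventions

- Count targets round half up; AUC uses midranks; aggregation reports
  population standard deviations (ddof = 0); winner counts award shared wins
  on exact ties.
- All seeds derive from one master seed through `numpy.random.SeedSequence`
  with structured keys (network, run, sampler, predictor), so every cell is
  reproducible in isolation and all derived seeds stay below 2³¹.
- PageRank is computed by power iteration (damping 0.85, tolerance 1e-9)
  with dangling-mass redistribution.
- The sampler-profile PCA centers per-network mean-AUC columns (no variance
  scaling by default), imputes missing cells with the domain mean, and fixes
  component signs so each loading vector sums to a nonnegative value.
- The skip-gram trainer uses minibatch SGD (batch 64): small batches avoid
  the stale-gradient blow-ups that large batches cause on small vocabularies.

## Limitations

- The tests validate protocol arithmetic, sampler and predictor invariants,
  oracle equivalences, and scaled-down directional contrasts on the synthetic
  suite; they do not compute or certify any empirical result on real network
  corpora.
- At n ≈ 200 the validation set Z holds only ~16% of edges, so supervised
  methods train on few unique positives; stacked-ensemble comparisons at this
  scale are noisier than the same contrasts on large networks, and the
  overfitting penalty of the leaky training arrangement is visible in
  calibration (collapsed score spread) more reliably than in AUC.
- MDL-DCSBM uses a greedy heuristic fit, not an exact or sampled posterior;
  node2vec uses unbiased walks (p = q = 1) rather than the biased
  second-order walk.
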