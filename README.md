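# missnet

Link-prediction benchmarks almost always create "missing" edges by deleting a
uniformly random subset of the edge list. Real gaps in network data are rarely
like that: a field survey misses the edges of under-sampled individuals, a web
crawl only sees what a traversal reaches, and an API-limited scrape follows
walks with occasional jumps. **missnet** measures how much this matters. It
removes edges from a graph with 20 different *missingness samplers* — uniform
edge deletion, degree- and PageRank-biased node sampling, depth- and
breadth-first traversals, diffusion and forest-fire processes, and a family of
random walks with restarts, jumps, and loop erasure — and evaluates 9 link
predictors (local similarity indices, spectral and node2vec embeddings,
modularity and MDL-selected degree-corrected block models, and a stacked
random-forest ensemble) under each pattern.

The core statistic is the **AUC**: the probability that a predictor scores a
randomly chosen held-out true edge above a randomly chosen non-edge, ties
counted one half. Each experiment cell hides 20% of the edges as the test set,
hands a sampler the remaining 80% to subsample down to an observed graph of
64% of the original edges, keeps the leftover ~16% as a validation set for
supervised methods, and computes the AUC on class-balanced test pairs.
Repeated over networks, samplers, predictors, and random seeds, this yields
mean±sd AUC tables per domain, winner counts per predictor, and a PCA that
characterizes samplers by their per-network AUC profiles.

Because the pipeline's appetite for real network corpora far exceeds a desk
machine, the package ships a synthetic six-domain benchmark suite
(community-structured graphs for social/informational, heavy-tailed graphs
for biological/economic, and spatial graphs for technological/transportation
domains, n between 21 and 899, mean degree ≈ 5).

## Run the tests

```sh
python -m pytest -q tests/
```

## Worked example

Generate two synthetic networks, remove edges uniformly and by depth-first
traversal, and compare two predictors:

```python
import missnet as mn
from missnet.missingness_samplers import SamplerSpec
from missnet.link_predictors import PredictorSpec
from missnet.evaluation_analysis import run_experiment, records_to_frame

suite = mn.make_benchmark_suite(
    mn.SuiteConfig(counts={"social": 1, "biological": 1}, seed=7)
)
for net_id, graph, domain in suite:
    print(net_id, domain, graph.n, graph.m)

records, failures = run_experiment(
    suite,
    [SamplerSpec("random_edge"), SamplerSpec("dfs")],
    [PredictorSpec("adamic_adar"), PredictorSpec("modularity")],
    repeats=2,
    master_seed=7,
    class_size=1000,
)
df = records_to_frame(records)
print(df.groupby(["sampler", "predictor"])["auc"].mean().round(3))
```

Output:

```text
biological_0 biological 384 1143
social_0 social 288 753
sampler      predictor
dfs          adamic_adar    0.506
             modularity     0.528
random_edge  adamic_adar    0.549
             modularity     0.642
Name: auc, dtype: float64
```

The traversal-based pattern depresses every predictor relative to uniform
edge removal — a DFS keeps a spanning-tree skeleton and destroys the local
redundancy (common neighbors, dense blocks) that predictors rely on.

A command-line interface mirrors the library: `missnet suite`, `missnet
subsample`, `missnet run`, `missnet aggregate`, `missnet winners`, and
`missnet pca` (see `missnet --help`).

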