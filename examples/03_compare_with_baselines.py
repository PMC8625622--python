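"""Benchmark the flow ranker against the five centrality baselines.

Runs 5 independent planted-driver fixtures and reports each method's mean
precision@5: the fraction of its top-5 drugs that target a planted driver.
The flow method sees both the network and the disease (risk genes); degree,
closeness, betweenness and PageRank see only the network topology, and the
restarting random walk is seeded at the risk genes.
"""

from ppiflow import SyntheticSpec, compare_methods, summarize_comparison

spec = SyntheticSpec(n_nodes=500, driver_boost=10, seed=0)
df = compare_methods(spec, n_replicates=5, k=5)
summary = summarize_comparison(df)
print(summary.to_string(index=False))
print(f"\nRandom-guess expectation: {df['random_expectation'].mean():.3f}")
print("mean_precision is the average fraction of top-5 drugs hitting a "
      "planted driver; methods above the random line carry real signal.")
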