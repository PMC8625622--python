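# ppiflow

Maximum-flow drug repurposing on protein–protein interaction (PPI) networks.

Systems-biology groups often have three data assets and one question: an
interactome, a list of proteins targeted by approved drugs, and a list of
disease risk genes (e.g. from GWAS) — which of the approved drugs are the
best candidates to repurpose for that disease? `ppiflow` answers this by
measuring how much interaction signal each drug target can push through the
network to the risk genes, and lifting that target score to the drugs.

## The method

1. **Edge weighting.** The unweighted PPI graph gets a weight per edge from
   the topological overlap measure (TOM):

   `TOM(x, y) = (|N(x) ∩ N(y)| + A_xy) / (min(|N(x)|, |N(y)|) + 1 − A_xy)`

   where `N(v)` is the neighbour set of `v` and `A_xy` the 0/1 adjacency
   indicator. TOM lies in [0, 1] and serves as the edge's flow capacity.

2. **Flow network ("MaxNet").** Each undirected edge becomes two antiparallel
   arcs of equal capacity. A dummy source `SDN` gains an arc to every drug
   target `t` with capacity `Σ` of `t`'s real out-capacities; every risk gene
   `g` gains an arc to a dummy sink `DDN` with capacity `Σ` of `g`'s real
   in-capacities. The dummy arcs are deliberately non-restrictive.

3. **Maximum flow.** A from-scratch FIFO push-relabel solver maximises the
   flow `SDN → DDN` subject to `0 ≤ flow(e) ≤ capacity(e)` and conservation
   at every non-terminal node. An independent Edmonds–Karp solver ships as a
   testing oracle.

4. **Prioritisation.** Targets are ranked by the flow on their source arc
   (their throughput toward the risk genes); each drug inherits the flow
   value of its best-ranked target from a drug–target interaction table.

Five baseline rankers (degree, closeness, betweenness, PageRank, random walk
with restart) run over the same inputs through the identical drug-ranking
rule, and a synthetic planted-driver benchmark scores all six methods.

## Worked example

`examples/02_rank_drugs_by_maxflow.py` builds a 500-node synthetic study
(50 targets, a 50-gene risk module, 5 hidden "driver" targets wired into the
module) and runs the full pipeline:

```
MaxNet: 502 nodes, 3188 arcs (50 source arcs, 50 sink arcs)
Total flow from targets to risk genes: 38.0726

rank	drug	best_target	flow	driver_drug?
1	D00011	G00122	3.9557	yes
2	D00013	G00122	3.9557	yes
3	D00014	G00122	3.9557	yes
4	D00060	G00122	3.9557	yes
5	D00061	G00122	3.9557	yes
```

All five top drugs hit planted drivers: the flow value 3.9557 is the amount
of capacity-weighted signal the shared best target `G00122` pushes into the
risk module, and the total flow 38.07 is the network-wide maximum. The
companion scripts print network statistics with TOM weight ranges (`01`) and
the benchmark against all baselines (`03`), where the flow ranker's mean
precision@5 (0.88) sits far above the topology-only baselines (0.12) and the
random-guess line (0.17).

The same pipeline runs from the shell on your own files:

```sh
ppiflow make-fixture --out-dir study/         # or bring your own TSVs
ppiflow rank --network study/network.tsv --targets study/targets.txt \
    --risk-genes study/risk_genes.txt --dti study/dti.tsv --out-dir out/
ppiflow compare --replicates 5                # method benchmark
```

Input formats: the network is a 2+ column TSV edge list (`#` comments; mark
header lines with `#`), node sets are one ID per line, and the drug–target
table is a two-column TSV.

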