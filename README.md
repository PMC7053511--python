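# herdnet

Activity-stratified proximity-network analysis for focal-sampling studies
of group-living animals.

In behavioral ecology, the social structure of a herd is often measured by
recording, for every animal in every observation period, the single
activity it performs (grazing, moving, standing, ruminating, wallowing,
lying, drinking) and the conspecifics it is in close proximity with while
doing so.  `herdnet` turns such records into **one binary undirected
network per (activity, period)** over the fixed full-herd vertex set,
quantifies each network with standard structural indices, and tests how
activities and animal attributes relate to those indices.  A seeded
synthetic-campaign generator emulates the whole observation design, so the
complete pipeline can be exercised, validated and benchmarked without any
field data.

## The model

For a herd of N animals, each observation period t and activity a yield an
adjacency matrix α with α_ij = 1 iff animals i and j were in proximity
while both performing a in period t (zero diagonal, symmetric; an activity
that does not occur gives an empty network).  Per network, the global
indices are

* density D = Σ_ij α_ij / (N² − N),
* number of connected components (isolates count as singletons),
* clustering coefficient CC = (1/N) Σ_i CC_i, where CC_i is the fraction
  of i's neighbour pairs that are themselves connected;

and per vertex the local indices are degree deg_i = Σ_j α_ij, closeness
Cl_i = 1 / Σ_j d_ij (geodesic distances, summed over reachable vertices),
Freeman betweenness b_i = Σ_{j<k} g_j(i)k / g_jk (raw, endpoints
excluded), and eigenvector centrality e_i, the Perron–Frobenius
eigenvector of α max-normalized to 1.

Associations are estimated with two-tailed Spearman rank correlations
(mid-ranks for ties; p from the t approximation) on three data sets:
per-network global indices vs. seven binary activity indicators;
per-(network, vertex) centralities vs. the same indicators; and, within
each activity, centralities vs. the animal's age and gender (1 = female,
2 = male).  Significance is flagged at p < 0.05 (*) and p < 0.01 (**).

## Worked example

Simulate a default campaign (91 animals — 88 females aged 0.5–23 y,
3 young males — and 240 half-hour periods) and analyze it end to end:

```bash
herdnet run-all --seed 1 --out demo
```

The log reports the design identities:

```
simulated 91 animals x 240 periods -> 21840 records
built 1680 networks (7 activities x 240 periods, 91 vertices)
indexed 1680 global rows, 152880 local cases
computed 105 association results
```

`demo/` then contains the roster and records CSVs, the index tables, the
association results and correlogram tables.  The global correlogram
(`demo/correlogram_global_vs_activity.txt`) for this seed reads:

```
              grazing   moving standing ruminating wallowing    lying drinking
density        0.60**   0.23**     0.04    -0.16**    -0.06*  -0.28**  -0.38**
n_components  -0.56**  -0.24**  -0.08**     0.18**    0.08**   0.24**   0.37**
clustering     0.67**   0.16**  -0.11**    -0.08**      0.01  -0.32**  -0.33**
```

Read column-wise: periods of grazing produce dense, highly clustered,
well-connected networks (positive density/clustering, negative component
count), while the rare, bout-synchronized resting activities fragment the
herd (negative density, positive component count).  These are exactly the
structures the synthetic generator is configured to produce — grazing
cohesive and clustered, lying sparse with a hub hierarchy, age and gender
participation biases in specific activities — so recovering these signs
(each at p < 0.01) is the pipeline's end-to-end correctness check.

The same run can be driven step by step (`herdnet simulate`,
`build-networks`, `indices`, `correlate`), from a YAML config
(`--config`), and fully in Python:

```python
from herdnet import GeneratorConfig, simulate, run_analysis

roster, records = simulate(GeneratorConfig(seed=1))
out = run_analysis(roster, records)
print(out.index_table.globals_.head())
```

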