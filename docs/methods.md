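# Methods

This note documents the models, conventions and numerical choices behind
`herdnet`: what each stage computes, where the design was genuinely open,
and what the synthetic data do and do not show about real observations.

## Observation model

The unit of observation is one animal in one 30-minute period: its single
activity (out of a closed catalogue of seven) and the set of conspecifics
it was in proximity with while performing it.  The default campaign
design is 12 months × 2 session days × 10 half-hour steps = 240 periods
over a herd of 91 animals (88 females 0.5–23 y, three males 2.5–3 y),
giving 21,840 records.

Validation enforces the protocol: exactly one record per (animal,
period); partners must be on the roster, observed in the same period, and
performing the same activity; no self-partnering.  Proximity is a
reciprocal relation, so one-sided reports (A lists B, B omits A) are
closed by union with a logged warning — observers record one side of a
mutual event.  Proximity is deliberately *not* transitively closed: the
pairwise distance criterion does not imply that two animals flanking a
third are themselves close.  Animals unobserved in a period are allowed
and simply appear isolated in that period's networks.

## Network construction

One binary undirected network per (activity, period) — 7 × 240 = 1680 in
the default design — always over the full 91-animal vertex set in roster
order.  Isolates are first-class: an animal performing another activity
is an isolated vertex, and an activity that does not occur yields an
empty network that stays in the ensemble.  This convention is forced by
the case bookkeeping (1680 networks × 91 vertices = 152,880 vertex-cases)
and by the components analysis, where fragmentation is the signal.
Serialization (GraphML via the standard library's XML tooling, or
edge-list CSV with a vertex side-car file) always declares all vertices
so isolates survive round-trips.

## Structural indices

All indices are computed from first principles in this package;
`networkx` appears only as an independent oracle in the test suite.
Computations are restricted to the non-isolated subgraph wherever
possible, because the ensemble is dominated by networks in which most of
the herd is isolated.

* **Density** D = Σ α_ij / (N² − N); undefined (error) for N < 2.
* **Components** by breadth-first search; isolates are singleton
  components, so an empty network has N components.
* **Clustering** CC = (1/N) Σ CC_i with CC_i = 0 when deg_i < 2; all N
  vertices enter the average (the formula divides by N).  A switch
  restricts the average to vertices with degree ≥ 2 for comparison with
  that alternative convention.
* **Closeness** Cl_i = 1/Σ d_ij.  On a fragmented network the strict sum
  is infinite, so distances are summed over vertices *reachable* from i,
  and isolates get 0.  This is the common graph-library convention; it
  keeps the index finite and monotone in connectivity, which matters in
  an ensemble where most networks are fragmented.
* **Betweenness** is Freeman's raw sum over unordered pairs, endpoints
  excluded, no normalization.  Implemented with Brandes' single-source
  accumulation (halving the undirected double count); the test suite
  checks it against exhaustive geodesic enumeration.
* **Eigenvector centrality** is the Perron–Frobenius eigenvector,
  max-normalized to 1.  It is computed per connected component by power
  iteration on A + I from the all-ones vector: the identity shift leaves
  eigenvectors unchanged but makes the Perron eigenvalue strictly
  dominant within each component, so bipartite components (stars,
  chains — ubiquitous in sparse proximity networks) converge rather than
  oscillate.  Only components attaining the network's leading eigenvalue
  carry mass; all other components and all isolates are *exactly* zero.
  The exact zero matters downstream: the association stage is rank-based,
  and numerical residue on sub-dominant components would spuriously
  outrank genuine isolates.  Components tied for the leading eigenvalue
  (within 1e-9 relative) each keep their Perron vector max-normalized to
  1 — a deterministic convention for a case the definition leaves open.
  Convergence: successive-iterate change < 1e-10 in max norm, cap 10,000
  iterations (an error reports the residual if ever reached).
* Empty networks take degenerate conventions without traversal: density
  0, N components, clustering 0, all centralities 0.  This keeps every
  network usable as a case in the correlation stage.

## Association analysis

Three data sets: (1) per-network global indices with seven binary
activity indicators (one per activity — each figure-style correlation is
one indicator vs. one index; a single categorical code could not produce
per-activity correlations); (2) per-(network, vertex) centralities with
the same indicators; (3) per activity, the centrality rows joined with
the vertex's age and gender (1 = female, 2 = male).  Empty networks are
included as cases at their degenerate values — excluding them would strip
rare activities of almost all contrast, and the strong negative density
associations of rare activities arise precisely from their many empty
networks.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties); the two-tailed p-value uses t = rho·√((n−2)/(1−rho²)) on n − 2
degrees of freedom, the standard large-sample approximation (|rho| = 1
returns p = 0; an exact permutation p is available for n ≤ 10).  Pairs
with a constant vector (e.g. a centrality that never varies) are
undefined and reported as missing with a logged reason.  No
multiple-testing correction is applied by default; a Holm step-down
option exists.  Significance flags: p < 0.05 and p < 0.01.

## Synthetic campaign generator

The generator emulates the observation design so the full pipeline is
testable end to end.  Per period: (0) activities with `bout_rate` < 1 are
only *available* in exactly that fraction of periods (scheduled at random
positions) — this models herd-level behavioral synchronization, e.g.
communal resting bouts, and concentrates the same overall prevalence into
fewer, larger co-performances; (1) each animal draws one activity from a
softmax over the available activities' log-weights, shifted by the
activity's participation biases (a slope on standardized age and an
additive male effect — one knob acting on both activity choice and group
joining, since both are facets of "participating in the activity's social
life"); (2) performers join the activity's social pool with a logistic
probability carrying the same biases; (3) the pool is partitioned into
groups with shifted-Poisson sizes, wired as a random spanning chain plus
independent extra pairs with probability `group_closure` — the chain
guarantees group connectivity while closure independently controls
triangle density, decoupling the density and clustering knobs; (4) where
`hub_attachment` > 0, pool members instead attach to a few acting hubs
(the highest-priority pool members under a fixed seed-derived ranking,
chained to each other), forming one star-of-stars component with a steep
eigenvector hierarchy.  Hubs are drawn from within the period's pool
because a globally designated hub would rarely perform a rare activity,
and the same-activity rule forbids wiring to an inactive animal.

Female ages follow a truncated normal on 0.5–23 y with location chosen so
the mean is ≈ 9 y; male ages are uniform on 2.5–3 y.  All randomness
flows from one master seed through a single `numpy` generator stream;
identical configs give bit-identical output.

### Default conditions

The study reports no activity time budget, so prevalences are design
choices: grazing 0.33, moving 0.15, standing 0.12, ruminating 0.10,
wallowing 0.10, lying 0.14, drinking 0.06.  The default profiles encode
the qualitative social structure the pipeline is meant to detect, and
they double as the parameter-recovery conditions in the acceptance
tests: grazing cohesive and clustered (groups of ~4, closure 0.9); moving
and standing loose with strong male participation (+1.5 logits) and
negative age participation (−1.0); wallowing with negative age
participation; lying bout-synchronized (30% of periods), hub-attached
(0.9) and hierarchical; drinking sparse and hub-attached.  Two details
were found to be load-bearing for the lying hierarchy signal and are
deliberate: acting hubs are chained (separate stars would split the
eigenvector mass across components), and the bout schedule uses an exact
count of periods rather than per-period coin flips (binomial noise in the
bout count otherwise dominates seed-to-seed variance of the effect).

### What the synthetic data do not show

The generator has no spatial movement model, no temporal autocorrelation
of activities across periods (beyond bout scheduling), no kinship
structure, and no observation error.  Group sizes follow a convenience
law (shifted Poisson), not a fitted one.  Passing the recovery tests
therefore shows that the *pipeline* faithfully propagates known structure
into the published-style correlograms — not that real herds have this
structure, nor that effect sizes on field data would match.

## Problem sizes and determinism

The default design (91 × 240; 1680 networks; 152,880 cases) runs in a few
seconds, so tests and the acceptance script use it directly; recovery
checks run the full pipeline for three master seeds.  The analysis stage
is fully deterministic — all randomness is confined to simulation, and
power iteration starts from a fixed vector — so identical inputs and
configuration produce identical outputs.

## Known limitations

* The closeness and eigenvector conventions on fragmented networks are
  choices among several defensible ones; both are documented above and
  the clustering/empty-network switches expose the main alternatives.
* The Spearman t approximation is inaccurate for very small n; the exact
  mode covers n ≤ 10 only.
* Rank correlations over (network, vertex) cases treat cases as
  exchangeable; network-level non-independence (e.g. node-permutation or
  QAP null models) is out of scope.
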